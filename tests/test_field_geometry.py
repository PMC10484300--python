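"""Tiling, NMS merging, homographies, ridge detection and ID assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from headcast.errors import (
    DegenerateLayoutError,
    EmptyWindowError,
    InvalidConfigError,
    InvalidDataError,
    ProjectionError,
)
from headcast.field_geometry import (
    Detection,
    ProjectiveTransform,
    TilingConfig,
    assign_ids,
    backward_project,
    crop_roi,
    detect_ridges,
    detections_to_positions,
    forward_project,
    nms_merge,
    tile_image,
)
from headcast.head_morphometry import HeadPolygon

from .oracles import brute_force_nms, lexicographic_ids


def random_homography(rng):
    """Random well-conditioned homography (affine + mild perspective)."""
    while True:
        m = np.eye(3) + rng.normal(0, 0.2, (3, 3))
        m[2, :2] = rng.normal(0, 1e-4, 2)  # mild perspective row
        m[2, 2] = 1.0
        if abs(np.linalg.det(m)) > 1e-3:
            return ProjectiveTransform(m)


class TestTiling:
    def test_paper_scale_sectors(self):
        windows = tile_image(TilingConfig((2600, 2600), 1300, 200))
        assert len(windows) == 4
        first = windows[0]
        assert first.core == (0, 0, 1300, 1300)
        assert first.buffered == (0, 0, 1500, 1500)
        # last sector touches the extent: buffer clipped, buffered == core
        assert windows[-1].core == (1300, 1300, 2600, 2600)
        assert windows[-1].buffered == windows[-1].core

    def test_single_sector_extent(self):
        (w,) = tile_image(TilingConfig((1300, 1300), 1300, 200))
        assert w.core == (0, 0, 1300, 1300)
        assert w.buffered == w.core

    def test_ragged_extent(self):
        windows = tile_image(TilingConfig((2000, 1300), 1300, 200))
        assert [w.core for w in windows] == [(0, 0, 1300, 1300), (1300, 0, 2000, 1300)]

    @given(
        w=st.integers(1, 900),
        h=st.integers(1, 900),
        s=st.integers(50, 400),
        buf_frac=st.floats(0, 0.99),
    )
    def test_core_windows_partition_extent(self, w, h, s, buf_frac):
        buf = int(buf_frac * s)
        windows = tile_image(TilingConfig((w, h), s, buf))
        # every pixel in exactly one core window: areas sum and windows are disjoint
        assert sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in
                   (win.core for win in windows)) == w * h
        for i, a in enumerate(windows):
            ax0, ay0, ax1, ay1 = a.core
            bx0, by0, bx1, by1 = a.buffered
            assert bx0 == ax0 and by0 == ay0 and bx1 >= ax1 and by1 >= ay1
            for b in windows[i + 1:]:
                ox = min(ax1, b.core[2]) - max(ax0, b.core[0])
                oy = min(ay1, b.core[3]) - max(ay0, b.core[1])
                assert ox <= 0 or oy <= 0

    def test_invalid_configs(self):
        with pytest.raises(InvalidConfigError):
            TilingConfig((100, 100), 0, 0)
        with pytest.raises(InvalidConfigError):
            TilingConfig((100, 100), 50, 50)  # buffer must be < sector size


class TestNMS:
    def test_duplicate_suppressed(self):
        a = Detection(0, 0, 10, 10, score=0.9)
        b = Detection(0, 0, 10, 10, score=0.8)
        kept = nms_merge([a, b], 0.5)
        assert kept == [a]

    def test_disjoint_all_kept_score_order(self):
        dets = [Detection(20 * i, 0, 20 * i + 10, 10, score=0.5 + 0.01 * i) for i in range(5)]
        kept = nms_merge(dets, 0.5)
        assert len(kept) == 5
        assert [d.score for d in kept] == sorted((d.score for d in dets), reverse=True)

    def test_matches_brute_force_on_random_boxes(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            xy = rng.uniform(0, 100, (n, 2))
            wh = rng.uniform(5, 30, (n, 2))
            scores = rng.uniform(0, 1, n)
            dets = [
                Detection(x, y, x + w, y + h, score=s)
                for (x, y), (w, h), s in zip(xy, wh, scores)
            ]
            kept = nms_merge(dets, 0.5)
            boxes = np.column_stack([xy, xy + wh])
            expect = brute_force_nms(boxes, scores, 0.5)
            assert [dets.index(d) for d in kept] == expect

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        dets = [
            Detection(x, y, x + 15, y + 15, score=s)
            for (x, y), s in zip(rng.uniform(0, 60, (40, 2)), rng.uniform(0, 1, 40))
        ]
        once = nms_merge(dets, 0.5)
        assert nms_merge(once, 0.5) == once

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidDataError):
            Detection(5, 5, 5, 10)

    def test_threshold_validated(self):
        with pytest.raises(InvalidConfigError):
            nms_merge([Detection(0, 0, 1, 1)], 1.5)


class TestPositions:
    def test_identity_transform_center(self):
        det = Detection(0, 0, 10, 10)
        pts = detections_to_positions([det], ProjectiveTransform.identity())
        assert pts[0] == pytest.approx([5.0, 5.0])

    def test_translation_homography(self):
        tf = ProjectiveTransform.scale_translate(1.0, 1.0, tx=3.0, ty=-2.0)
        det = Detection(0, 0, 10, 10)
        assert detections_to_positions([det], tf)[0] == pytest.approx([8.0, 3.0])

    def test_missing_sector_transform(self):
        det = Detection(0, 0, 10, 10, sector_id=3)
        with pytest.raises(InvalidConfigError):
            detections_to_positions([det], {0: ProjectiveTransform.identity()})


class TestProjection:
    def test_identity_and_scale(self):
        poly = HeadPolygon(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0]]))
        same = forward_project(poly, ProjectiveTransform.identity())
        assert np.allclose(same.vertices, poly.vertices)
        scaled = forward_project(poly, ProjectiveTransform.scale_translate(3.0, 3.0))
        assert np.allclose(scaled.vertices, 3.0 * poly.vertices)

    @given(seed=st.integers(0, 10_000))
    def test_round_trip_within_1e8(self, seed):
        rng = np.random.default_rng(seed)
        tf = random_homography(rng)
        pts = rng.uniform(-100, 100, (50, 2))
        back = backward_project(forward_project(pts, tf), tf)
        assert np.max(np.abs(back - pts)) < 1e-8

    def test_matches_skimage_reference(self):
        skimage_tf = pytest.importorskip("skimage.transform")
        rng = np.random.default_rng(99)
        for _ in range(20):
            tf = random_homography(rng)
            pts = rng.uniform(-50, 50, (20, 2))
            ref = skimage_tf.ProjectiveTransform(tf.matrix)(pts)
            assert np.allclose(tf.apply(pts), ref, atol=1e-9)

    def test_line_at_infinity(self):
        m = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        tf = ProjectiveTransform(m)
        with pytest.raises(ProjectionError):
            tf.apply(np.array([-1.0, 0.0]))  # w = x + 1 = 0

    def test_singular_rejected(self):
        with pytest.raises(InvalidConfigError):
            ProjectiveTransform(np.zeros((3, 3)))


class TestRidges:
    @staticmethod
    def grid_positions(rng, n_ridges, per_ridge, jitter):
        x = np.repeat(np.arange(n_ridges) * 0.70, per_ridge)
        y = np.tile(-np.arange(per_ridge) * 0.35, n_ridges)
        pts = np.column_stack([x, y])
        return pts + rng.normal(0, jitter, pts.shape), np.repeat(
            np.arange(n_ridges), per_ridge
        )

    def test_three_ridges_perfectly_assigned(self):
        rng = np.random.default_rng(0)
        pts, truth = self.grid_positions(rng, 3, 30, 0.03)
        assert np.array_equal(detect_ridges(pts, 0.70), truth)

    def test_single_ridge(self):
        rng = np.random.default_rng(1)
        pts, _ = self.grid_positions(rng, 1, 20, 0.03)
        assert np.array_equal(detect_ridges(pts, 0.70), np.zeros(20, dtype=int))

    def test_field_scale_ridge_count(self):
        # a 10-ridge, ~740-plant season-scale layout
        rng = np.random.default_rng(2)
        pts, truth = self.grid_positions(rng, 10, 74, 0.03)
        found = detect_ridges(pts, 0.70)
        assert found.max() + 1 == 10
        assert np.array_equal(found, truth)

    def test_empty_errors(self):
        with pytest.raises(DegenerateLayoutError):
            detect_ridges(np.empty((0, 2)), 0.70)


class TestAssignIds:
    def test_stated_ordering(self):
        # W-ridge N, W-ridge S, E-ridge N, E-ridge S
        pts = np.array([[0.0, 0.0], [0.0, -0.35], [0.7, 0.0], [0.7, -0.35]])
        ridges = np.array([0, 0, 1, 1])
        assert np.array_equal(assign_ids(pts, ridges), [1, 2, 3, 4])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, (40, 2))
        ridges = rng.integers(0, 4, 40)
        ids = assign_ids(pts, ridges)
        perm = rng.permutation(40)
        assert np.array_equal(assign_ids(pts[perm], ridges[perm]), ids[perm])

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 50, (500, 2))
        ridges = rng.integers(0, 10, 500)
        assert np.array_equal(assign_ids(pts, ridges), lexicographic_ids(pts, ridges))


class TestCropROI:
    def test_centered_window(self):
        assert crop_roi((50.0, 50.0), 100) == (0, 0, 100, 100)

    def test_corner_clipped(self):
        assert crop_roi((0.0, 0.0), 100, image_extent=(1000, 1000)) == (0, 0, 50, 50)

    def test_outside_image(self):
        with pytest.raises(EmptyWindowError):
            crop_roi((1500.0, 10.0), 100, image_extent=(1000, 1000))
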