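import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from headcast.growth_model import GrowthModelParams, TemperatureSeries

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_2020() -> GrowthModelParams:
    """Field-initialization growth parameters of the 2020-style season."""
    return GrowthModelParams(a=5.53, b=2.05, c=0.00546)


@pytest.fixture(scope="session")
def params_2021() -> GrowthModelParams:
    return GrowthModelParams(a=5.57, b=2.11, c=0.00558)


def const_temps(tmean: float, start="2020-03-01", end="2020-06-30") -> TemperatureSeries:
    idx = pd.date_range(start, end, freq="D")
    return TemperatureSeries(idx, np.full(len(idx), float(tmean)))


@pytest.fixture(scope="session")
def temps_warm() -> TemperatureSeries:
    """Constant 19.6 degC (a typical May mean) over the season."""
    return const_temps(19.6)


def headlike_polygon(rng, n_vertices=None, diameter=120.0, radial_noise=0.05,
                     stretch=1.0, angle_deg=0.0):
    """Random star-convex outline emulating a segmented head boundary.

    Roundish many-vertex polygons are the domain the morphometry operates
    on; tiny-vertex-count polygons can have exactly tied minimum-area
    rectangle orientations with different long sides, which no segmentation
    outline exhibits.
    """
    n = int(n_vertices if n_vertices is not None else rng.integers(12, 64))
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = (diameter / 2.0) * (1 + rng.normal(0, radial_noise, n))
    pts = np.column_stack([r * np.cos(theta) * stretch, r * np.sin(theta)])
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ rot.T
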