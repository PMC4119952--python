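import numpy as np
import pytest

from dxt.detector import Panel
from dxt.fixtures import FixtureSpec, random_spots, write_smv_sweep


def make_standard_panel(**overrides) -> Panel:
    """The reference single-panel geometry used across the tests: fast
    (1,0,0), slow (0,-1,0), origin (-50, 50, 200), 0.1 mm pixels, 1000x1000,
    so the direct beam (0,0,1) strikes at (50, 50) mm."""
    kwargs = dict(
        name="std",
        fast_axis=(1.0, 0.0, 0.0),
        slow_axis=(0.0, -1.0, 0.0),
        origin=(-50.0, 50.0, 200.0),
        pixel_size=(0.1, 0.1),
        image_size=(1000, 1000),
    )
    kwargs.update(overrides)
    return Panel(**kwargs)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def make_random_panel(rng, **overrides) -> Panel:
    """A randomly oriented and shifted copy of the standard panel.

    Rotating the whole frame keeps the sample on the front side, so rays
    aimed at panel points always intersect."""
    R = random_rotation(rng)
    shift = rng.uniform(-20, 20, size=3)
    base = make_standard_panel()
    return make_standard_panel(
        fast_axis=R @ base.fast_axis,
        slow_axis=R @ base.slow_axis,
        origin=R @ (base.origin + shift),
        **overrides,
    )


def ray_to_panel_point(panel: Panel, xy_mm) -> np.ndarray:
    lab = panel.lab_coord(xy_mm)
    return lab / np.linalg.norm(lab)


@pytest.fixture
def standard_panel() -> Panel:
    return make_standard_panel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140719)


@pytest.fixture
def sweep_spec() -> FixtureSpec:
    """A small 5-image rotation fixture with a handful of spots."""
    spec = FixtureSpec(image_size=(200, 200), beam_centre=(10.0, 10.0), n_images=5, seed=7)
    spec.spots = random_spots(spec, 4, np.random.default_rng(7))
    return spec


@pytest.fixture
def sweep_paths(tmp_path, sweep_spec):
    return write_smv_sweep(sweep_spec, tmp_path / "sweep")
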