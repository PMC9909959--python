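import numpy as np
import pytest

from ctoam.imageio import CTVolume
from ctoam.phantom import PhantomSpec
from ctoam.surface_mapping import DensityMap2D

#: scaled-down phantom geometry used where many phantoms are generated
SMALL_SPEC = PhantomSpec(grid_shape=(28, 28, 24), shell_thickness_mm=8.0)


@pytest.fixture
def small_spec() -> PhantomSpec:
    return SMALL_SPEC


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> CTVolume:
    return CTVolume(data=np.asarray(data), spacing_mm=spacing)


def random_volume_and_mask(rng, max_side=20, lo=-200, hi=1500):
    """A random integer-HU volume with a random ROI mask (small grids)."""
    shape = tuple(int(rng.integers(6, max_side + 1)) for _ in range(3))
    hu = rng.integers(lo, hi, size=shape)
    mask = rng.random(shape) < 0.5
    return make_volume(hu), mask


# ---------------------------------------------------------------------------
# pattern-classification fixtures: one map per taxonomy label


def _disc(values, cx, cy, r, val=1000.0):
    n = values.shape[0]
    xs, ys = np.meshgrid(np.arange(values.shape[0]), np.arange(values.shape[1]), indexing="ij")
    values[(xs - cx) ** 2 + (ys - cy) ** 2 <= r**2] = val
    return values


def _band(values, x0, x1, y0, y1, val=1000.0):
    values[x0 : x1 + 1, y0 : y1 + 1] = val
    return values


def _map_from(values, bone, side="right") -> DensityMap2D:
    footprint = np.ones_like(values, dtype=bool)
    return DensityMap2D(
        values=values.astype(float),
        footprint=footprint,
        pixel_spacing_mm=(1.0, 1.0),
        bone=bone,
        side=side,
    )


def build_pattern_fixtures() -> list[tuple[str, str, DensityMap2D, str]]:
    """(name, bone, map, expected label) covering all seven taxonomy labels.

    40x40 footprint at 1 mm pixels; background 400 HU, high-density areas
    at 1000 HU (cutoff 901); min area 25 mm^2, tibial "center" 100 mm^2.
    """
    base = lambda: np.full((40, 40), 400.0)  # noqa: E731
    fixtures = [
        ("femur_blank", "distal_femur", _map_from(base(), "distal_femur"), "Blank"),
        (
            "femur_anterior_lateral",
            "distal_femur",
            _map_from(_disc(base(), 33, 6, 4), "distal_femur"),
            "Anterior-Lateral",
        ),
        (
            "femur_dual_center",
            "distal_femur",
            _map_from(_disc(_disc(base(), 6, 20, 4), 33, 20, 4), "distal_femur"),
            "Dual Center",
        ),
        (
            "femur_center_connections",
            "distal_femur",
            _map_from(_band(base(), 5, 35, 18, 22), "distal_femur"),
            "Center Connections",
        ),
        ("tibia_blank", "tibial_plateau", _map_from(base(), "tibial_plateau"), "Blank"),
        (
            "tibia_scatter",
            "tibial_plateau",
            _map_from(_disc(_disc(base(), 6, 6, 3.5), 6, 33, 3.5), "tibial_plateau"),
            "Scatter",
        ),
        (
            "tibia_multi_center",
            "tibial_plateau",
            _map_from(_disc(_disc(base(), 6, 20, 6), 33, 20, 6), "tibial_plateau"),
            "Multi-Center",
        ),
        (
            "tibia_multi_center_connections",
            "tibial_plateau",
            _map_from(_band(base(), 5, 35, 18, 22), "tibial_plateau"),
            "Multi-Center Connections",
        ),
    ]
    return fixtures


@pytest.fixture(scope="session")
def pattern_fixtures():
    return build_pattern_fixtures()
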