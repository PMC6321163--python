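import numpy as np
import pytest

from fibriltrace import ConditionLabel, HeightMap, SceneSpec, render_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 512 px / 5 x 5 um scene with well-separated objects, rendered once."""
    spec = SceneSpec(
        image_px=512,
        scan_size=5000.0,
        n_fibrils=25,
        n_oligomers=12,
        length_median=250.0,
        seed=7,
    )
    return spec, *render_scene(spec)


@pytest.fixture(scope="session")
def isotropic_scene():
    """Like small_scene but without per-scan-line offsets, whose row
    alignment is the one deliberately anisotropic background term; used for
    rotation-invariance checks of the morphometry itself."""
    spec = SceneSpec(
        image_px=512,
        scan_size=5000.0,
        n_fibrils=25,
        n_oligomers=12,
        length_median=250.0,
        line_offset_sigma=0.0,
        seed=7,
    )
    return spec, *render_scene(spec)


@pytest.fixture()
def any_condition():
    return ConditionLabel(0.0, 24.0)


def paint_rod(shape, r0, c0, n_rows, n_cols):
    """Axis-aligned rectangular rod mask."""
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + n_rows, c0 : c0 + n_cols] = True
    return m


def heightmap_from_mask(mask, height=5.0, pixel_size=10.0):
    return HeightMap(np.where(mask, height, 0.0), pixel_size)
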