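import numpy as np
import pytest

from parcelscope.raster_io import Scene


def gaussian_bump(shape, centre_rc, sigma_px, amplitude):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return amplitude * np.exp(
        -((rr - centre_rc[0]) ** 2 + (cc - centre_rc[1]) ** 2) / (2 * sigma_px**2)
    )


def make_test_scene(
    width=64,
    height=64,
    gsd=1.0,
    origin=(1000.0, 2000.0),
    roles=("blue", "green", "red", "nir1"),
    fill=(0.06, 0.10, 0.18, 0.24),
    crs_id="EPSG:32630",
):
    """A flat multispectral scene to paint features onto."""
    bands = np.empty((len(roles), height, width), dtype=np.float32)
    for i, v in enumerate(fill):
        bands[i] = v
    return Scene(
        bands=bands,
        band_map={r: i for i, r in enumerate(roles)},
        geotransform=(origin[0], origin[1], gsd, gsd),
        crs_id=crs_id,
    )


@pytest.fixture
def flat_scene():
    return make_test_scene()


@pytest.fixture(scope="session")
def default_sim():
    from parcelscope.scene_sim import SimConfig, make_scene

    return make_scene(SimConfig(seed=7))
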