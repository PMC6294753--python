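import numpy as np
import pytest

from octavld import (
    DeviceProfile,
    DEVICE_PROFILES,
    NetworkConfig,
    generate_vessel_network,
    render_angiogram,
)
from octavld.synthetic import CAPILLARY, LARGE, quadrant_geometries, rasterize_centerlines


@pytest.fixture(scope="session")
def network():
    """Default phantom vasculature (disc, 5 radial vessels, 22 mm^-1 mesh)."""
    return generate_vessel_network(seed=1, config=NetworkConfig())


@pytest.fixture(scope="session")
def noise_free_image(network):
    """Noise-free render of the default phantom (device PSF, no noise)."""
    profile = DeviceProfile(
        "NoiseFree", psf_sigma_mm=0.004, noise_sd=0.0, capillary_sensitivity=1.0
    )
    return render_angiogram(network, profile, seed=2)


@pytest.fixture(scope="session")
def device_image(network):
    """Default phantom rendered with a realistic device profile (noise on)."""
    return render_angiogram(network, DEVICE_PROFILES["Triton"], seed=3)


@pytest.fixture(scope="session")
def capillary_centerlines(network):
    return rasterize_centerlines(network, CAPILLARY)


@pytest.fixture(scope="session")
def large_centerlines(network):
    return rasterize_centerlines(network, LARGE)


@pytest.fixture(scope="session")
def quadrant_gt_density(network):
    """Ground-truth capillary VLD (mm^-1) per quadrant from polyline clipping."""
    quads = quadrant_geometries(network.disc_center_mm, 1.5, 2.25, "OD")
    return {
        loc: network.region_length_mm(geom, CAPILLARY) / geom.area
        for loc, geom in quads.items()
    }
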