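import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from organoquant import image_core as ic, synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_plane(pixels, channel="APOL1", px=1.0, provenance="raw", image_id="img"):
    return ic.ImagePlane(
        pixels=np.asarray(pixels, dtype=float),
        channel_name=channel,
        pixel_size_um=px,
        image_id=image_id,
        provenance=provenance,
    )


def make_mask(pixels, px=1.0):
    return ic.BinaryMask(np.asarray(pixels, dtype=bool), px, origin="threshold")


@pytest.fixture
def small_config():
    """A quick-to-render organoid field used by generator and assay tests."""
    return sd.GeneratorConfig(
        field_size_px=(192, 192),
        z_slices=5,
        organoid=sd.OrganoidConfig(semi_axes_um=(45.0, 35.0), tuft_radius_um=10.0),
        nuclei=sd.NucleiConfig(count=40),
        seed=7,
    )


@pytest.fixture
def noiseless_config(small_config):
    """Same geometry with noise and background switched off."""
    return small_config.replace(
        noise=sd.NoiseConfig(gaussian_sigma=0.0, poisson_gain=0.0),
        channels=sd.ChannelConfig(background=0.0),
    )
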