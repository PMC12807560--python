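import numpy as np
import pytest

from nircat.synthetic import AcquisitionProtocol, GroundTruthManifest, HotspotSpec, NoiseModel


@pytest.fixture
def small_protocol() -> AcquisitionProtocol:
    """Scaled-down acquisition for fast tests: 30 x 24 um FOV, 90 frames."""
    return AcquisitionProtocol(
        frame_rate=9.0,
        n_frames=90,
        stim_frame=30,
        fov_width_um=30.0,
        fov_height_um=24.0,
        um_per_pixel=0.5,
    )


@pytest.fixture
def quiet_noise() -> NoiseModel:
    return NoiseModel(baseline_level=1000.0, additive_sd=0.0, bleach_fraction=0.0)


@pytest.fixture
def one_hotspot_manifest(small_protocol, quiet_noise) -> GroundTruthManifest:
    """A single hotspot in the middle of the small FOV, noiseless."""
    return GroundTruthManifest(
        hotspots=[
            HotspotSpec(
                center_um=(14.75, 11.75),
                footprint_sigma_um=1.5,
                amplitude=0.05,
                tau_on_s=0.2,
                tau_off_s=5.0,
            )
        ],
        protocol=small_protocol,
        noise=quiet_noise,
        seed=7,
    )
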