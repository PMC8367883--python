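import numpy as np
import pytest

from dida import KineticsModel, RegionOfInterest, SimulationConfig, generate_assay


@pytest.fixture(scope="session")
def small_decay_config():
    """Compact complete-disintegration assay: 30 s at 10 Hz, noiseless."""
    return SimulationConfig(
        frame_size_px=(64, 64),
        tablet_center_px=(32.0, 32.0),
        tablet_radius_px=16.0,
        duration_s=30.0,
        noise_sd=0.0,
        n_replicates=1,
        seed=11,
        kinetics=KineticsModel(model="decay_to_plateau", rate_k_per_s=0.2, plateau_pct=0.0),
    )


@pytest.fixture(scope="session")
def small_decay_bundle(small_decay_config):
    return generate_assay(small_decay_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def uniform_roi():
    """ROI covering the central quarter of a 64x64 frame."""
    return RegionOfInterest.from_rectangle(16, 16, 48, 48, (64, 64))


def brute_force_mgv(frame, mask):
    """Independent oracle: explicit Python loop over masked pixels."""
    total = 0.0
    count = 0
    h, w = frame.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                total += float(frame[y, x])
                count += 1
    return total / count
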