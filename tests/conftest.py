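import numpy as np
import pytest

import helipore as hp


@pytest.fixture(scope="session")
def small_traj():
    """2 copies x 30 frames, rigid-ish helices above the bilayer."""
    spec = hp.TrajectorySpec(
        sequence=hp.TEMPORIN_L, n_copies=2, n_frames=30, kappa=200.0, seed=11
    )
    return hp.generate_helix_trajectory(spec)


@pytest.fixture(scope="session")
def three_level_trace():
    amps = [0.8, 2.5, 5.4]
    q = np.zeros((4, 4))
    q[0, 1:] = [30.0, 15.0, 8.0]
    q[1:, 0] = 300.0
    spec = hp.TraceSpec(
        amplitudes=amps, rates=q, duration=2.0, noise_sigma=0.15, seed=42
    )
    trace, truth = hp.generate_channel_trace(spec)
    return spec, trace, truth
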