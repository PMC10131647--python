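import pytest

from turncoord.simulate import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def nf_sim():
    """Noise-free default trial with ground truth (shared, read-only)."""
    return simulate_trial(SimulationConfig(marker_noise_sd_m=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default trial with 2 mm marker noise (shared, read-only)."""
    return simulate_trial(SimulationConfig(seed=1))


#: configured onset latencies expressed in the cranial-reference sign
#: convention (negative: cranial segment starts first)
TRUE_LATENCIES = {
    "sternum_head": -0.08,
    "pelvis_head": -0.18,
    "pelvis_sternum": -0.10,
}
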