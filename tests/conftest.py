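import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cogwear.deconvolution import event_match_f1  # noqa: E402
from cogwear.synthetic import simulate_sparse_impulse_train, synthesize_scr_trace

# re-exported for the test modules
make_sparse_impulses = simulate_sparse_impulse_train
detection_f1 = event_match_f1


def make_scr_trace(seed, n_steps=800, snr_db=20.0, tonic_level=1.5, y_p0=0.2):
    """Synthetic skin conductance at a given phasic SNR; returns
    (trace, impulse locations, amplitudes, noise_sd)."""
    impulses, locs, amps = simulate_sparse_impulse_train(seed, n_steps)
    phasic_only = synthesize_scr_trace(
        impulses, tonic_coeffs=0.0, y_p0=0.0, noise_sd=0.0
    ).y
    noise_sd = float(np.sqrt(np.mean(phasic_only**2) / 10 ** (snr_db / 10)))
    trace = synthesize_scr_trace(
        impulses, tonic_coeffs=tonic_level, y_p0=y_p0,
        noise_sd=noise_sd, seed=seed + 1000,
    )
    return trace, locs, amps, noise_sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
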