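import numpy as np
import pytest

from asickin.sweeps import (
    RecordingMeta,
    StimulusEpoch,
    StimulusProtocol,
    Sweep,
    SweepBlock,
    stimulus_waveform,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


@pytest.fixture
def pulse_protocol():
    """100 ms rest, 500 ms pH 5 test pulse, short tail."""
    return StimulusProtocol(epochs=(StimulusEpoch(0.1, 0.5, 5.0, "test"),), rest_level=8.0)


def make_square_block(
    amplitudes,
    protocol=None,
    sample_interval=1e-3,
    t_end=0.7,
    noise_sd=0.0,
    seed=0,
):
    """Block of square-pulse sweeps with prescribed (signed) peak amplitudes.

    Current is 0 at rest and `amplitude` during the stimulation epoch; handy
    for exercising peak-based selection logic with exactly known peaks.
    """
    protocol = protocol or StimulusProtocol(
        epochs=(StimulusEpoch(0.1, 0.5, 5.0, "test"),), rest_level=8.0
    )
    time = np.arange(0.0, t_end, sample_interval)
    stim = stimulus_waveform(protocol, time)
    ep = protocol.epochs[0]
    in_pulse = (time >= ep.start) & (time < ep.end)
    rng = np.random.default_rng(seed)
    meta = RecordingMeta(sample_interval=sample_interval)
    sweeps = []
    for k, amp in enumerate(amplitudes):
        cur = np.where(in_pulse, float(amp), 0.0)
        if noise_sd > 0:
            cur = cur + rng.normal(0.0, noise_sd, time.size)
        sweeps.append(Sweep(time=time, current=cur, stimulus=stim, meta=meta, sweep_index=k))
    return SweepBlock(sweeps=sweeps, protocol=protocol)


def random_scheme(rng, n_states=4, rate_scale=50.0):
    """Random irreducible kinetic scheme with two pH levels."""
    from asickin.gating import KineticScheme

    states = tuple(f"S{i}" for i in range(n_states))
    rates = {}
    for level in (8.0, 5.0):
        Q = rng.lognormal(mean=0.0, sigma=1.0, size=(n_states, n_states)) * rate_scale / 10
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rates[level] = Q
    return KineticScheme(states=states, conducting=frozenset({states[-1]}), rates=rates)
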