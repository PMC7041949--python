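"""Synthetic patch-clamp data generators.

No raw recordings accompany the study this package supports, so every
analysis stage is exercised against synthetic outside-out patch data whose
ground truth is known: N independently gating channels (exact event-driven
Gillespie simulation of a kinetic scheme, or per-sample binomial thinning of
a deterministic open-probability time course), a single-channel current i,
white Gaussian baseline noise, multiplicative cumulative per-sweep rundown,
and a finite solution-exchange time (10-90% transit 250-500 us) smoothing
the pH command.  Phenomenological generators produce recovery fractions and
desensitization decays directly from their closed forms so round-trip fits
can be checked without the stochastic layer.

Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .recovery import RecoveryCurve, recovery_model
from .gating import KineticScheme, steady_state
from .sweeps import (
    RecordingMeta,
    StimulusProtocol,
    Sweep,
    SweepBlock,
    stimulus_waveform,
)

__all__ = [
    "NoiseModel",
    "EnsembleSpec",
    "apply_solution_exchange",
    "simulate_stochastic_sweep",
    "generate_nsfa_block",
    "generate_recovery_fractions",
    "generate_decay_trace",
    "activation_desensitization_popen",
]

LN9 = math.log(9.0)


@dataclass(frozen=True)
class NoiseModel:
    baseline_sd: float = 0.0  # pA
    rundown_per_sweep: float = 0.0  # fraction lost per sweep
    rundown_jitter_sd: float = 0.0  # fractional jitter on the per-sweep factor

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if abs(self.rundown_per_sweep) >= 0.2:
            raise ValueError("|rundown_per_sweep| must be < 0.2")


@dataclass
class EnsembleSpec:
    n_channels: int
    single_channel_current: float  # pA
    scheme: KineticScheme | None = None
    popen: np.ndarray | None = None  # deterministic P_open on the sample grid
    exchange_time_10_90: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.exchange_time_10_90 < 0:
            raise ValueError("exchange_time_10_90 must be >= 0")
        if (self.scheme is None) == (self.popen is None):
            raise ValueError("give exactly one of scheme or popen")


# ---------------------------------------------------------------------------
# Solution exchange
# ---------------------------------------------------------------------------

def apply_solution_exchange(
    protocol: StimulusProtocol,
    exchange_time_10_90: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Replace each pH step by an exponential relaxation toward the new level.

    The relaxation time constant is exchange/ln 9 so the 10-90% transit of
    each step equals ``exchange_time_10_90``.  Zero exchange returns the
    ideal square command unchanged.  Returns the smoothed stimulus samples;
    a warning flag is attached as ``.exchange_warning`` when the exchange
    time exceeds the shortest epoch.
    """
    grid = np.asarray(grid, dtype=float)
    square = stimulus_waveform(protocol, grid)
    if exchange_time_10_90 == 0.0:
        return square
    shortest = min(ep.duration for ep in protocol.epochs) if protocol.epochs else np.inf
    if exchange_time_10_90 > shortest:
        import warnings

        warnings.warn(
            "solution-exchange time exceeds the shortest epoch; steps will not settle",
            stacklevel=2,
        )
    dt = grid[1] - grid[0]
    tau = exchange_time_10_90 / LN9
    alpha = math.exp(-dt / tau)
    out = np.empty_like(square)
    y = square[0]
    for k, target in enumerate(square):
        y = target + (y - target) * alpha
        out[k] = y
    return out


# ---------------------------------------------------------------------------
# Stochastic channel ensembles
# ---------------------------------------------------------------------------

def _gillespie_open_counts(
    scheme: KineticScheme,
    protocol: StimulusProtocol,
    n_channels: int,
    grid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact event-driven simulation of state counts, zero-order-held onto
    the sample grid.  pH changes at epoch boundaries; all channels share the
    piecewise-constant rate matrix but jump independently (the aggregate
    count process is simulated, which is statistically exact)."""
    from .gating import _segments  # piecewise-constant cover of the protocol

    n_states = scheme.n_states
    cond = scheme.conducting_indices
    p0 = steady_state(scheme, protocol.rest_level)
    counts = rng.multinomial(n_channels, p0).astype(np.int64)
    open_counts = np.zeros(grid.size, dtype=np.int64)
    dt = grid[1] - grid[0]
    pos = 0  # next grid index to fill

    flat_targets = np.repeat(np.arange(n_states), n_states), np.tile(np.arange(n_states), n_states)
    for start, end, level in _segments(protocol, t_end=float(grid[-1]) + dt):
        Q = scheme.Q(level)
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        exit_rates = off.sum(axis=1)  # per-channel exit rate per state
        t = start
        while t < end:
            total = float(counts @ exit_rates)
            if total <= 0.0:
                t = end
            else:
                t = t + rng.exponential(1.0 / total)
            # hold current open count up to min(t, end)
            stop = min(t, end)
            upto = min(grid.size, int(math.ceil((stop - 1e-12) / dt)))
            if upto > pos:
                open_counts[pos:upto] = counts[cond].sum()
                pos = upto
            if t >= end:
                break
            # pick the transition a -> b by inverse-CDF over the flattened
            # (source, target) propensity table
            weights = (counts[:, None] * off).ravel()
            cum = np.cumsum(weights)
            k = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            a, b = flat_targets[0][k], flat_targets[1][k]
            counts[a] -= 1
            counts[b] += 1
    if pos < grid.size:
        open_counts[pos:] = counts[cond].sum()
    return open_counts


def simulate_stochastic_sweep(
    spec: EnsembleSpec,
    protocol: StimulusProtocol,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    sample_interval: float = 1e-4,
    t_end: float | None = None,
    meta: RecordingMeta | None = None,
    sweep_index: int = 0,
    amplitude_scale: float = 1.0,
) -> Sweep:
    """One synthetic sweep: i x (open count)(t) + Gaussian baseline noise.

    Deterministic given the seed.  ``amplitude_scale`` is applied to the
    noise-free component (used by the block generator for rundown).
    """
    rng = np.random.default_rng(seed)
    end = protocol.end + 0.05 if t_end is None else t_end
    grid = np.arange(0.0, end, sample_interval)
    if spec.scheme is not None:
        open_counts = _gillespie_open_counts(spec.scheme, protocol, spec.n_channels, grid, rng)
    else:
        p = np.asarray(spec.popen, dtype=float)
        if p.size != grid.size:
            raise ValueError(
                f"popen length {p.size} does not match grid length {grid.size}"
            )
        open_counts = rng.binomial(spec.n_channels, np.clip(p, 0.0, 1.0))
    clean = spec.single_channel_current * open_counts.astype(float) * amplitude_scale
    current = clean + rng.normal(0.0, noise.baseline_sd, grid.size)
    stimulus = apply_solution_exchange(protocol, spec.exchange_time_10_90, grid)
    return Sweep(
        time=grid,
        current=current,
        stimulus=stimulus,
        meta=meta or RecordingMeta(sample_interval=sample_interval),
        sweep_index=sweep_index,
    )


def generate_nsfa_block(
    spec: EnsembleSpec,
    protocol: StimulusProtocol,
    n_sweeps: int,
    noise: NoiseModel,
    seed: int,
    sample_interval: float = 1e-4,
    t_end: float | None = None,
    meta: RecordingMeta | None = None,
) -> SweepBlock:
    """A run of sweeps on a shared grid, with multiplicative cumulative
    rundown: sweep s is scaled by prod_{k<=s} (1 - rundown + jitter_k)."""
    if n_sweeps < 2:
        raise ValueError("need at least 2 sweeps for a block")
    master = np.random.SeedSequence(seed)
    sweep_seeds = master.spawn(n_sweeps + 1)
    jitter_rng = np.random.default_rng(sweep_seeds[-1])
    scale = 1.0
    sweeps = []
    for s in range(n_sweeps):
        if s > 0:
            factor = 1.0 - noise.rundown_per_sweep
            if noise.rundown_jitter_sd > 0:
                factor += jitter_rng.normal(0.0, noise.rundown_jitter_sd)
            scale *= max(0.0, factor)
        sweeps.append(
            simulate_stochastic_sweep(
                spec, protocol, noise, sweep_seeds[s],
                sample_interval=sample_interval, t_end=t_end,
                meta=meta, sweep_index=s, amplitude_scale=scale,
            )
        )
    return SweepBlock(sweeps=sweeps, protocol=protocol)


# ---------------------------------------------------------------------------
# Phenomenological generators
# ---------------------------------------------------------------------------

def generate_recovery_fractions(
    tau: float,
    m: float,
    intervals: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    form: str = "hh_power",
) -> RecoveryCurve:
    """Fraction-recovered points from the configured recovery form, with
    Gaussian noise, clipped to [0, 1.05] (measured ratios can exceed 1)."""
    if tau <= 0 or m <= 0:
        raise ValueError("tau and m must be positive")
    intervals = np.asarray(intervals, dtype=float)
    frac = recovery_model(intervals, tau, m, form)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = frac + rng.normal(0.0, noise_sd, frac.size)
    frac = np.clip(frac, 0.0, 1.05)
    return RecoveryCurve(interval=intervals, fraction=frac)


def generate_decay_trace(
    tau_des: float,
    iss_fraction: float,
    peak: float,
    sample_interval: float = 1e-4,
    duration: float = 1.5,
    onset: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
    stim_level: float = 5.0,
    rest_level: float = 8.0,
) -> Sweep:
    """A desensitizing current: 0 before onset, then
    peak * (iss + (1-iss) * exp(-(t-onset)/tau_des)), plus optional noise."""
    if tau_des <= 0:
        raise ValueError("tau_des must be positive")
    if not (0.0 <= iss_fraction <= 1.0):
        raise ValueError("iss_fraction must be in [0, 1]")
    from .sweeps import StimulusEpoch

    grid = np.arange(0.0, onset + duration, sample_interval)
    current = np.zeros(grid.size)
    after = grid >= onset
    tt = grid[after] - onset
    current[after] = peak * (iss_fraction + (1.0 - iss_fraction) * np.exp(-tt / tau_des))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, grid.size)
    protocol = StimulusProtocol(
        epochs=(StimulusEpoch(onset, duration, stim_level, "test"),),
        rest_level=rest_level,
    )
    stim = stimulus_waveform(protocol, grid)
    sweep = Sweep(
        time=grid, current=current, stimulus=stim,
        meta=RecordingMeta(sample_interval=sample_interval),
    )
    sweep.protocol = protocol
    return sweep


def activation_desensitization_popen(
    grid: np.ndarray,
    peak_popen: float,
    tau_rise: float,
    tau_des: float,
    onset: float,
    iss_fraction: float = 0.0,
) -> np.ndarray:
    """Deterministic open-probability time course: a fast exponential rise
    multiplying a desensitizing decay, renormalized so its maximum equals
    ``peak_popen``.  Used as the binomial-thinning target for NSFA blocks."""
    grid = np.asarray(grid, dtype=float)
    p = np.zeros(grid.size)
    after = grid >= onset
    tt = grid[after] - onset
    shape = (1.0 - np.exp(-tt / tau_rise)) * (
        iss_fraction + (1.0 - iss_fraction) * np.exp(-tt / tau_des)
    )
    peak = shape.max()
    if peak <= 0:
        raise ValueError("degenerate open-probability shape")
    p[after] = peak_popen * shape / peak
    return p
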