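"""Non-stationary fluctuation analysis (NSFA).

For a patch of N identical channels with single-channel current i, the
ensemble variance of the macroscopic current I obeys the parabola

    sigma^2(I) = i*I - I^2/N + sigma^2_baseline

so fitting binned (I, sigma^2) pairs yields i and N, and from them the peak
open probability P_open = |I_peak| / |i*N| and the single-channel
conductance g = i / (V_hold - E_rev).

Variance is computed from successive-sweep differences,
delta_i^2(t) = (T_{i+1}(t) - T_i(t))^2 / 2, rather than deviations from the
grand mean: slow rundown that is locally linear across neighbouring sweeps
cancels to first order.  Sweep selection mimics experimental practice: the
longest contiguous stretch whose peak amplitudes stay within a 10% band is
kept, and sweeps with spurious variance (brief electrical artifacts) are
excluded by a robust z-score on their successive-difference variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .recovery import measure_epoch_peak
from .sweeps import RecordingMeta, SweepBlock

__all__ = [
    "VarianceTrace",
    "NSFAResult",
    "select_stable_stretch",
    "exclude_artifact_sweeps",
    "pairwise_variance",
    "baseline_variance",
    "bin_current_variance",
    "fit_current_variance",
    "run_nsfa",
]


@dataclass
class VarianceTrace:
    time: np.ndarray
    mean_current: np.ndarray  # pA
    ensemble_variance: np.ndarray  # pA^2
    n_pairs: int


@dataclass
class NSFAResult:
    binned_current: np.ndarray
    binned_variance: np.ndarray
    baseline_variance: float
    i_single: float  # pA, signed like the current
    n_channels: float
    peak_open_probability: float
    conductance: float  # pS
    fit_rss: float
    sweeps_used: list[int]
    low_confidence: bool = False
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sweep selection
# ---------------------------------------------------------------------------

def _stimulation_window(block: SweepBlock) -> tuple[int, int]:
    ep = block.protocol.first_nonrest()
    if ep is None:
        raise ValueError("protocol has no stimulation epoch")
    dt = block.meta.sample_interval
    return int(round(ep.start / dt)), min(block.time.size, int(round(ep.end / dt)))


def _peaks(block: SweepBlock, smooth_samples: int = 3) -> np.ndarray:
    w0, w1 = _stimulation_window(block)
    nb = max(2, min(w0, int(round(0.05 / block.meta.sample_interval))))
    base = (w0 - nb, w0)
    return np.array(
        [measure_epoch_peak(sw, (w0, w1), base, smooth_samples) for sw in block.sweeps]
    )


def select_stable_stretch(block: SweepBlock, tolerance: float = 0.10) -> list[int]:
    """Longest contiguous run of sweeps whose |peak| stays within a
    max/min <= 1 + tolerance band; earliest run wins ties."""
    if len(block) < 2:
        raise ValueError("need at least 2 sweeps")
    peaks = np.abs(_peaks(block))
    n = peaks.size
    best: tuple[int, int] | None = None
    start = 0
    # two-pointer scan with running window extrema
    for end in range(1, n + 1):
        while start < end - 1:
            window = peaks[start:end]
            if window.max() <= (1.0 + tolerance) * window.min():
                break
            start += 1
        window = peaks[start:end]
        if window.max() <= (1.0 + tolerance) * window.min():
            if best is None or (end - start) > (best[1] - best[0]):
                best = (start, end)
    if best is None or best[1] - best[0] < 2:
        raise ValueError("no stable stretch of >= 2 sweeps; record more data")
    return list(range(best[0], best[1]))


def exclude_artifact_sweeps(
    block: SweepBlock,
    variance_z_threshold: float = 5.0,
    max_passes: int = 5,
) -> list[int]:
    """Drop sweeps whose successive-sample difference variance is a robust
    (median/MAD) outlier; iterates to convergence."""
    if len(block) < 3:
        raise ValueError("need at least 3 sweeps")
    diff_var = np.array([np.var(np.diff(sw.current)) for sw in block.sweeps])
    keep = np.ones(len(block), dtype=bool)
    if not np.isfinite(variance_z_threshold):
        return list(range(len(block)))
    for _ in range(max_passes):
        vals = diff_var[keep]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        scale = 1.4826 * mad if mad > 0 else (np.std(vals) or 1.0)
        z = (diff_var - med) / scale
        new_keep = keep & (z <= variance_z_threshold)
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            keep = new_keep if new_keep.sum() >= 3 else keep
            break
        keep = new_keep
    return [int(k) for k in np.flatnonzero(keep)]


# ---------------------------------------------------------------------------
# Variance estimation
# ---------------------------------------------------------------------------

def pairwise_variance(block: SweepBlock) -> VarianceTrace:
    """Successive-difference ensemble variance and mean current per sample."""
    if len(block) < 2:
        raise ValueError("need at least 2 sweeps for pairwise variance")
    cur = block.current_matrix()
    diffs = np.diff(cur, axis=0)
    var = np.mean(diffs**2 / 2.0, axis=0)
    return VarianceTrace(
        time=block.time,
        mean_current=cur.mean(axis=0),
        ensemble_variance=var,
        n_pairs=len(block) - 1,
    )


def baseline_variance(block: SweepBlock, window: float = 0.050) -> float:
    """Mean pairwise ensemble variance over a window just before stimulation."""
    if window <= 0:
        raise ValueError("baseline window must be positive")
    w0, _ = _stimulation_window(block)
    nb = int(round(window / block.meta.sample_interval))
    if nb > w0:
        raise ValueError("baseline window extends into stimulation")
    trace = pairwise_variance(block)
    return float(trace.ensemble_variance[w0 - nb : w0].mean())


def bin_current_variance(
    trace: VarianceTrace,
    window: tuple[int, int],
    n_bins: int = 10,
    baseline_current: float = 0.0,
    snr_floor: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin the decay-phase samples into ``n_bins`` bins uniform in |mean
    current|.

    Uniform-amplitude bins correspond to progressively larger time bins
    along an exponential relaxation and equalize information per bin.  Empty
    bins are dropped.  Requires the peak to stand clear of the baseline
    (SNR >= ``snr_floor`` in units of the pre-peak variance estimate).
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    w0, w1 = window
    amp = np.abs(trace.mean_current[w0:w1] - baseline_current)
    if amp.max() == 0:
        raise ValueError("no dynamic range: current never leaves baseline")
    noise_sd = math.sqrt(max(trace.ensemble_variance[:w0].mean(), 1e-300)) if w0 > 0 else 0.0
    if noise_sd > 0 and amp.max() / noise_sd < snr_floor:
        raise ValueError("peak not distinguishable from baseline (SNR < 3)")
    pk = int(np.argmax(amp))
    seg_amp = amp[pk:]
    seg_cur = trace.mean_current[w0 + pk : w1]
    seg_var = trace.ensemble_variance[w0 + pk : w1]
    edges = np.linspace(0.0, seg_amp.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(seg_amp, edges) - 1, 0, n_bins - 1)
    bc, bv = [], []
    for b in range(n_bins):
        mask = idx == b
        if not np.any(mask):
            continue
        bc.append(float(seg_cur[mask].mean()))
        bv.append(float(seg_var[mask].mean()))
    return np.array(bc), np.array(bv)


def fit_current_variance(
    binned_current: np.ndarray,
    binned_variance: np.ndarray,
    baseline: float,
    meta: RecordingMeta,
    peak_current: float | None = None,
    free_baseline: bool = False,
) -> NSFAResult:
    """Least-squares fit of the current-variance parabola.

    With the baseline variance fixed (the default; it is a measured additive
    term) the model sigma^2 - baseline = i*I - I^2/N is linear in (i, 1/N)
    and solved directly.  The fitted i carries the sign of the current; a
    negative channel-count estimate is an error, and data that never bend
    over (P_open < 0.5 throughout, variance still rising at max |I|) yield a
    low-confidence flag.
    """
    I = np.asarray(binned_current, dtype=float)
    V = np.asarray(binned_variance, dtype=float)
    if I.size < 3:
        raise ValueError("need at least 3 bins")
    if free_baseline:
        X = np.column_stack([I, -(I**2), np.ones_like(I)])
        coef, rss_arr, *_ = np.linalg.lstsq(X, V, rcond=None)
        i_hat, inv_n, baseline = float(coef[0]), float(coef[1]), float(coef[2])
    else:
        X = np.column_stack([I, -(I**2)])
        coef, rss_arr, *_ = np.linalg.lstsq(X, V - baseline, rcond=None)
        i_hat, inv_n = float(coef[0]), float(coef[1])
    if inv_n <= 0:
        raise ValueError("fitted channel count is not positive; data may lack curvature")
    n_hat = 1.0 / inv_n
    pred = X[:, 0] * i_hat - (I**2) * inv_n + baseline
    rss = float(np.sum((V - pred) ** 2))
    # variance still rising at the largest |I| => vertex beyond the data
    order = np.argsort(np.abs(I))
    lowconf = bool(abs(I[order[-1]]) < abs(i_hat) * n_hat / 2.0)
    popen = float("nan")
    if peak_current is not None:
        popen = abs(peak_current) / abs(i_hat * n_hat)
        if not (0.0 <= popen <= 1.05):
            popen = min(max(popen, 0.0), 1.05)
    erev = meta.reversal_potential if meta.reversal_potential is not None else 0.0
    conductance = 1000.0 * i_hat / (meta.holding_potential - erev)  # pA/mV -> pS
    return NSFAResult(
        binned_current=I,
        binned_variance=V,
        baseline_variance=float(baseline),
        i_single=i_hat,
        n_channels=n_hat,
        peak_open_probability=popen,
        conductance=conductance,
        fit_rss=rss,
        sweeps_used=[],
        low_confidence=lowconf,
        extra={"weighting": "unweighted"},
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_nsfa(
    block: SweepBlock,
    tolerance: float = 0.10,
    n_bins: int = 10,
    baseline_window: float = 0.050,
    variance_z_threshold: float = 5.0,
    free_baseline: bool = False,
) -> NSFAResult:
    """Full NSFA pipeline: stability filter, artifact exclusion, pairwise
    variance, binning, parabola fit, and P_open / conductance conversion."""
    stable = select_stable_stretch(block, tolerance)
    sub = block.subset(stable)
    kept_local = exclude_artifact_sweeps(sub, variance_z_threshold)
    used = [stable[i] for i in kept_local]
    sub = block.subset(used)
    trace = pairwise_variance(sub)
    base = baseline_variance(sub, baseline_window)
    window = _stimulation_window(sub)
    w0, w1 = window
    nb = int(round(baseline_window / sub.meta.sample_interval))
    baseline_level = float(trace.mean_current[w0 - nb : w0].mean()) if w0 else 0.0
    bc, bv = bin_current_variance(trace, window, n_bins, baseline_current=baseline_level)
    peaks = _peaks(sub)
    mean_peak = float(np.mean(peaks))
    result = fit_current_variance(
        bc, bv, base, sub.meta, peak_current=mean_peak, free_baseline=free_baseline
    )
    result.sweeps_used = used
    result.extra["mean_peak_current"] = mean_peak
    return result
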