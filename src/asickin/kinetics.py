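"""Desensitization decay, rise time, sustained current and pH dose-response.

Covers the per-sweep kinetics read-outs used throughout the pipeline:
exponential fits of the desensitization decay (tau_des), 10-90% rise times,
the fractional sustained current Iss/Ipeak and its fold change between pH
values, interleaved-reference normalization of dose-response peaks, the Hill
fit of proton activation

    I(pH) = 1 / (1 + 10^(n * (pH - pH50)))

oriented so acidification increases the response, and the
normalized-peak-trajectory quantification used for photomodulation sweep
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .sweeps import Sweep

__all__ = [
    "DecayFit",
    "HillFit",
    "DoseResponsePoint",
    "fit_exponential_decay",
    "rise_time_10_90",
    "iss_over_ipeak",
    "sustained_fold_change",
    "normalize_interleaved",
    "fit_hill",
    "hill_model",
    "sweep_series_peaks",
]


@dataclass
class DecayFit:
    tau_components: tuple[float, ...]  # s, ordered fast -> slow
    amplitudes: tuple[float, ...]  # pA, matching order
    offset: float  # pA steady-state current
    n_components: int
    fit_window: tuple[int, int]
    flagged: bool = False  # amplitude ~ 0 or tau at window bound

    @property
    def tau_des(self) -> float:
        """Dominant (largest-|amplitude|) time constant."""
        k = int(np.argmax(np.abs(self.amplitudes)))
        return self.tau_components[k]


@dataclass
class HillFit:
    ph50: float
    hill_n: float
    rss: float

    def __post_init__(self) -> None:
        if self.hill_n <= 0:
            raise ValueError("Hill slope must be positive")

    def predict(self, ph: np.ndarray) -> np.ndarray:
        return hill_model(np.asarray(ph, dtype=float), self.ph50, self.hill_n)


@dataclass
class DoseResponsePoint:
    ph: float
    normalized_peak: float
    iss_over_ipeak: float | None = None

    def __post_init__(self) -> None:
        if self.normalized_peak < 0:
            raise ValueError("normalized peak must be >= 0")


def hill_model(ph: np.ndarray, ph50: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (n * (ph - ph50)))


# ---------------------------------------------------------------------------
# Decay / rise / sustained current
# ---------------------------------------------------------------------------

def _peak_in_window(sweep: Sweep, window: tuple[int, int]) -> tuple[int, float, float]:
    """(absolute peak index, signed baseline-subtracted peak, baseline)."""
    w0, w1 = window
    nb = max(2, min(w0, int(round(0.05 / sweep.sample_interval)))) if w0 else 0
    baseline = float(np.mean(sweep.current[w0 - nb : w0])) if nb else 0.0
    seg = sweep.current[w0:w1] - baseline
    k = int(np.argmax(np.abs(seg)))
    return w0 + k, float(seg[k]), baseline


def fit_exponential_decay(
    sweep: Sweep,
    window: tuple[int, int],
    n_components: int = 1,
    start_fraction: float = 0.95,
) -> DecayFit:
    """Fit I(t) = offset + sum_k a_k exp(-t/tau_k) to the decay after a peak.

    The fit window opens at the first post-peak sample where |I| has fallen
    below ``start_fraction`` of the peak (skipping the activation cusp) and
    runs to the window end.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    pk_idx, peak, baseline = _peak_in_window(sweep, window)
    if peak == 0.0:
        raise ValueError("no resolvable peak in the epoch")
    seg = sweep.current[pk_idx : window[1]] - baseline
    below = np.flatnonzero(np.abs(seg) < start_fraction * abs(peak))
    start = int(below[0]) if below.size else 1
    y = seg[start:]
    if y.size < 10:
        raise ValueError("decay window shorter than 10 samples")
    t = np.arange(y.size) * sweep.sample_interval
    t_span = t[-1] if t[-1] > 0 else sweep.sample_interval

    flagged = False
    if n_components == 1:
        def model(tt, a, tau, off):
            return off + a * np.exp(-tt / tau)

        p0 = [y[0] - y[-1], max(t_span / 5.0, sweep.sample_interval), y[-1]]
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
        a, tau, off = popt
        tau = abs(tau)
        taus, amps = (tau,), (float(a),)
    else:
        def model(tt, a1, tau1, a2, tau2, off):
            return off + a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

        amp0 = y[0] - y[-1]
        p0 = [0.6 * amp0, t_span / 20.0, 0.4 * amp0, t_span / 2.0, y[-1]]
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=40000)
        a1, tau1, a2, tau2, off = popt
        pairs = sorted([(abs(tau1), float(a1)), (abs(tau2), float(a2))])
        taus = tuple(p[0] for p in pairs)
        amps = tuple(p[1] for p in pairs)
    if max(abs(a) for a in amps) < 1e-3 * max(abs(peak), 1e-12):
        flagged = True  # essentially a plateau
    if any(tau > 5.0 * t_span for tau in taus):
        flagged = True  # tau at the window-length bound
    return DecayFit(
        tau_components=taus,
        amplitudes=amps,
        offset=float(off),
        n_components=n_components,
        fit_window=(pk_idx + start, window[1]),
        flagged=flagged,
    )


def rise_time_10_90(sweep: Sweep, window: tuple[int, int]) -> float:
    """Time between the last 10% and first 90% crossings preceding the peak,
    with linear interpolation between samples."""
    pk_idx, peak, baseline = _peak_in_window(sweep, window)
    if peak == 0.0:
        raise ValueError("no resolvable peak")
    seg = np.abs(sweep.current[window[0] : pk_idx + 1] - baseline)
    target = abs(peak)
    lo, hi = 0.1 * target, 0.9 * target
    above_hi = np.flatnonzero(seg >= hi)
    if above_hi.size == 0:
        raise ValueError("rise never reaches 90% before the peak")
    k90 = int(above_hi[0])
    below_lo = np.flatnonzero(seg[:k90] <= lo)
    if below_lo.size == 0:
        raise ValueError("no 10% crossing precedes the 90% crossing")
    k10 = int(below_lo[-1])
    dt = sweep.sample_interval

    def interp(k: int, level: float) -> float:
        if k + 1 >= seg.size or seg[k + 1] == seg[k]:
            return k * dt
        return (k + (level - seg[k]) / (seg[k + 1] - seg[k])) * dt

    t10 = interp(k10, lo)
    t90 = interp(k90 - 1, hi) if k90 > 0 and seg[k90] != hi else k90 * dt
    return max(t90 - t10, 0.0)


def iss_over_ipeak(sweep: Sweep, window: tuple[int, int], noise_floor: float = 0.0) -> float:
    """Steady-state (mean of the last 5% of the epoch) over peak current,
    both baseline-subtracted."""
    w0, w1 = window
    if (w1 - w0) * sweep.sample_interval < 0.1:
        raise ValueError("epoch must be at least 100 ms for a steady-state estimate")
    pk_idx, peak, baseline = _peak_in_window(sweep, window)
    if abs(peak) <= noise_floor:
        raise ValueError("peak below noise floor")
    k = max(1, int(round(0.05 * (w1 - w0))))
    steady = float(np.mean(sweep.current[w1 - k : w1])) - baseline
    return steady / peak


def sustained_fold_change(test: DoseResponsePoint, reference: DoseResponsePoint) -> float:
    """(Iss/Ipeak) at the test pH over the same ratio at the reference pH."""
    if test.iss_over_ipeak is None or reference.iss_over_ipeak is None:
        raise ValueError("both points must carry Iss/Ipeak")
    if reference.iss_over_ipeak == 0:
        raise ValueError("reference Iss/Ipeak is zero")
    return test.iss_over_ipeak / reference.iss_over_ipeak


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

def normalize_interleaved(
    peaks: list[tuple[str, float, float]],
) -> list[DoseResponsePoint]:
    """Normalize test peaks by the mean of their flanking reference peaks.

    ``peaks`` is an ordered list of (kind, pH, peak) with kind in
    {"test", "reference"}; every test response must be flanked by reference
    responses on both sides, which corrects first-order rundown.
    """
    points: list[DoseResponsePoint] = []
    for k, (kind, ph, peak) in enumerate(peaks):
        if kind == "reference":
            continue
        if kind != "test":
            raise ValueError(f"unknown response kind {kind!r}")
        prev = next((p for K, _, p in reversed(peaks[:k]) if K == "reference"), None)
        nxt = next((p for K, _, p in peaks[k + 1 :] if K == "reference"), None)
        if prev is None or nxt is None:
            raise ValueError(f"test response at pH {ph} is not flanked by references")
        points.append(DoseResponsePoint(ph=ph, normalized_peak=peak / ((prev + nxt) / 2.0)))
    return points


def fit_hill(points: list[DoseResponsePoint]) -> HillFit:
    """Least-squares Hill fit of normalized peaks vs pH (maximum fixed at 1)."""
    if len(points) < 4:
        raise ValueError("need at least 4 points spanning the transition")
    ph = np.array([p.ph for p in points])
    y = np.array([p.normalized_peak for p in points])
    if y.max() < 0.6 or y.min() > 0.4:
        raise ValueError("no transition within the sampled pH range")
    # midpoint start: pH where response crosses 0.5
    order = np.argsort(ph)
    ph50_0 = float(np.interp(0.5, y[order][::-1], ph[order][::-1]))
    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        try:
            popt, _ = curve_fit(
                hill_model, ph, y, p0=[ph50_0, n0],
                bounds=([ph.min() - 2, 1e-3], [ph.max() + 2, 100.0]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((hill_model(ph, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("Hill fit failed to converge")
    rss, (ph50, n) = best
    return HillFit(ph50=float(ph50), hill_n=float(n), rss=rss)


# ---------------------------------------------------------------------------
# Sweep-series quantification (photomodulation protocols)
# ---------------------------------------------------------------------------

def sweep_series_peaks(
    sweeps: list[Sweep],
    window: tuple[int, int],
    n_baseline: int = 1,
) -> dict:
    """Peak and Iss/Ipeak trajectories across an ordered sweep series,
    peaks normalized to the mean of the first ``n_baseline`` sweeps."""
    if n_baseline < 1 or n_baseline > len(sweeps):
        raise ValueError("need at least one baseline sweep")
    peaks = np.array([_peak_in_window(sw, window)[1] for sw in sweeps])
    ref = float(np.mean(np.abs(peaks[:n_baseline])))
    ratios = []
    for sw in sweeps:
        try:
            ratios.append(iss_over_ipeak(sw, window))
        except ValueError:
            ratios.append(float("nan"))
    return {
        "normalized_peak": np.abs(peaks) / ref,
        "iss_over_ipeak": np.array(ratios),
    }
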