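"""Paired-pulse recovery-from-desensitization analysis.

The protocol: a 1.5 s conditioning acidification fully desensitizes the
channel population, a variable interval at rest pH lets some fraction
recover, and a test acidification reads out that fraction as the ratio of
test peak to conditioning peak.  The recovery time course is fit with

    I(t) = (1 - exp(-t/tau))**m          ("hh_power", default)
    I(t) = 1 - exp(-(t/tau)**m)          ("stretched_exp")

where ``tau`` is the recovery time constant and ``m`` a Hodgkin-Huxley-type
slope; both forms reduce to a mono-exponential at m = 1.  Wild-type-like
channels recover mono-exponentially (m near 1) over seconds, while fast
mutants require steep slopes (m up to ~10) over milliseconds, so fits are
multi-started over a broad (tau, m) grid to avoid m = 1 local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .sweeps import Sweep, SweepBlock

__all__ = [
    "RecoveryCurve",
    "RecoveryFit",
    "recovery_model",
    "measure_epoch_peak",
    "fraction_recovered",
    "fit_recovery",
    "summarize_fits",
    "tau_slope_correlation",
]

FORMS = ("hh_power", "stretched_exp")


@dataclass
class RecoveryCurve:
    interval: np.ndarray  # s, strictly increasing
    fraction: np.ndarray  # test peak / conditioning peak
    n_repeats_averaged: np.ndarray | None = None
    warn_no_peak: np.ndarray | None = None  # per-point flag, optional

    def __post_init__(self) -> None:
        self.interval = np.asarray(self.interval, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.interval.size != self.fraction.size:
            raise ValueError("interval and fraction must have equal length")
        if np.any(np.diff(self.interval) <= 0):
            raise ValueError("intervals must be strictly increasing")
        if self.n_repeats_averaged is None:
            self.n_repeats_averaged = np.ones(self.interval.size, dtype=int)


@dataclass
class RecoveryFit:
    tau: float  # s
    m: float
    form: str
    rss: float
    n_points: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.tau > 0 and self.m > 0):
            raise ValueError("tau and m must be positive")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return recovery_model(np.asarray(t, dtype=float), self.tau, self.m, self.form)


def recovery_model(t: np.ndarray, tau: float, m: float, form: str = "hh_power") -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if form == "hh_power":
        return (1.0 - np.exp(-t / tau)) ** m
    if form == "stretched_exp":
        with np.errstate(over="ignore"):  # (t/tau)**m may overflow to inf -> exp(-inf)=0
            return 1.0 - np.exp(-((t / tau) ** m))
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# Peak measurement
# ---------------------------------------------------------------------------

def measure_epoch_peak(
    sweep: Sweep,
    window: tuple[int, int],
    baseline_window: tuple[int, int],
    smooth_samples: int = 3,
) -> float:
    """Signed extremum of baseline-subtracted current within a window.

    Inward currents are negative, so the returned peak of an inward response
    is negative.  A short boxcar (default 3 samples) suppresses single-sample
    noise before the extremum search.
    """
    b0, b1 = baseline_window
    w0, w1 = window
    if not (0 <= b0 < b1 <= w0 < w1 <= sweep.n_samples):
        raise ValueError("baseline window must precede the epoch window")
    if smooth_samples < 1 or (w1 - w0) < smooth_samples:
        raise ValueError("window shorter than smoothing kernel")
    baseline = float(np.mean(sweep.current[b0:b1]))
    seg = sweep.current[w0:w1] - baseline
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        seg = np.convolve(seg, kernel, mode="same")
    idx = int(np.argmax(np.abs(seg)))
    return float(seg[idx])


def _epoch_to_window(sweep: Sweep, start: float, end: float) -> tuple[int, int]:
    dt = sweep.sample_interval
    i0 = max(0, int(round(start / dt)))
    i1 = min(sweep.n_samples, int(round(end / dt)))
    return i0, i1


def fraction_recovered(
    block: SweepBlock,
    noise_floor: float = 0.0,
    smooth_samples: int = 3,
) -> RecoveryCurve:
    """Per-sweep test/conditioning peak ratios, repeats at one interval averaged.

    Each sweep's protocol must carry labeled ``conditioning`` and ``test``
    epochs; the interval is the gap between conditioning end and test start.
    Sweeps whose conditioning peak does not clear ``noise_floor`` (absolute
    pA) are dropped.
    """
    protocol = block.protocol
    conds = protocol.by_label("conditioning")
    tests = protocol.by_label("test")
    if not conds or not tests:
        raise ValueError("protocol must define conditioning and test epochs")
    cond, test = conds[0], tests[0]
    interval = test.start - cond.end
    points: dict[float, list[float]] = {}
    for sw in block.sweeps:
        cw = _epoch_to_window(sw, cond.start, cond.end)
        tw = _epoch_to_window(sw, test.start, test.end)
        nb = max(2, int(round(0.05 / sw.sample_interval)))
        base = (max(0, cw[0] - nb), cw[0])
        cond_peak = measure_epoch_peak(sw, cw, base, smooth_samples)
        test_peak = measure_epoch_peak(sw, tw, base, smooth_samples)
        if abs(cond_peak) <= noise_floor:
            continue  # conditioning response lost in noise
        points.setdefault(interval, []).append(test_peak / cond_peak)
    if not points:
        raise ValueError("no sweep yielded a conditioning peak above the noise floor")
    intervals = np.array(sorted(points))
    fractions = np.array([np.mean(points[iv]) for iv in intervals])
    n_rep = np.array([len(points[iv]) for iv in intervals])
    return RecoveryCurve(interval=intervals, fraction=fractions, n_repeats_averaged=n_rep)


def merge_recovery_points(curves: list[RecoveryCurve]) -> RecoveryCurve:
    """Combine single-interval curves (one per paired-pulse block) into one
    curve, averaging repeats at identical intervals."""
    points: dict[float, list[float]] = {}
    for c in curves:
        for iv, fr, n in zip(c.interval, c.fraction, c.n_repeats_averaged):
            points.setdefault(float(iv), []).extend([float(fr)] * int(n))
    intervals = np.array(sorted(points))
    fractions = np.array([np.mean(points[iv]) for iv in intervals])
    n_rep = np.array([len(points[iv]) for iv in intervals])
    return RecoveryCurve(interval=intervals, fraction=fractions, n_repeats_averaged=n_rep)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_recovery(
    curve: RecoveryCurve,
    form: str = "hh_power",
    constrain_m_1: bool = False,
) -> RecoveryFit:
    """Nonlinear least-squares fit of the recovery time course.

    Multi-started over a decade grid of tau spanning the interval range and
    m in {0.5, 1, 2, 5, 10}; the lowest-RSS convergent solution wins.
    """
    t = curve.interval
    y = curve.fraction
    if t.size < 4:
        raise ValueError("need at least 4 points to fit recovery")
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")

    lo, hi = math.log10(t.min()), math.log10(t.max())
    tau_starts = [10.0 ** e for e in np.arange(math.floor(lo), math.ceil(hi) + 1)]
    m_starts = [1.0] if constrain_m_1 else [0.5, 1.0, 2.0, 5.0, 10.0]

    best: tuple[float, np.ndarray] | None = None
    attempts: list[dict] = []
    for tau0 in tau_starts:
        for m0 in m_starts:
            if constrain_m_1:
                def resid(p):
                    return recovery_model(t, math.exp(p[0]), 1.0, form) - y
                x0 = [math.log(tau0)]
            else:
                def resid(p):
                    return recovery_model(t, math.exp(p[0]), math.exp(p[1]), form) - y
                x0 = [math.log(tau0), math.log(m0)]
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=2000)
            except Exception as exc:  # pragma: no cover - scipy internal failures
                attempts.append({"tau0": tau0, "m0": m0, "error": str(exc)})
                continue
            rss = float(np.sum(sol.fun**2))
            attempts.append({"tau0": tau0, "m0": m0, "rss": rss, "success": bool(sol.success)})
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError(f"recovery fit failed from all starts: {attempts}")
    rss, x = best
    tau = math.exp(x[0])
    m = 1.0 if constrain_m_1 else math.exp(x[1])
    return RecoveryFit(
        tau=tau, m=m, form=form, rss=rss, n_points=int(t.size),
        diagnostics={"n_starts": len(tau_starts) * len(m_starts)},
    )


def summarize_fits(fits: list[RecoveryFit]) -> dict:
    """Mean and SEM of tau and m across per-patch fits (N = one patch)."""
    if not fits:
        raise ValueError("need at least one fit")
    taus = np.array([f.tau for f in fits])
    ms = np.array([f.m for f in fits])
    n = len(fits)

    def _sem(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    return {
        "tau_mean": float(taus.mean()),
        "tau_sem": _sem(taus),
        "m_mean": float(ms.mean()),
        "m_sem": _sem(ms),
        "n": n,
        "sem_defined": n > 1,
    }


def tau_slope_correlation(fits: list[RecoveryFit]) -> float:
    """Pearson correlation between log10(tau) and log10(m) across fits."""
    if len(fits) < 3:
        raise ValueError("need at least 3 fits")
    lt = np.log10([f.tau for f in fits])
    lm = np.log10([f.m for f in fits])
    if np.std(lt) == 0 or np.std(lm) == 0:
        raise ValueError("zero variance in tau or m")
    return float(np.corrcoef(lt, lm)[0, 1])
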