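# Methods

This note documents the models, estimators and numerical choices behind
`asickin`, and what the synthetic-data generators do and do not emulate.

## Data model and conventions

All analyses operate on `Sweep`/`SweepBlock` objects: uniformly sampled
current (pA) and stimulus-pH traces with patch metadata. Inward currents are
negative; every "peak" is the signed extremum of baseline-subtracted current
(baseline = mean over a window, default 50 ms, immediately before the
epoch). Index windows are 0-based and half-open. Two file dialects exist —
a `#key=value`-headed TSV (canonical for fixtures; lossless to 1e-9) and an
HDF5 container (bit-exact) — and both round-trip the stimulus protocol as
JSON metadata. Epoch boundaries are detected on the stimulus/command
channel with a threshold at 50 % of the step amplitude and a 5-sample
debounce; both are configurable. Command-based boundaries are an
approximation: real solution exchange at the patch lags the command by the
measured 250–500 µs transit, which the generators emulate but the detector
deliberately ignores.

## Recovery from desensitization

The paired-pulse read-out is the ratio of test-epoch to conditioning-epoch
peak, one point per sweep, repeats at the same interpulse interval averaged.
The interval is defined from conditioning end to test start. Two fit forms
are implemented:

* `hh_power` (default): `I(t) = (1 − e^(−t/τ))^m` — the classic
  Hodgkin–Huxley activation form; chosen as the default because the slope
  parameter is described in those terms in the electrophysiology literature
  this package serves.
* `stretched_exp`: `I(t) = 1 − e^(−(t/τ)^m)`.

Both reduce to a mono-exponential at m = 1 and are strictly increasing for
τ, m > 0. Generators and fitters always share one configured form; the test
suite round-trips both across τ ∈ [4 ms, 10 s] × m ∈ [0.7, 10] to 1 %.
Fits are nonlinear least squares in log-parameters, multi-started over a
decade grid of τ spanning the interval range crossed with
m ∈ {0.5, 1, 2, 5, 10}; single-start fits demonstrably fall into m = 1
local minima for steep (m ≈ 9–10) curves, which is why the multi-start is
not optional. Fractions are not constrained ≤ 1 (measured ratios can
slightly exceed 1; generated noisy fractions are clipped at 1.05), but the
fitted asymptote is fixed at 1. Per-patch fits are summarized as mean ±
SEM with n = patches; SEM at n = 1 is reported as 0 with a flag.

## Desensitization entry, sustained current, dose–response

Decay fits use `I(t) = offset + Σ aₖ e^(−t/τₖ)` (1 or 2 components, fast
component listed first, τ_des = dominant-amplitude component). The fit
window opens at the first post-peak sample where |I| falls below 95 % of the
peak — skipping the activation–desensitization cusp — and runs to the epoch
end; fits whose amplitude is negligible or whose τ reaches the window-length
bound are flagged rather than rejected. τ estimates are invariant to
current scaling and baseline offset. Rise times are 10–90 % crossings with
linear interpolation; steady state is the mean of the last 5 % of the
application epoch (the averaging window is a package choice; nothing in the
protocols pins it). Dose–response peaks are normalized by the mean of the
two flanking reference-pH responses, which cancels first-order rundown, and
fit with `I(pH) = 1/(1 + 10^{n (pH − pH50)})`. The orientation is chosen so
acidification increases the response — the alternative sign of the exponent
would make response fall with acidity, contradicting proton activation —
and the maximum is fixed at 1 (normalized data; no free maximum).

## Non-stationary fluctuation analysis

Sweep selection mimics experimental practice: the longest contiguous stretch
whose |peak| amplitudes satisfy max/min ≤ 1.10 is kept (the 10 % band is
interpreted as a max/min ratio; ties go to the earliest run), then sweeps
with spurious variance are removed by a robust z-score (median/MAD, default
threshold 5, iterated to convergence, ≤ 5 passes) on their
successive-sample difference variance. The ensemble variance is the
successive-sweep pairwise estimator `δ²ᵢ(t) = (Tᵢ₊₁(t) − Tᵢ(t))²/2`
averaged over the M − 1 pairs (the Heinemann–Conti convention); it is
unbiased for stationary noise and insensitive at first order to amplitude
drift that is locally linear across neighbouring sweeps, which is the point
of using it instead of deviations from the grand mean. Baseline variance is
the mean pairwise variance over the 50 ms before stimulation and is held
fixed in the fit (it is a measured additive term; a flag frees it).

Binning is uniform in |mean current| between baseline and peak over the
decay phase, which equalizes information per bin and corresponds to
progressively larger time bins along an exponential relaxation; empty bins
are dropped, and a peak/baseline SNR < 3 is an error. With the baseline
fixed, `σ²(I) = iI − I²/N + σ²_b` is linear in (i, 1/N) and solved by
unweighted linear least squares (whether bins should be weighted by
occupancy is an open choice; unweighted is recorded in the result
metadata). A non-positive N̂ is an error; data whose variance is still
rising at max |I| (peak P_open < 0.5, vertex beyond the data) fit fine but
carry a low-confidence flag. P_open uses the stable-stretch mean peak
current; conductance is `g [pS] = 1000 · i [pA] / (V_hold − E_rev) [mV]`,
with E_rev defaulting to 0 mV (configurable — the conversion, not the
estimate, depends on it). Extremum-based peak measurement is biased outward
by roughly σ_smoothed·√(2 ln n_window) under noise; the boxcar default
(3 samples) keeps this at a few percent for realistic SNR, and the test
suite asserts the analytic envelope rather than pretending the bias away.

## Kinetic schemes

A scheme is (states, conducting subset, per-pH rate matrices Q) with
off-diagonal rates ≥ 0 and rows summing to zero; pH dependence is a lookup
over the discrete levels the protocols use (no continuous proton-binding law
is asserted). Occupancies evolve as `p(t) = p₀ e^{Qt}` per constant-pH
segment, evaluated by eigen-decomposition; if the eigenvector matrix is
ill-conditioned (cond > 1e8) or defective the propagator falls back to
scipy's scaling-and-squaring `expm`, and the trajectory records that. The
segment-final occupancy is always chained exactly, so continuity across
epoch boundaries does not depend on the output grid. Steady states come
from the null space of Qᵀ after a strong-connectivity check that names the
disconnected components. The propagation is verified against a dense
`expm` oracle to 1e-8 and conserves total probability to 1e-10 across 1,000
random schemes.

Two default schemes ship in `schemes/default_schemes.yaml` (rates live in
config, not code, because no published rate table exists for this channel's
four-state behaviour): a linear R–O–D scheme in which desensitization is
entered from the open state, and a branching R–C–O–D scheme with a
protonated-closed state C from which the channel either opens or
desensitizes, plus a direct D→C recovery path. The branching scheme's rates
were calibrated once so that pH 5 desensitization proceeds with
τ ≈ 0.18 s and pH 8 recovery with τ ≈ 0.84 s — the wild-type values — with
activation and deprotonation fast (≥ 300 s⁻¹ and 5000 s⁻¹) so those steps
are not rate-limiting. The D→C rate at pH 5 (0.002 s⁻¹) is far smaller than
at pH 8 (1.19 s⁻¹), encoding the observed strong pH dependence of recovery
and keeping pH 5 desensitization essentially complete. `scan_recovery_rate`
multiplies one transition's rate at every pH level, recomputes the
deterministic recovery curve and the sustained current, and refits the
recovery form — reproducing the standard model prediction that a one-step
acceleration of recovery speeds τ_rec and raises Iss/Ipeak without
materially changing the slope m.

## Synthetic data generator

The generator emulates outside-out patch runs: N channels gating
independently, single-channel current i, white Gaussian baseline noise,
multiplicative cumulative per-sweep rundown `scale_s = Π_{k≤s}(1 − r + εₖ)`
(r default 0; the NSFA study conditions use r = 5e-4 with equal jitter, a
sub-10 %-per-run drift the stability filter must absorb), and pH commands
smoothed by an exponential whose 10–90 % transit equals the configured
solution-exchange time (default 350 µs, mid-range of the measured 250–500
µs). Channel stochasticity comes in two modes: exact event-driven Gillespie
simulation of the aggregate state-count process (statistically exact for
independent channels; pH switches at epoch boundaries; zero-order hold onto
the sample grid) or per-sample binomial thinning of a deterministic
open-probability time course. The binomial mode has no temporal
correlation between samples — adequate for variance-vs-mean analyses, which
are pointwise in time, but not for dwell-time statistics, which this package
does not attempt. Not emulated: amplifier/filter coloring of the noise
(the recordings' 10 kHz Bessel filter), capacitive transients, series
resistance artifacts, and real patch-to-patch heterogeneity. Passing tests
therefore validate estimator correctness under idealized noise, not
robustness to every instrumental artifact.

The NSFA study condition used throughout (drivers, acceptance) is a
200-sweep run, 100 channels, peak P_open 0.86, 10 pS at −60 mV
(i = −0.6 pA), 500 ms pH 5 application on a 10 kHz grid with 0.3 pA
baseline noise — sizes matching the stated recording practice (runs of
50–200 responses, filtered blocks of 50–100). Every generator is a pure
function of its arguments and a seed; per-sweep seeds are spawned from the
master seed, and pipeline stages derive their streams by hashing
(master seed, stage label) so adding stages never perturbs existing ones.

## Randomization statistics

The test statistic is the absolute difference of group means (recorded in
the result so alternatives can be added unambiguously). Sampled tests use
uniformly shuffled labels with the add-one convention
p = (exceedances + 1)/(iterations + 1), so p = 0 is never reported; the
exact enumerator (all C(nx+ny, nx) assignments, bounded at 1e6) reports the
raw exceedance fraction. At n = 5 vs 5 the smallest attainable exact
two-tailed p for this statistic is 2/252 ≈ 0.0079 — reported bounds smaller
than that must come from a different resampling unit, and the package
surfaces the floor alongside the sampled p. Ties are handled with a 1e-12
slack on the exceedance comparison. Type-I error at α = 0.05 is verified to
lie in [0.035, 0.065] over 2,000 Gaussian null datasets.

## Structure metrics

PDB I/O (including multi-model trajectories; highest-occupancy altloc kept)
is delegated to biotite; a plain (frame, atom, x, y, z) table reader covers
converted MD output, and native binary trajectory formats are deliberately
out of scope. Kabsch superposition is implemented directly (SVD with the
determinant correction that excludes reflections; collinear selections are
rejected) and cross-checked in tests against a brute-force rotation
optimizer. RMSD series superpose each frame on the fit selection and
measure over the measure selection, defaulting fit = measure — the local
linker alignment; RMSF superposes each frame's selection onto the first
frame, then measures fluctuation about the time-averaged positions (a
whole-selection external alignment can be disabled for pre-aligned input;
whether fluctuations should be computed after local or global alignment is
genuinely open, and local is the default here). χ dihedrals use the
standard four-atom torsion with the IUPAC sign convention, verified against
biotite (which computes in float32, bounding that comparison at ~1e-4°) and
against an independent float64 projection formula at 1e-9°. All metrics are
rigid-motion invariant to 1e-9.

## Problem sizes and determinism

The shipped drivers and checks use: 12–20 recovery points per curve
(log-spaced over 3 ms–30 s, the protocol's interval design), 1.5 s decay
traces at 10 kHz, 200-sweep NSFA blocks at 10 kHz, 1,000 random schemes for
the propagation oracle, 2,000 datasets for the type-I calibration at 999
iterations per test, and 50 small-sample cases for the sampled-vs-exact
comparison at 20,000 iterations — sizes chosen to give the comparisons
enough statistical resolution. All stochastic results are reproducible from
a single master seed.

## Known limitations

* No aggregated-Markov single-channel (dwell-time likelihood) fitting, no
  voltage dependence, no continuous-pH rate laws.
* The binomial ensemble mode is uncorrelated in time (see above).
* Eq-form ambiguity: both recovery forms are implemented, but analyses mix
  forms only explicitly, never silently; cross-form fits are a sensitivity
  check, not a default.
* The structure module assumes whole, unwrapped molecules; no periodic
  boundary handling.
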