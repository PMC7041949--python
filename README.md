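# asickin

Kinetics, fluctuation analysis and structural metrics for acid-sensing ion
channel (ASIC) desensitization studies.

ASICs are trimeric, sodium-selective channels activated by extracellular
acidification. During sustained low pH they desensitize — enter a
non-conducting, agonist-bound state — and recover only after the pH returns
toward rest. Mutations in the β11–12 linker of the extracellular palm domain
(Leu414 and its neighbours in chicken ASIC1) can accelerate both entry into
and exit from desensitization by orders of magnitude. Quantifying that
behaviour from fast-perfusion outside-out patch recordings requires a small
zoo of analyses; this package implements all of them as a tested library,
with a synthetic-data generator that emulates the recordings so every stage
can be validated against known ground truth:

- **Recovery from desensitization** (paired-pulse protocols). The fraction
  recovered after an interpulse interval *t* is fit with a
  Hodgkin–Huxley-type form
  `I(t) = (1 − e^(−t/τ))^m`
  (a stretched-exponential alternative `1 − e^(−(t/τ)^m)` is selectable);
  τ is the recovery time constant and m the slope, with m = 1 the
  mono-exponential case.
- **Desensitization entry kinetics**: exponential decay fits (τ_des),
  10–90 % rise times, fractional sustained current Iss/Ipeak and its fold
  change between pH values.
- **pH dose–response**: interleaved-reference normalization and Hill fits
  `I(pH) = 1 / (1 + 10^{n (pH − pH50)})`.
- **Non-stationary fluctuation analysis (NSFA)**. Sweep stability filtering
  (longest stretch with peaks within 10 %), artifact exclusion,
  successive-sweep pairwise variance `δ²ᵢ(t) = (Tᵢ₊₁(t) − Tᵢ(t))²/2`
  (insensitive to slow rundown), amplitude binning, and the
  current–variance parabola
  `σ²(I) = iI − I²/N + σ²_baseline`
  yielding single-channel current i, channel count N, peak open probability
  `P_open = |I_peak|/|iN|` and conductance `g = i/(V_hold − E_rev)`.
- **Markov kinetic schemes**: per-pH rate matrices propagated by spectral
  decomposition (`p(t) = p₀ e^{Qt}`) over piecewise-constant pH protocols,
  with deterministic paired-pulse simulations and microscopic-rate scans.
- **Stochastic patch simulation**: exact event-driven (Gillespie) channel
  ensembles or binomial thinning of a deterministic open-probability time
  course, plus Gaussian baseline noise, multiplicative rundown and finite
  solution-exchange (250–500 µs) smoothing of the pH command.
- **Randomization statistics**: two-tailed unpaired tests on the difference
  of group means (100,000 iterations, add-one p-value) with an exact
  enumeration oracle.
- **Structure/trajectory metrics**: Kabsch superposition, local-alignment
  RMSD series and two-reference state planes, per-residue RMSF, side-chain
  χ1–χ3 dihedrals, atom-pair distances with an H-bond cutoff report.

## Worked example

The numbered scripts under `analysis/` are thin drivers over the library;
each prints what it found and writes a table under `results/`. For example,
regenerating the construct panel's recovery curves from their fitted
parameters and refitting them:

```sh
$ python analysis/01_recovery_kinetics.py
fitted tau spans 2.7 ms - 0.84 s
WT / L414A recovery fold change: 210.0
log-tau vs log-m correlation across constructs: r = -0.98 (faster recoveries pair with steeper slopes)
wrote results/recovery_fits.tsv
```

The 210-fold acceleration is the ratio of the fitted recovery time constants
of the fastest mutant (τ = 4 ms, m = 9) and wild type (τ = 840 ms,
m = 0.96); the strong negative log–log correlation shows that faster
recoveries require steeper slopes. Running the NSFA pipeline on a simulated
200-sweep wild-type-like patch (100 channels, 10 pS, peak P_open 0.86):

```sh
$ python analysis/03_nsfa.py
sweeps kept after stability/artifact filtering: 151/200
single-channel current: -0.563 pA (truth -0.600)
channel count: 100.0 (truth 100)
peak open probability: 0.903 (truth 0.86)
conductance: 9.39 pS (truth 10)
```

and the four-state-model prediction that a one-step acceleration of the
microscopic recovery rate cannot reproduce the measured τ–m correlation:

```sh
$ python analysis/04_model_rate_scan.py
 multiplier  tau_rec_s  slope_m  iss_over_ipeak
        1.0   0.842184 0.996487        0.000773
       10.0   0.084889 0.982051        0.004304
      100.0   0.008636 0.915481        0.038398
tau_rec falls 98-fold; Iss/Ipeak rises 50-fold; slope m changes only 8.1%
```

A `asickin` command-line interface exposes the same stages
(`simulate`, `nsfa`, `recovery`, `kinetics`, `dose`, `stats`, `model`,
`structmetrics`, `fixtures`); see `asickin --help`.

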