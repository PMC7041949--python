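#!/usr/bin/env python
"""Recovery-from-desensitization round trips for the construct panel.

Generates noiseless paired-pulse recovery curves at the per-construct fitted
parameters (recovery time constant tau and Hodgkin-Huxley slope m) reported
for chicken ASIC1 wild type and the 414/hydrophobic-patch mutants, refits
each with the package's recovery-fit machinery, and tabulates the recovered
parameters plus the headline fold change between the fastest mutant and wild
type.  Writes results/recovery_fits.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from asickin.recovery import fit_recovery, tau_slope_correlation
from asickin.synth import generate_recovery_fractions

# (construct, tau_s, m) — per-patch mean fitted values for the pH 8
# interpulse condition
CONSTRUCTS = [
    ("WT", 0.840, 0.96),
    ("L414A", 0.004, 9.0),
    ("L414N", 0.0027, 11.0),
    ("L414F", 0.021, 3.4),
    ("L414Y", 0.029, 2.7),
    ("L414I", 0.145, 1.4),
    ("L281A", 0.025, 3.9),
    ("I306A", 0.135, 1.31),
    ("M364A", 0.140, 1.44),
    ("V368A", 0.520, 0.99),
]


def main() -> None:
    out_dir = Path("results")
    out_dir.mkdir(exist_ok=True)
    rows = []
    fits = []
    for name, tau, m in CONSTRUCTS:
        intervals = np.geomspace(max(3e-3, tau / 50), min(30.0, tau * 40), 12)
        curve = generate_recovery_fractions(tau, m, intervals)
        fit = fit_recovery(curve)
        fits.append(fit)
        rows.append({
            "construct": name, "tau_true_s": tau, "m_true": m,
            "tau_fit_s": fit.tau, "m_fit": fit.m, "rss": fit.rss,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "recovery_fits.tsv", sep="\t", index=False)

    wt = df.loc[df.construct == "WT", "tau_fit_s"].item()
    fastest = df.loc[df.construct == "L414A", "tau_fit_s"].item()
    r = tau_slope_correlation(fits)
    print(f"fitted tau spans {df.tau_fit_s.min()*1e3:.1f} ms - {df.tau_fit_s.max():.2f} s")
    print(f"WT / L414A recovery fold change: {wt / fastest:.1f}")
    print(f"log-tau vs log-m correlation across constructs: r = {r:.2f} "
          "(faster recoveries pair with steeper slopes)")
    print(f"wrote {out_dir / 'recovery_fits.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
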