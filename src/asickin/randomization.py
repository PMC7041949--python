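"""Unpaired two-tailed randomization tests and mean/SEM summaries.

Significance between groups of per-patch estimates is assessed by shuffling
group labels: the statistic is the absolute difference of group means, the
default 100,000 random label assignments mirror experimental practice, and
the reported p-value uses the add-one convention
p = (exceedances + 1) / (iterations + 1) so a sampled test never reports
zero.  An exact enumeration over all distinct label assignments is provided
as the oracle for small groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["RandomizationResult", "randomization_test", "exact_permutation_test", "mean_sem"]

_TIE_EPS = 1e-12


@dataclass
class RandomizationResult:
    p_value: float
    observed_stat: float
    n_iterations: int
    n_exceedances: int
    seed: int | None
    exact: bool
    statistic: str = "abs_mean_difference"


def _check_groups(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    return x, y


def randomization_test(
    x: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 100_000,
    seed: int | None = None,
) -> RandomizationResult:
    """Two-tailed sampled randomization test on |mean(x) - mean(y)|."""
    x, y = _check_groups(x, y)
    nx = x.size
    pooled = np.concatenate([x, y])
    observed = abs(x.mean() - y.mean())
    rng = np.random.default_rng(seed)
    total = pooled.sum()
    # Shuffle in manageable chunks to bound memory at large iteration counts.
    exceed = 0
    chunk = 20_000
    done = 0
    while done < n_iterations:
        k = min(chunk, n_iterations - done)
        mat = np.tile(pooled, (k, 1))
        mat = rng.permuted(mat, axis=1)
        sx = mat[:, :nx].sum(axis=1)
        stat = np.abs(sx / nx - (total - sx) / y.size)
        exceed += int(np.sum(stat >= observed - _TIE_EPS))
        done += k
    p = (exceed + 1) / (n_iterations + 1)
    return RandomizationResult(
        p_value=p, observed_stat=observed, n_iterations=n_iterations,
        n_exceedances=exceed, seed=seed, exact=False,
    )


def exact_permutation_test(x: np.ndarray, y: np.ndarray) -> RandomizationResult:
    """Exact two-tailed permutation test enumerating all C(nx+ny, nx)
    distinct label assignments (bounded at 1e6)."""
    x, y = _check_groups(x, y)
    nx, ny = x.size, y.size
    n_assign = math.comb(nx + ny, nx)
    if n_assign > 1_000_000:
        raise ValueError(
            f"{n_assign} assignments exceed the enumeration bound; use randomization_test"
        )
    pooled = np.concatenate([x, y])
    total = pooled.sum()
    observed = abs(x.mean() - y.mean())
    exceed = 0
    for idx in combinations(range(nx + ny), nx):
        sx = pooled[list(idx)].sum()
        stat = abs(sx / nx - (total - sx) / ny)
        if stat >= observed - _TIE_EPS:
            exceed += 1
    return RandomizationResult(
        p_value=exceed / n_assign, observed_stat=observed,
        n_iterations=n_assign, n_exceedances=exceed, seed=None, exact=True,
    )


def mean_sem(values: np.ndarray) -> dict:
    """Mean, SEM (sd/sqrt(n); reported 0 with a flag at n = 1) and n."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 1:
        raise ValueError("need at least one value")
    n = v.size
    sem = float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return {"mean": float(v.mean()), "sem": sem, "n": n, "sem_defined": n > 1}
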