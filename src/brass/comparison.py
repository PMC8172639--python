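"""Attribution of method differences: sign tests and Friedman tests.

Performance differences between measurement methods are attributed to single
steps of the measurement process (sample preparation P, signal detection D,
measurand M) by comparing pairs of methods that differ in exactly that step.
Paired higher/lower counts get an exact two-sided sign test; bias across all
methods (blocked by replicate, or vice versa) gets a tie-corrected Friedman
test with an optional exact within-block permutation null.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methods import Measurand, MethodID

__all__ = [
    "attribution_pairs",
    "sign_test",
    "FriedmanResult",
    "friedman_test",
    "bias_report",
]

logger = logging.getLogger(__name__)

#: Default measurand contrast for step-M attribution: protein vs labeled-RNA
#: fluorescence.  Estimated RNA counts are a conversion of RNA fluorescence,
#: not an independent split, so count-vs-fluorescence pairs are excluded by
#: default; pass ``measurand_contrast=None`` for the fully general rule.
DEFAULT_MEASURAND_CONTRAST = (Measurand.PROTEIN, Measurand.RNA_FLUORESCENCE)


def attribution_pairs(
    methods,
    step: str,
    measurand_contrast: tuple[Measurand, Measurand] | None = DEFAULT_MEASURAND_CONTRAST,
) -> list[tuple[MethodID, MethodID]]:
    """Unordered method pairs differing in exactly the named step ('P'/'D'/'M')."""
    if step not in ("P", "D", "M"):
        raise ValueError("step must be one of 'P', 'D', 'M'")
    pairs = []
    for a, b in itertools.combinations(sorted(set(methods)), 2):
        if a.differs_in(b) != (step,):
            continue
        if step == "M" and measurand_contrast is not None:
            if {a.measurand, b.measurand} != set(measurand_contrast):
                continue
        pairs.append((a, b))
    return pairs


def sign_test(n_pos: int, n_neg: int) -> float:
    """Exact two-sided sign-test p-value on non-tied paired counts.

    p = min(1, 2 * min(P(X <= min), P(X >= max))) for X ~ Binomial(N, 1/2)
    with N = n_pos + n_neg; N = 0 returns 1 by convention.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    n = n_pos + n_neg
    if n == 0:
        return 1.0
    lo, hi = min(n_pos, n_neg), max(n_pos, n_neg)
    p = 2.0 * min(stats.binom.cdf(lo, n, 0.5), stats.binom.sf(hi - 1, n, 0.5))
    return float(min(1.0, p))


@dataclass(frozen=True)
class FriedmanResult:
    """Tie-corrected Friedman test of consistent ordering across blocks."""

    primary_factor: str
    blocking_factor: str
    k: int
    n_blocks: int
    statistic: float
    p_value: float
    exact: bool = False


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-block midranks (blocks x k)."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:  # every value tied within every block
        return 0.0
    return float(numer / denom)


def friedman_test(
    values,
    primary: str = "method",
    blocking: str = "replicate",
    exact: bool = False,
    max_exact: int = 500_000,
) -> FriedmanResult:
    """Friedman test on a k x n matrix of estimates (treatments x blocks).

    ``values`` has one row per level of the primary factor and one column
    per block.  Blocks containing missing values are dropped with a warning.
    The p-value is from the chi-square approximation with k-1 df, or, with
    ``exact=True`` and a feasible enumeration ((k!)^n <= max_exact), from
    the exact permutation null of independent within-block rankings.
    """
    mat = np.asarray(values, dtype=float)
    if mat.ndim != 2:
        raise ValueError("values must be a 2-D (treatments x blocks) matrix")
    keep = ~np.isnan(mat).any(axis=0)
    if not keep.all():
        logger.warning("friedman_test: dropping %d incomplete block(s)", int((~keep).sum()))
    mat = mat[:, keep]
    k, n = mat.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 treatments and 2 complete blocks")

    ranks = np.apply_along_axis(stats.rankdata, 1, mat.T)  # blocks x k, midranks
    statistic = _friedman_statistic(ranks)
    use_exact = False
    if exact and math.factorial(k) ** n <= max_exact:
        use_exact = True
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        for combo in itertools.product(perms, repeat=n):
            perm_ranks = np.stack([ranks[i][list(combo[i])] for i in range(n)])
            total += 1
            if _friedman_statistic(perm_ranks) >= statistic - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.chi2.sf(statistic, k - 1))
    return FriedmanResult(
        primary_factor=primary,
        blocking_factor=blocking,
        k=k,
        n_blocks=n,
        statistic=statistic,
        p_value=float(max(min(p, 1.0), np.nextafter(0, 1))),
        exact=use_exact,
    )


def bias_report(
    hill_fits: pd.DataFrame,
    parameters=("offset", "amplitude", "k_half", "n"),
    exact: bool = False,
) -> pd.DataFrame:
    """Friedman p-values per parameter for method and replicate bias.

    ``hill_fits`` is long-format with columns method, replicate,
    normalization, parameter, estimate.  For each (parameter, normalization)
    the test runs twice: method as primary factor blocked by replicate, and
    replicate as primary blocked by method.  Rows that cannot be tested
    (too few complete blocks) are reported with NaN statistic/p rather than
    aborting the report.
    """
    required = {"method", "replicate", "normalization", "parameter", "estimate"}
    if not required.issubset(hill_fits.columns):
        raise ValueError(f"hill_fits must have columns {sorted(required)}")
    rows = []
    for (norm, param) in itertools.product(
        sorted(hill_fits["normalization"].unique()), parameters
    ):
        sub = hill_fits[(hill_fits["normalization"] == norm)
                        & (hill_fits["parameter"] == param)]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="method", columns="replicate",
                               values="estimate", aggfunc="first")
        for primary, blocking in (("method", "replicate"), ("replicate", "method")):
            mat = wide.to_numpy() if primary == "method" else wide.to_numpy().T
            row = {"parameter": param, "normalization": norm,
                   "primary_factor": primary, "blocking_factor": blocking}
            try:
                res = friedman_test(mat, primary=primary, blocking=blocking, exact=exact)
                row.update(k=res.k, n_blocks=res.n_blocks,
                           statistic=res.statistic, p_value=res.p_value)
            except ValueError as err:
                logger.warning("bias_report: %s/%s (%s primary): %s",
                               param, norm, primary, err)
                row.update(k=mat.shape[0], n_blocks=0,
                           statistic=np.nan, p_value=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
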