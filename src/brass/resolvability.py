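"""Resolvability of single-cell distributions via ROC AUC.

The AUC between the distributions measured at two stimulus levels is the
probability that a random cell from the higher-stimulus sample exceeds a
random cell from the lower-stimulus sample, counting ties as one half
(midrank convention).  0.5 means complete overlap (no resolvability), 1.0
complete separation in the expected direction, 0.0 complete separation in
the unexpected direction; values below 0.5 are reported as-is, never folded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .comparison import sign_test
from .events import CellEventTable
from .methods import MethodID

__all__ = ["compute_auc", "AUCProfile", "auc_profile", "pairwise_auc_table", "PairwiseAUCResult"]

logger = logging.getLogger(__name__)


def compute_auc(low, high) -> float:
    """AUC of ``high`` vs ``low``: [#(h > l) + 0.5 #(h = l)] / (n_h n_l).

    Computed from the rank-based Mann-Whitney U statistic with midranks,
    in O(n log n).
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValueError("both samples must be non-empty")
    u = mannwhitneyu(high, low, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (low.size * high.size)


@dataclass(frozen=True)
class AUCProfile:
    """Adjacent-pair AUC values over an ordered stimulus series."""

    method: MethodID
    replicate: int
    levels: tuple[float, ...]
    auc_adjacent: tuple[float, ...]  # NaN marks pairs touching a missing level
    average_auc: float

    def __post_init__(self) -> None:
        if len(self.auc_adjacent) != len(self.levels) - 1:
            raise ValueError("need one adjacent-pair AUC per consecutive level pair")
        vals = np.asarray(self.auc_adjacent, dtype=float)
        ok = vals[~np.isnan(vals)]
        if ((ok < 0) | (ok > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")


def auc_profile(tables, levels) -> AUCProfile:
    """Build the adjacent-pair AUC profile of one method/replicate.

    ``tables`` maps stimulus level -> :class:`CellEventTable` (or is an
    iterable of tables whose samples carry the level).  Pairs touching a
    missing level are recorded as NaN and excluded from the average, with a
    logged warning; the gap is never bridged.
    """
    levels = tuple(float(x) for x in levels)
    if len(levels) < 2:
        raise ValueError("need at least two stimulus levels")
    if list(levels) != sorted(set(levels)):
        raise ValueError("levels must be strictly increasing")
    if not isinstance(tables, dict):
        tables = {t.sample.iptg_umol_per_l: t for t in tables}
    first = next(iter(tables.values()))
    method, replicate = first.method, first.sample.replicate

    aucs = []
    for lo, hi in zip(levels[:-1], levels[1:]):
        if lo in tables and hi in tables:
            aucs.append(compute_auc(tables[lo].signal, tables[hi].signal))
        else:
            logger.warning(
                "missing level in %s replicate %s: pair (%s, %s) dropped",
                method.label, replicate, lo, hi,
            )
            aucs.append(np.nan)
    arr = np.asarray(aucs)
    avail = arr[~np.isnan(arr)]
    if avail.size == 0:
        raise ValueError("no adjacent pair has both levels present")
    return AUCProfile(
        method=method,
        replicate=replicate,
        levels=levels,
        auc_adjacent=tuple(aucs),
        average_auc=float(avail.mean()),
    )


@dataclass(frozen=True)
class PairwiseAUCResult:
    """Pairwise method comparison over matched (replicate, adjacent-pair) cells."""

    method_a: MethodID
    method_b: MethodID
    n_a_higher: int
    n_b_higher: int
    n_ties: int
    p_two_sided: float


def pairwise_auc_table(profiles_a, profiles_b) -> PairwiseAUCResult:
    """Count matched AUC cells where each method resolves better.

    Profiles are matched on (replicate, adjacent pair); NaN cells on either
    side are skipped.  Ties are excluded from the sign test but reported.
    """
    by_rep_a = {p.replicate: p for p in profiles_a}
    by_rep_b = {p.replicate: p for p in profiles_b}
    n_a = n_b = n_tie = 0
    matched = 0
    for rep in sorted(set(by_rep_a) & set(by_rep_b)):
        pa, pb = by_rep_a[rep], by_rep_b[rep]
        if pa.levels != pb.levels:
            raise ValueError("profiles must share the stimulus series")
        for va, vb in zip(pa.auc_adjacent, pb.auc_adjacent):
            if np.isnan(va) or np.isnan(vb):
                continue
            matched += 1
            if va > vb:
                n_a += 1
            elif vb > va:
                n_b += 1
            else:
                n_tie += 1
    if matched == 0:
        raise ValueError("no matched (replicate, pair) cells to compare")
    return PairwiseAUCResult(
        method_a=by_rep_a[min(by_rep_a)].method,
        method_b=by_rep_b[min(by_rep_b)].method,
        n_a_higher=n_a,
        n_b_higher=n_b,
        n_ties=n_tie,
        p_two_sided=sign_test(n_a, n_b),
    )
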