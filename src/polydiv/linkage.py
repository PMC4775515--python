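"""Linkage disequilibrium and recombination statistics.

Pairwise r^2 with Fisher exact tests and Bonferroni correction, Kelly's ZnS
(mean r^2 over eligible site pairs), and the Hudson-Kaplan minimum number of
recombination events Rm from four-gamete incompatibilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._matrix import biallelic_encoding, four_gamete_incompatible
from .alignment import Alignment

__all__ = ["LDResult", "RmResult", "pairwise_ld", "zns", "hudson_kaplan_rm"]


@dataclass
class LDPair:
    site_i: int  # 0-based alignment columns
    site_j: int
    r2: float
    exact_p: float
    significant_raw: bool
    significant_bonferroni: bool


@dataclass
class LDResult:
    pairs: list[LDPair] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def ZnS(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(np.mean([p.r2 for p in self.pairs]))

    @property
    def n_significant_raw(self) -> int:
        return sum(p.significant_raw for p in self.pairs)

    @property
    def n_significant_bonferroni(self) -> int:
        return sum(p.significant_bonferroni for p in self.pairs)


def _r2(code_i: np.ndarray, code_j: np.ndarray) -> tuple[float, np.ndarray]:
    """r^2 between two 0/1 coded sites (pairwise deletion) and the 2x2 table."""
    ok = (code_i >= 0) & (code_j >= 0)
    x, y = code_i[ok].astype(float), code_j[ok].astype(float)
    table = np.array(
        [
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ],
        dtype=int,
    )
    px, py = x.mean(), y.mean()
    denom = px * (1 - px) * py * (1 - py)
    if denom == 0:
        return float("nan"), table
    d = np.mean(x * y) - px * py
    return float(d * d / denom), table


def pairwise_ld(
    aln: Alignment,
    include_singletons: bool = False,
    alpha: float = 0.05,
) -> LDResult:
    """Pairwise LD over biallelic segregating sites.

    ``include_singletons=False`` (default) restricts pairs to informative
    sites (minor allele count >= 2); with ``True`` every biallelic
    segregating site enters the pair list, which reproduces the
    all-segregating-sites pair counts of the classical software. The exact
    test is a two-tailed Fisher test on the 2x2 haplotype count table;
    Bonferroni uses alpha / n_pairs.
    """
    min_minor = 1 if include_singletons else 2
    positions, code = biallelic_encoding(aln.matrix, min_minor=min_minor)
    if len(positions) < 2:
        warnings.warn("fewer than 2 eligible sites; empty LD result")
        return LDResult(alpha=alpha)
    result = LDResult(alpha=alpha)
    raw: list[tuple[int, int, float, float]] = []
    m = len(positions)
    for i in range(m):
        for j in range(i + 1, m):
            r2, table = _r2(code[:, i], code[:, j])
            _, p = stats.fisher_exact(table, alternative="two-sided")
            raw.append((positions[i], positions[j], r2, float(p)))
    n_pairs = len(raw)
    bonf = alpha / n_pairs
    for pi_, pj, r2, p in raw:
        result.pairs.append(
            LDPair(
                site_i=pi_,
                site_j=pj,
                r2=r2,
                exact_p=p,
                significant_raw=p < alpha,
                significant_bonferroni=p < bonf,
            )
        )
    return result


def zns(aln: Alignment, include_singletons: bool = False) -> float:
    """Kelly's ZnS: mean r^2 over eligible biallelic site pairs."""
    min_minor = 1 if include_singletons else 2
    positions, code = biallelic_encoding(aln.matrix, min_minor=min_minor)
    m = len(positions)
    if m < 2:
        return float("nan")
    vals = []
    for i in range(m):
        for j in range(i + 1, m):
            r2, _ = _r2(code[:, i], code[:, j])
            vals.append(r2)
    return float(np.nanmean(vals))


@dataclass
class RmResult:
    Rm: int
    incompatible_intervals: list[tuple[int, int]]  # 0-based column pairs


def hudson_kaplan_rm(aln: Alignment) -> RmResult:
    """Hudson & Kaplan (1985) minimum number of recombination events.

    Runs the four-gamete test on every pair of biallelic sites, then reduces
    the incompatible intervals to a maximal set of non-overlapping
    (disjoint, open) intervals; Rm is the size of that set.
    """
    positions, code = biallelic_encoding(aln.matrix, min_minor=2)
    m = len(positions)
    intervals: list[tuple[int, int]] = []
    for i in range(m):
        for j in range(i + 1, m):
            if four_gamete_incompatible(code[:, i], code[:, j]):
                intervals.append((positions[i], positions[j]))
    # Hudson-Kaplan reduction: greedy selection of disjoint open intervals
    chosen: list[tuple[int, int]] = []
    last_right = -1
    for left, right in sorted(intervals, key=lambda iv: iv[1]):
        if left >= last_right:  # open intervals (a,b): may share endpoints
            chosen.append((left, right))
            last_right = right
    return RmResult(Rm=len(chosen), incompatible_intervals=chosen)
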