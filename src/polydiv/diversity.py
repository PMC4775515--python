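"""Per-locus diversity and divergence estimators.

Implements the classical per-site summaries for a sample of aligned alleles
(S, Watterson's theta, nucleotide diversity pi, haplotype diversity Hd,
Tajima's D with the 1989 normalizing constants), Jukes-Cantor-corrected
between-group divergence with fixed-difference enumeration, Nei-Gojobori
(1986) synonymous/nonsynonymous site and difference counting, and sliding
window profiles of any of these statistics.

Missing-data conventions (see also :mod:`polydiv.alignment`):

* ``S`` counts polymorphic columns without gaps/N (complete deletion);
* pairwise statistics (pi, K) use pairwise deletion: each sequence pair is
  compared over the columns where both have a plain nucleotide, and the
  per-pair per-site distance is averaged over pairs;
* Tajima's D is computed on the gap/N-free columns so that its S and
  mean-pairwise-difference ingredients refer to the same sites.

Standard deviations use the no-recombination variance formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt

import numpy as np

from . import codon as _codon
from ._matrix import MISSING
from .alignment import Alignment, AlignmentError, classify_site, collapse_haplotypes, segregating_sites

__all__ = [
    "harmonic",
    "harmonic2",
    "watterson_theta",
    "nucleotide_diversity",
    "haplotype_diversity",
    "tajimas_d",
    "tajima_constants",
    "locus_summary",
    "jc_correct",
    "jc_divergence",
    "nei_gojobori_within",
    "nei_gojobori_between",
    "fixed_aa_replacements",
    "sliding_window",
    "LocusSummary",
    "DivergenceResult",
    "WindowProfile",
]


def harmonic(n: int) -> float:
    """a_{n-1} = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def harmonic2(n: int) -> float:
    """sum_{i=1}^{n-1} 1/i^2."""
    return sum(1.0 / i**2 for i in range(1, n))


# ---------------------------------------------------------------------------
# Core per-site summaries
# ---------------------------------------------------------------------------

def watterson_theta(n: int, S: int, L: int) -> tuple[float, float]:
    """Watterson's per-site theta and its (no-recombination) SD."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L <= 0:
        raise ValueError("need L > 0")
    a1 = harmonic(n)
    a2 = harmonic2(n)
    theta_locus = S / a1
    theta = theta_locus / L
    var_S = a1 * theta_locus + a2 * theta_locus**2
    sd = sqrt(var_S) / (a1 * L)
    return theta, sd


def _pair_diff_counts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (differences, compared sites) with pairwise deletion."""
    n = matrix.shape[0]
    good = ~np.isin(matrix, MISSING)
    diffs, comps = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ok = good[i] & good[j]
            comps.append(int(ok.sum()))
            diffs.append(int((matrix[i, ok] != matrix[j, ok]).sum()))
    return np.array(diffs), np.array(comps)


def nucleotide_diversity(aln: Alignment, deletion: str = "pairwise") -> float:
    """Per-site nucleotide diversity pi.

    ``deletion='pairwise'`` (default) averages per-pair per-site distances;
    ``deletion='complete'`` first drops every column with missing data.
    """
    if aln.n < 2:
        raise AlignmentError("need n >= 2")
    matrix = aln.matrix
    if deletion == "complete":
        keep = ~np.isin(matrix, MISSING).any(axis=0)
        matrix = matrix[:, keep]
    diffs, comps = _pair_diff_counts(matrix)
    valid = comps > 0
    if not valid.any():
        return 0.0
    return float(np.mean(diffs[valid] / comps[valid]))


def pi_standard_deviation(pi: float, n: int, L: int) -> float:
    """SD of per-site pi under no recombination (Tajima 1983/Nei 1987)."""
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    return sqrt(b1 * pi / L + b2 * pi**2)


def haplotype_diversity(aln: Alignment) -> tuple[float, float]:
    """Gene diversity Hd = n/(n-1) (1 - sum p_i^2) and its SD (Nei 1987)."""
    if aln.n < 2:
        raise AlignmentError("need n >= 2")
    n = aln.n
    counts = np.array([c for _, c in collapse_haplotypes(aln)], dtype=float)
    p = counts / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return hd, sqrt(max(var, 0.0))


def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989)."""
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D on the gap/N-free columns.

    Returns nan when undefined: S = 0, or n = 2 (pi and theta_w coincide
    identically, so the normalizing variance is zero).
    """
    if aln.n < 2:
        raise AlignmentError("need n >= 2")
    if aln.n == 2:
        return float("nan")
    keep = ~np.isin(aln.matrix, MISSING).any(axis=0)
    matrix = aln.matrix[:, keep]
    poly = np.array(
        [len({*matrix[:, j]}) > 1 for j in range(matrix.shape[1])], dtype=bool
    )
    S = int(poly.sum())
    if S == 0:
        return float("nan")
    diffs, comps = _pair_diff_counts(matrix)
    k_mean = float(np.mean(diffs))
    _ = comps
    a1 = harmonic(aln.n)
    e1, e2 = tajima_constants(aln.n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n = 3 has identically zero variance (k == 2S/3)
        return float("nan")
    return (k_mean - S / a1) / sqrt(var)


@dataclass
class LocusSummary:
    """One row of the per-locus per-species summary table."""

    name: str
    species: str
    n: int
    L: int
    S: int
    theta_w: float
    sd_theta_w: float
    pi: float
    sd_pi: float
    Hd: float
    sd_Hd: float
    tajima_D: float  # nan when S == 0

    def as_dict(self) -> dict:
        return {
            "locus": self.name,
            "species": self.species,
            "n": self.n,
            "L": self.L,
            "S": self.S,
            "theta_w": self.theta_w,
            "sd_theta_w": self.sd_theta_w,
            "pi": self.pi,
            "sd_pi": self.sd_pi,
            "Hd": self.Hd,
            "sd_Hd": self.sd_Hd,
            "tajima_D": self.tajima_D,
        }


def locus_summary(aln: Alignment, name: str = "", species: str = "") -> LocusSummary:
    table = segregating_sites(aln)
    S = table.S
    theta, sd_theta = watterson_theta(aln.n, S, aln.L)
    pi = nucleotide_diversity(aln)
    hd, sd_hd = haplotype_diversity(aln)
    d = tajimas_d(aln) if S > 0 else float("nan")
    return LocusSummary(
        name=name or aln.name,
        species=species,
        n=aln.n,
        L=aln.L,
        S=S,
        theta_w=theta,
        sd_theta_w=sd_theta,
        pi=pi,
        sd_pi=pi_standard_deviation(pi, aln.n, aln.L),
        Hd=hd,
        sd_Hd=sd_hd,
        tajima_D=d,
    )


# ---------------------------------------------------------------------------
# Between-group divergence
# ---------------------------------------------------------------------------

def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a p-distance."""
    if p >= 0.75:
        raise ValueError("JC undefined for p >= 0.75")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass
class FixedDifference:
    position: int  # 0-based column
    state_a: str
    state_b: str
    syn_class: str
    residue: int | None  # 1-based amino-acid position within the fragment
    aa_change: str | None  # e.g. "N63D"


@dataclass
class DivergenceResult:
    K_raw: float
    K_JC: float
    net_divergence: float  # Da = K_raw - mean within-group pi
    fixed_differences: list[FixedDifference] = field(default_factory=list)


def _between_pair_distance(ma: np.ndarray, mb: np.ndarray) -> float:
    good_a = ~np.isin(ma, MISSING)
    good_b = ~np.isin(mb, MISSING)
    dists = []
    for i in range(ma.shape[0]):
        for j in range(mb.shape[0]):
            ok = good_a[i] & good_b[j]
            m = int(ok.sum())
            if m:
                dists.append(float((ma[i, ok] != mb[j, ok]).sum()) / m)
    return float(np.mean(dists)) if dists else 0.0


def fixed_aa_replacements(
    group_a: Alignment, group_b: Alignment, table_id: int = 1
) -> list[tuple[int, str, str]]:
    """Amino-acid replacements fixed between two groups.

    Returns (1-based residue, aa in group a, aa in group b) for each codon
    position where both groups are monomorphic (over their clean codons) and
    the encoded amino acids differ.
    """
    out = []
    for ci in range(min(group_a.n_codons, group_b.n_codons)):
        aas_a = {
            _codon.translate_codon(group_a.codon_at(i, ci), table_id)
            for i in range(group_a.n)
            if _codon.is_clean(group_a.codon_at(i, ci))
        }
        aas_b = {
            _codon.translate_codon(group_b.codon_at(j, ci), table_id)
            for j in range(group_b.n)
            if _codon.is_clean(group_b.codon_at(j, ci))
        }
        if len(aas_a) == 1 and len(aas_b) == 1 and aas_a != aas_b:
            out.append((ci + 1, aas_a.pop(), aas_b.pop()))
    return out


def jc_divergence(
    group_a: Alignment, group_b: Alignment, table_id: int = 1
) -> DivergenceResult:
    """Mean between-group p-distance with Jukes-Cantor correction.

    Fixed differences are columns monomorphic within each group but carrying
    different states, classified syn/nonsyn from their codon context; the
    net divergence Da (K minus mean within-group diversity) is also reported.
    """
    if group_a.L != group_b.L:
        raise AlignmentError("groups must share alignment length")
    if group_a.n == 0 or group_b.n == 0:
        raise AlignmentError("groups must be non-empty")
    k_raw = _between_pair_distance(group_a.matrix, group_b.matrix)
    k_jc = jc_correct(k_raw)
    pi_a = nucleotide_diversity(group_a) if group_a.n > 1 else 0.0
    pi_b = nucleotide_diversity(group_b) if group_b.n > 1 else 0.0
    da = k_raw - (pi_a + pi_b) / 2.0

    aa_fixed = {r: (x, y) for r, x, y in fixed_aa_replacements(group_a, group_b, table_id)}
    fixed: list[FixedDifference] = []
    off = group_a.reading_frame_offset
    for pos in range(group_a.L):
        col_a = {s for s in group_a.matrix[:, pos] if s not in MISSING}
        col_b = {s for s in group_b.matrix[:, pos] if s not in MISSING}
        if len(col_a) == 1 and len(col_b) == 1 and col_a != col_b:
            merged = Alignment(
                labels=group_a.labels + [f"b::{l}" for l in group_b.labels],
                species=group_a.species + group_b.species,
                individuals=group_a.individuals + group_b.individuals,
                alleles=group_a.alleles + group_b.alleles,
                matrix=np.vstack([group_a.matrix, group_b.matrix]),
                reading_frame_offset=off,
            )
            cls = classify_site(merged, pos, table_id)
            residue = (pos - off) // 3 + 1 if pos >= off else None
            change = None
            if cls == "nonsynonymous" and residue in aa_fixed:
                x, y = aa_fixed[residue]
                change = f"{x}{residue}{y}"
            fixed.append(
                FixedDifference(pos, col_a.pop(), col_b.pop(), cls, residue, change)
            )
    return DivergenceResult(
        K_raw=k_raw, K_JC=k_jc, net_divergence=da, fixed_differences=fixed
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori synonymous / nonsynonymous statistics
# ---------------------------------------------------------------------------

def _pair_codon_stats(
    aln_a: Alignment, i: int, aln_b: Alignment, j: int, table_id: int
) -> tuple[float, float, float, float]:
    """(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs) for one pair."""
    s_sites = n_sites = s_diff = n_diff = 0.0
    for ci in range(min(aln_a.n_codons, aln_b.n_codons)):
        c1 = aln_a.codon_at(i, ci)
        c2 = aln_b.codon_at(j, ci)
        if not (_codon.is_clean(c1) and _codon.is_clean(c2)):
            continue
        if c1 in _codon.stop_codons(table_id) or c2 in _codon.stop_codons(table_id):
            raise AlignmentError(f"internal stop codon at codon {ci + 1}")
        s1, n1 = _codon.syn_nonsyn_sites(c1, table_id)
        s2, n2 = _codon.syn_nonsyn_sites(c2, table_id)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = _codon.pathway_differences(c1, c2, table_id)
        s_diff += sd
        n_diff += nd
    return s_sites, n_sites, s_diff, n_diff


@dataclass
class NeiGojoboriResult:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float  # per-synonymous-site p-distance
    pn: float  # per-nonsynonymous-site p-distance
    ds: float | None  # JC-corrected (None when undefined)
    dn: float | None


def _nei_gojobori_pairs(
    pairs: list[tuple[Alignment, int, Alignment, int]], table_id: int
) -> NeiGojoboriResult:
    acc = np.zeros(4)
    ps_list, pn_list = [], []
    for aln_a, i, aln_b, j in pairs:
        s_sites, n_sites, s_diff, n_diff = _pair_codon_stats(aln_a, i, aln_b, j, table_id)
        acc += (s_sites, n_sites, s_diff, n_diff)
        ps_list.append(s_diff / s_sites if s_sites else 0.0)
        pn_list.append(n_diff / n_sites if n_sites else 0.0)
    k = len(pairs)
    ps = float(np.mean(ps_list)) if ps_list else 0.0
    pn = float(np.mean(pn_list)) if pn_list else 0.0
    try:
        ds = jc_correct(ps)
    except ValueError:
        ds = None
    try:
        dn = jc_correct(pn)
    except ValueError:
        dn = None
    return NeiGojoboriResult(
        syn_sites=acc[0] / k if k else 0.0,
        nonsyn_sites=acc[1] / k if k else 0.0,
        syn_diffs=acc[2] / k if k else 0.0,
        nonsyn_diffs=acc[3] / k if k else 0.0,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
    )


def nei_gojobori_within(aln: Alignment, table_id: int = 1) -> NeiGojoboriResult:
    """pi_a (= pn) and pi_s (= ps) over all within-group pairs (uncorrected)."""
    if aln.n < 2:
        raise AlignmentError("need n >= 2")
    pairs = [
        (aln, i, aln, j) for i in range(aln.n) for j in range(i + 1, aln.n)
    ]
    return _nei_gojobori_pairs(pairs, table_id)


def nei_gojobori_between(
    group_a: Alignment, group_b: Alignment, table_id: int = 1
) -> NeiGojoboriResult:
    """Ka (= dn) and Ks (= ds) over all between-group pairs (JC-corrected)."""
    pairs = [
        (group_a, i, group_b, j)
        for i in range(group_a.n)
        for j in range(group_b.n)
    ]
    return _nei_gojobori_pairs(pairs, table_id)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

@dataclass
class WindowProfile:
    statistic: str
    window_bp: int
    step_bp: int
    midpoints: list[float]
    values: list[float]
    flags: list[str]  # "" or "zero-denominator" / "undefined"


def _window_slice(aln: Alignment, start: int, stop: int) -> Alignment:
    sub = aln.subset(range(aln.n))
    sub.matrix = aln.matrix[:, start:stop].copy()
    off = aln.reading_frame_offset
    # keep codon structure: shift offset so downstream codon indexing stays in frame
    shift = (3 - ((start - off) % 3)) % 3
    sub.reading_frame_offset = shift
    return sub


def sliding_window(
    statistic: str,
    window_bp: int,
    step_bp: int,
    aln: Alignment,
    other: Alignment | None = None,
    table_id: int = 1,
) -> WindowProfile:
    """Per-window recomputation of a statistic along the alignment.

    ``statistic`` is one of ``pi`` (within ``aln``), ``K`` (between ``aln``
    and ``other``), ``pia_pis`` (within) or ``ka_ks`` (between). Windows tile
    ``[0, L)`` at the given step; windows whose denominator vanishes (e.g.
    pi_s = 0) are flagged rather than dropped.
    """
    if window_bp > aln.L:
        raise ValueError("window larger than alignment")
    if step_bp < 1:
        raise ValueError("step must be >= 1")
    if statistic in ("K", "ka_ks") and other is None:
        raise ValueError(f"statistic {statistic!r} needs a second group")
    midpoints, values, flags = [], [], []
    start = 0
    while start < aln.L:
        stop = min(start + window_bp, aln.L)
        win = _window_slice(aln, start, stop)
        win_other = _window_slice(other, start, stop) if other is not None else None
        flag = ""
        try:
            if statistic == "pi":
                val = nucleotide_diversity(win)
            elif statistic == "K":
                val = _between_pair_distance(win.matrix, win_other.matrix)
            elif statistic == "pia_pis":
                ng = nei_gojobori_within(win, table_id)
                if ng.ps == 0.0:
                    val, flag = float("nan"), "zero-denominator"
                else:
                    val = ng.pn / ng.ps
            elif statistic == "ka_ks":
                ng = nei_gojobori_between(win, win_other, table_id)
                if ng.ps == 0.0:
                    val, flag = float("nan"), "zero-denominator"
                else:
                    val = ng.pn / ng.ps
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
        except AlignmentError:
            val, flag = float("nan"), "undefined"
        midpoints.append((start + stop) / 2.0)
        values.append(val)
        flags.append(flag)
        if stop == aln.L:
            break
        start += step_bp
    return WindowProfile(statistic, window_bp, step_bp, midpoints, values, flags)
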