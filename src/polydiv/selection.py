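"""Polymorphism-to-divergence selection inference.

McDonald-Kreitman 2x2 exact test, the multilocus maximum-likelihood HKA
model with per-locus selection coefficients and nested likelihood-ratio
tests, and the Levene/Haldane exact test for heterozygote excess.

ML-HKA model
------------
For locus *i* with polymorphism count ``S_i`` (infinite-sites compatible),
divergence count ``D_i``, length ``L_i``, sample size ``n_i`` and inheritance
scalar ``c_i`` (1 for nuclear, 0.25 for mtDNA by default), the likelihood is

    S_i ~ Poisson( k_i * c_i * theta_i * L_i * a_{n_i - 1} )
    D_i ~ Poisson( c_i * theta_i * L_i * (T + 1) )

with ``theta_i`` per site, ``T`` the species divergence in coalescent units
(the ``+ 1`` is the ancestral-polymorphism term, configurable), and ``k_i``
the selection coefficient multiplying the polymorphism expectation only
(k < 1: sweep-like polymorphism deficit; k > 1: balancing-selection excess).
The MLE profile over ``T`` is one-dimensional because, given ``T``, every
``theta_i`` (and each free ``k_i``) has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, lgamma, log

import numpy as np
from scipy import optimize, stats

from .alignment import Alignment, AlignmentError, segregating_sites
from .diversity import harmonic

__all__ = [
    "MKTable",
    "mk_counts",
    "mk_test",
    "heterozygote_excess_test",
    "LocusCounts",
    "HKAModel",
    "hka_loglik",
    "fit_mlhka",
    "LRTResult",
    "lrt",
]


# ---------------------------------------------------------------------------
# McDonald-Kreitman
# ---------------------------------------------------------------------------

@dataclass
class MKTable:
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    p_value: float = float("nan")
    #: neutrality index (Pn/Ps)/(Dn/Ds); None when undefined
    NI: float | None = None
    #: unrounded fractional counts from pathway-averaged site classification
    fractional: tuple[float, float, float, float] | None = None


def _classify_counts(aln: Alignment, table_id: int) -> tuple[float, float]:
    """(nonsyn, syn) fractional counts of segregating sites within ``aln``."""
    table = segregating_sites(aln, table_id)
    pn = ps = 0.0
    for cls, states in zip(table.syn_class, table.states):
        k = len(states) - 1  # minimum mutations at the column
        if cls == "nonsynonymous":
            pn += k
        elif cls == "synonymous":
            ps += k
    return pn, ps


def mk_counts(
    polymorphism: Alignment | list[Alignment],
    divergence_pair: tuple[Alignment, Alignment],
    table_id: int = 1,
) -> MKTable:
    """Build the MK 2x2 table.

    Polymorphic counts come from the segregating sites of the polymorphism
    source (one focal species by default; pass a list to pool several).
    Fixed counts come from columns monomorphic within each of the two groups
    but different between them, classified syn/nonsyn from codon context.
    """
    sources = polymorphism if isinstance(polymorphism, list) else [polymorphism]
    pn = ps = 0.0
    for src in sources:
        a, b = _classify_counts(src, table_id)
        pn += a
        ps += b
    from .diversity import jc_divergence  # local import to avoid cycle at module load

    div = jc_divergence(*divergence_pair, table_id=table_id)
    dn = sum(1 for f in div.fixed_differences if f.syn_class == "nonsynonymous")
    ds = sum(1 for f in div.fixed_differences if f.syn_class == "synonymous")
    tbl = MKTable(
        Pn=round(pn), Ps=round(ps), Dn=dn, Ds=ds, fractional=(pn, ps, float(dn), float(ds))
    )
    return tbl


def mk_test(
    polymorphism: Alignment | list[Alignment],
    divergence_pair: tuple[Alignment, Alignment],
    table_id: int = 1,
    alternative: str = "two-sided",
) -> MKTable:
    """McDonald-Kreitman exact test on the 2x2 (syn/nonsyn x poly/fixed) table.

    Two-tailed by summation of all tables with probability <= observed
    (scipy's Fisher convention). G-test style mid-p alternatives are not
    implemented; a one-sided p is available via ``alternative``.
    """
    tbl = mk_counts(polymorphism, divergence_pair, table_id)
    if (tbl.Pn + tbl.Ps == 0) and (tbl.Dn + tbl.Ds == 0):
        raise AlignmentError("degenerate table: no polymorphism and no divergence")
    if (tbl.Pn + tbl.Dn == 0) and (tbl.Ps + tbl.Ds == 0):
        raise AlignmentError("degenerate table: all counts zero")
    contingency = [[tbl.Pn, tbl.Dn], [tbl.Ps, tbl.Ds]]
    _, p = stats.fisher_exact(contingency, alternative=alternative)
    tbl.p_value = float(p)
    if tbl.Ps > 0 and tbl.Ds > 0 and tbl.Dn > 0:
        tbl.NI = (tbl.Pn / tbl.Ps) / (tbl.Dn / tbl.Ds)
    return tbl


# ---------------------------------------------------------------------------
# Heterozygote excess (Levene/Haldane exact)
# ---------------------------------------------------------------------------

def _log_levene(n_het: int, n_a: int, n: int) -> float:
    """log P(heterozygote count | allele count) under Hardy-Weinberg."""
    n_aa = (n_a - n_het) // 2
    n_bb = n - n_het - n_aa
    return (
        lgamma(n + 1)
        - lgamma(n_aa + 1)
        - lgamma(n_het + 1)
        - lgamma(n_bb + 1)
        + n_het * log(2.0)
        + lgamma(n_a + 1)
        + lgamma(2 * n - n_a + 1)
        - lgamma(2 * n + 1)
    )


def heterozygote_excess_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-sided exact p-value for heterozygote excess at a diallelic system.

    Conditions on the observed allele counts (Levene 1949) and sums the
    probabilities of all genotype configurations with at least as many
    heterozygotes as observed.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no individuals")
    n_a = 2 * n_AA + n_Aa  # count of allele A
    h_values = [h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)]
    logs = {h: _log_levene(h, n_a, n) for h in h_values}
    # normalize for numerical safety (the enumeration is exact up to rounding)
    mx = max(logs.values())
    z = sum(np.exp(v - mx) for v in logs.values())
    p = sum(np.exp(logs[h] - mx) for h in h_values if h >= n_Aa) / z
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Multilocus ML-HKA
# ---------------------------------------------------------------------------

@dataclass
class LocusCounts:
    """Per-locus sufficient statistics for the HKA likelihood."""

    name: str
    S: int  # polymorphism count (infinite-sites compatible)
    D: int  # divergence count
    L: int  # sites
    n: int  # alleles sampled
    c: float = 1.0  # inheritance scalar (0.25 for mtDNA)

    @property
    def a(self) -> float:
        return harmonic(self.n)

    @classmethod
    def from_alignments(
        cls,
        name: str,
        focal: Alignment,
        other: Alignment,
        c: float = 1.0,
    ) -> "LocusCounts":
        """S from the focal species, D as the count of fixed differences."""
        from .diversity import jc_divergence

        S = segregating_sites(focal).S
        D = len(jc_divergence(focal, other).fixed_differences)
        return cls(name=name, S=S, D=D, L=focal.L, n=focal.n, c=c)


@dataclass
class HKAModel:
    loci: list[LocusCounts]
    theta: dict[str, float]  # per-site theta_i
    T: float  # divergence time, coalescent units
    k: dict[str, float]  # selection coefficients (1.0 when fixed)
    free_k: frozenset[str]
    lnL: float
    ancestral_term: float = 1.0
    restart_spread: float = 0.0
    converged: bool = True

    @property
    def n_free_parameters(self) -> int:
        return len(self.loci) + 1 + len(self.free_k)


def hka_loglik(model: HKAModel) -> float:
    """Joint Poisson log-likelihood of (S_i, D_i) under the model."""
    lnl = 0.0
    for loc in model.loci:
        th = model.theta[loc.name]
        ki = model.k.get(loc.name, 1.0)
        rate_s = ki * loc.c * th * loc.L * loc.a
        rate_d = loc.c * th * loc.L * (model.T + model.ancestral_term)
        if rate_s < 0 or rate_d < 0:
            raise ValueError("non-positive rate")
        lnl += stats.poisson.logpmf(loc.S, max(rate_s, 1e-300))
        lnl += stats.poisson.logpmf(loc.D, max(rate_d, 1e-300))
    return float(lnl)


def _profile_lnl(
    T: float,
    loci: list[LocusCounts],
    free_k: frozenset[str],
    ancestral_term: float,
) -> tuple[float, dict[str, float], dict[str, float]]:
    """Maximized lnL over (theta_i, free k_i) at fixed T (closed form)."""
    lnl = 0.0
    thetas: dict[str, float] = {}
    ks: dict[str, float] = {}
    tiny = 1e-12
    for loc in loci:
        a, B = loc.a, T + ancestral_term
        if loc.name in free_k:
            theta = max(loc.D / (loc.c * loc.L * B), tiny)
            k = max(loc.S / (loc.c * theta * loc.L * a), tiny)
        else:
            theta = max((loc.S + loc.D) / (loc.c * loc.L * (a + B)), tiny)
            k = 1.0
        thetas[loc.name] = theta
        ks[loc.name] = k
        rate_s = k * loc.c * theta * loc.L * a
        rate_d = loc.c * theta * loc.L * B
        lnl += stats.poisson.logpmf(loc.S, max(rate_s, 1e-300))
        lnl += stats.poisson.logpmf(loc.D, max(rate_d, 1e-300))
    return float(lnl), thetas, ks


def fit_mlhka(
    loci: list[LocusCounts],
    free_k: set[str] | frozenset[str] = frozenset(),
    ancestral_term: float = 1.0,
    T_bounds: tuple[float, float] = (1e-6, 200.0),
    n_restarts: int = 3,
    tol: float = 1e-4,
) -> HKAModel:
    """Maximum-likelihood fit of the multilocus HKA model.

    Loci named in ``free_k`` get a free selection coefficient; the rest are
    fixed at k = 1. The optimization is a 1-D profile likelihood over T
    (every other parameter is closed-form given T), run from ``n_restarts``
    bracketing intervals; the spread of the restart optima is reported and
    the fit flagged non-converged when it exceeds ``tol``.
    """
    if len(loci) < 2:
        raise ValueError("need >= 2 loci")
    free = frozenset(free_k)
    unknown = free - {loc.name for loc in loci}
    if unknown:
        raise ValueError(f"free_k names not among loci: {sorted(unknown)}")

    def neg(T: float) -> float:
        return -_profile_lnl(T, loci, free, ancestral_term)[0]

    lo, hi = T_bounds
    # the profile is a deterministic 1-D function of T, so "restarts" are
    # log-spaced bracketing windows that jointly cover the whole range;
    # the winner is then polished locally
    edges = np.geomspace(lo, hi, n_restarts + 1)
    best = None
    for w in range(n_restarts):
        res = optimize.minimize_scalar(
            neg, bounds=(edges[w], edges[w + 1]), method="bounded"
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x)
    lnl, T_hat = best
    res = optimize.minimize_scalar(
        neg,
        bounds=(max(lo, T_hat / 3), min(hi, T_hat * 3 + 1.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    spread = float(abs(-res.fun - lnl))
    if -res.fun > lnl:
        lnl, T_hat = -res.fun, res.x
    lnl, thetas, ks = _profile_lnl(T_hat, loci, free, ancestral_term)
    return HKAModel(
        loci=loci,
        theta=thetas,
        T=float(T_hat),
        k=ks,
        free_k=free,
        lnL=lnl,
        ancestral_term=ancestral_term,
        restart_spread=spread,
        converged=spread <= max(tol, 1e-3),
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float


def lrt(null: HKAModel | float, alt: HKAModel | float, df: int | None = None) -> LRTResult:
    """Chi-square likelihood-ratio test of nested models.

    Accepts fitted :class:`HKAModel` objects (df inferred from the parameter
    counts) or raw log-likelihoods with an explicit ``df``.
    """
    lnl0 = null.lnL if isinstance(null, HKAModel) else float(null)
    lnl1 = alt.lnL if isinstance(alt, HKAModel) else float(alt)
    if df is None:
        if not (isinstance(null, HKAModel) and isinstance(alt, HKAModel)):
            raise ValueError("df required when passing raw log-likelihoods")
        df = alt.n_free_parameters - null.n_free_parameters
    if df <= 0:
        raise ValueError("alternative must have more free parameters")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -1e-6:
        raise ValueError(
            f"optimization failure: alt lnL {lnl1:.4f} below null {lnl0:.4f}"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(lnL_null=lnl0, lnL_alt=lnl1, statistic=stat, df=df, p_value=p)


def mk_exact_p_oracle(Pn: int, Ps: int, Dn: int, Ds: int) -> float:
    """Independent hypergeometric enumeration of the two-tailed exact p.

    Conditions on all margins of the 2x2 table and sums the probabilities of
    tables at most as probable as the observed one. Used as a brute-force
    oracle for :func:`mk_test` on small tables.
    """
    row1, row2 = Pn + Dn, Ps + Ds
    col1 = Pn + Ps
    ntot = row1 + row2

    def prob(a: int) -> float:
        # a = Pn cell; hypergeometric
        return comb(row1, a) * comb(row2, col1 - a) / comb(ntot, col1)

    amin = max(0, col1 - row2)
    amax = min(col1, row1)
    p_obs = prob(Pn)
    return float(
        sum(prob(a) for a in range(amin, amax + 1) if prob(a) <= p_obs * (1 + 1e-9))
    )
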