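"""Mismatch-distribution analysis and coalescent demographic model comparison.

Two independent lines of evidence about past population size:

* the pairwise mismatch spectrum, with closed-form expectations under
  constant size and under a sudden (stepwise) expansion, least-squares
  fitting of (theta0, theta1, tau), the R2 and raggedness statistics, and
  tau-based dating of the expansion;

* a Monte-Carlo coalescent likelihood of the observed site configuration
  under a model in which, at time T (units of 2N generations) in the past,
  an instantaneous burst of coalescent intensity of strength S compresses
  the genealogy — the shared-(T,S) version is a population bottleneck, the
  per-locus version a selective-sweep analogue — compared by likelihood
  ratio across three nested models: M1 constant size (one theta per locus),
  M2 shared bottleneck (+2 parameters), M3 per-locus sweep (+2 per locus).
  Two configuration summaries are implemented (full perfect-phylogeny
  importance sampling for small S; a stable (S, singleton-count) summary for
  the model comparison), and LRT thresholds can be calibrated by parametric
  bootstrap.

``theta`` in this module is the per-locus population mutation rate
(4N mu L) unless noted, matching the (0, 30] search range used for the
model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

import numpy as np
from scipy import optimize, special, stats

from .alignment import Alignment, AlignmentError, segregating_sites
from .simulate import Demography, genealogy_lengths, simulate_genealogy

__all__ = [
    "mismatch_observed",
    "mismatch_expected_constant",
    "mismatch_expected_expansion",
    "MismatchFit",
    "fit_expansion",
    "r2_statistic",
    "raggedness",
    "date_expansion",
    "exponential_growth_time",
    "segregating_sites_pmf",
    "contraction_loglik",
    "folded_sfs",
    "SiteConfig",
    "DemographicFit",
    "ThreeModelSettings",
    "ThreeModelResult",
    "fit_three_models",
    "calibrate_critical_values",
]


# ---------------------------------------------------------------------------
# Mismatch spectra
# ---------------------------------------------------------------------------

def pairwise_difference_counts(aln: Alignment) -> np.ndarray:
    """Raw pairwise difference counts (pairwise deletion) for all pairs."""
    if aln.n < 2:
        raise AlignmentError("need n >= 2")
    matrix = aln.matrix
    good = ~np.isin(matrix, ("N", "-"))
    out = []
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            ok = good[i] & good[j]
            out.append(int((matrix[i, ok] != matrix[j, ok]).sum()))
    return np.array(out)


def mismatch_observed(aln: Alignment, i_max: int | None = None) -> np.ndarray:
    """Normalized histogram of pairwise difference counts (classes 0..i_max)."""
    counts = pairwise_difference_counts(aln)
    top = int(counts.max()) if i_max is None else i_max
    hist = np.bincount(counts, minlength=top + 1)[: top + 1].astype(float)
    return hist / hist.sum()


def _geometric_spectrum(theta: float, i_max: int) -> np.ndarray:
    """F(i) = theta^i / (1+theta)^(i+1), the constant-size mismatch law."""
    if theta <= 0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    i = np.arange(i_max + 1)
    return np.exp(i * log(theta) - (i + 1) * log(1.0 + theta))


def mismatch_expected_constant(
    theta: float, i_max: int, normalize: bool = True
) -> np.ndarray:
    """Constant-size expectation, truncated at ``i_max``.

    With ``normalize`` the truncated vector is rescaled to sum to 1;
    without, the raw (infinite-support) probabilities are returned.
    """
    f = _geometric_spectrum(theta, i_max)
    return f / f.sum() if normalize else f


def mismatch_expected_expansion(
    theta0: float,
    theta1: float,
    tau: float,
    i_max: int,
    normalize: bool = True,
) -> np.ndarray:
    """Sudden-expansion mismatch expectation (Rogers-Harpending model).

    The population has present-day scaled diversity ``theta1`` back to
    ``tau`` units of mutational time, and ``theta0`` before. Pairs that
    coalesce in the recent epoch contribute a truncated geometric term;
    older pairs carry Poisson(tau) extra differences on top of a geometric
    ancestral spectrum:

        F(i) = F_eq(i; theta1) * P[Gamma(i+1, (theta1+1)/theta1) <= tau]
             + exp(-tau/theta1) * sum_j Pois(j; tau) F_eq(i-j; theta0)

    With ``tau = 0`` this reduces exactly to the constant-size spectrum at
    ``theta0`` (the ancestral diversity).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    i = np.arange(i_max + 1)
    if tau == 0:
        f = _geometric_spectrum(theta0, i_max)
        return f / f.sum() if normalize else f
    th1 = max(theta1, 1e-12)
    recent = _geometric_spectrum(th1, i_max) * stats.gamma.cdf(
        tau, a=i + 1, scale=th1 / (th1 + 1.0)
    )
    pois = stats.poisson.pmf(i, tau)
    anc = _geometric_spectrum(theta0, i_max)
    old = exp(-tau / th1) * np.convolve(pois, anc)[: i_max + 1]
    f = recent + old
    return f / f.sum() if normalize else f


def r2_statistic(aln: Alignment) -> float:
    """Ramos-Onsins & Rozas (2002) R2: singleton load vs mean diversity."""
    table = segregating_sites(aln)
    S = table.S_pairwise
    if S == 0:
        return float("nan")
    n = aln.n
    u = np.zeros(n)
    for pos, states in zip(table.positions, table.states):
        if len(states) != 2:
            continue
        (minor, cnt) = min(states.items(), key=lambda kv: kv[1])
        if cnt == 1:
            carrier = int(np.nonzero(aln.matrix[:, pos] == minor)[0][0])
            u[carrier] += 1
    k_mean = float(np.mean(pairwise_difference_counts(aln)))
    return float(np.sqrt(np.mean((u - k_mean / 2.0) ** 2)) / S)


def raggedness(spectrum: np.ndarray) -> float:
    """Harpending's raggedness r = sum of squared successive differences."""
    x = np.append(np.asarray(spectrum, dtype=float), 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchFit:
    observed: np.ndarray
    expected_constant: np.ndarray
    expected_expansion: np.ndarray
    tau: float
    theta0: float
    theta1: float
    R2: float
    raggedness: float
    sse_constant: float
    sse_expansion: float
    converged: bool = True


def fit_expansion(aln: Alignment, i_max: int | None = None) -> MismatchFit:
    """Least-squares fit of the sudden-expansion model to the spectrum.

    (theta0, theta1, tau) minimize the sum of squared deviations between the
    observed and expected spectra (theta1 >= theta0 enforced by
    parameterizing theta1 = theta0 + delta). The constant-size expectation
    uses theta = mean pairwise differences. R2 and raggedness are computed
    from the data.
    """
    obs = mismatch_observed(aln, i_max)
    top = len(obs) - 1
    k_mean = float(np.mean(pairwise_difference_counts(aln)))
    const = mismatch_expected_constant(max(k_mean, 1e-9), top)

    if np.argmax(obs) == 0 and obs[0] >= 0.999999:
        # monomorphic / point-mass-at-zero spectrum: tau = 0
        expansion = mismatch_expected_expansion(0.0, 0.0, 0.0, top)
        return MismatchFit(
            observed=obs,
            expected_constant=const,
            expected_expansion=expansion,
            tau=0.0,
            theta0=0.0,
            theta1=0.0,
            R2=r2_statistic(aln),
            raggedness=raggedness(obs),
            sse_constant=float(np.sum((obs - const) ** 2)),
            sse_expansion=float(np.sum((obs - expansion) ** 2)),
        )

    def residuals(params):
        th0, delta, tau = params
        f = mismatch_expected_expansion(th0, th0 + delta, tau, top)
        return f - obs

    x0 = np.array([min(0.5, k_mean / 4), max(k_mean * 5, 1.0), max(k_mean, 0.5)])
    res = optimize.least_squares(
        residuals,
        x0,
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-12,
    )
    th0, delta, tau = res.x
    expansion = mismatch_expected_expansion(th0, th0 + delta, tau, top)
    return MismatchFit(
        observed=obs,
        expected_constant=const,
        expected_expansion=expansion,
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th0 + delta),
        R2=r2_statistic(aln),
        raggedness=raggedness(obs),
        sse_constant=float(np.sum((obs - const) ** 2)),
        sse_expansion=float(np.sum((obs - expansion) ** 2)),
        converged=bool(res.success),
    )


def date_expansion(
    tau: float,
    substitution_rate: float,
    L: int,
    rate_is_pairwise: bool = False,
) -> float:
    """Years since expansion from tau.

    ``substitution_rate`` is per site per million years (e.g. 0.02 for
    2%/My). tau = 2 u t with u the per-locus per-year rate, so
    t = tau / (2 u); with ``rate_is_pairwise`` the printed rate already
    refers to a pair of diverging lineages and the factor 2 is dropped.
    """
    if substitution_rate <= 0 or L <= 0:
        raise ValueError("rate and L must be positive")
    u_per_year = substitution_rate * L / 1e6
    denom = u_per_year if rate_is_pairwise else 2.0 * u_per_year
    return tau / denom


def exponential_growth_time(theta_ratio: float, g: float) -> float:
    """Time (in 1/g units) satisfying theta_t = theta_0 exp(-g t).

    ``theta_ratio`` is theta_0 / theta_t (present over past); solves
    t = ln(theta_ratio) / g.
    """
    if theta_ratio <= 0 or g <= 0:
        raise ValueError("ratio and growth rate must be positive")
    return log(theta_ratio) / g


# ---------------------------------------------------------------------------
# Coalescent likelihood of the segregating-site count
# ---------------------------------------------------------------------------

def segregating_sites_pmf(k, n: int, theta: float) -> np.ndarray:
    """Exact P(S = k) under a constant-size coalescent (Tavare 1984).

    ``theta`` is per locus. Serves as the analytic oracle for the
    Monte-Carlo likelihood at S_event = 0 and as the fast M1 kernel check.
    """
    scalar = np.isscalar(k)
    k = np.atleast_1d(k).astype(int)
    out = np.zeros(len(k), dtype=float)
    for idx, kk in enumerate(k):
        total = 0.0
        for i in range(2, n + 1):
            total += (
                (-1) ** i
                * special.comb(n - 1, i - 1)
                * (i - 1)
                / (theta + i - 1)
                * (theta / (theta + i - 1)) ** kk
            )
        out[idx] = max(total, 0.0)
    return float(out[0]) if scalar else out


def _mc_lnl(
    S_obs: int,
    theta: float,
    lengths: np.ndarray,
    log_extra: np.ndarray | float = 0.0,
) -> tuple[float, float]:
    """(log-likelihood, MC standard error) of the data given genealogy draws.

    ``log_extra`` carries per-genealogy log-probability terms that do not
    depend on theta (the multinomial frequency-configuration factor).
    """
    mu = theta / 2.0 * lengths
    logw = stats.poisson.logpmf(S_obs, np.maximum(mu, 1e-300)) + log_extra
    m = special.logsumexp(logw) - log(len(lengths))
    w = np.exp(logw - m)  # weights relative to the mean (mean ~ 1)
    se = float(np.std(w) / np.sqrt(len(w)))
    return float(m), se


# -- site-configuration machinery -------------------------------------------

def folded_sfs(aln: Alignment) -> np.ndarray:
    """Folded site-frequency spectrum (minor-allele counts, classes 1..n//2).

    Only biallelic gap/N-free columns enter (run the infinite-sites filter
    first for homoplasic data).
    """
    table = segregating_sites(aln)
    n = aln.n
    xi = np.zeros(n // 2, dtype=int)
    for pos, states, biall, miss in zip(
        table.positions, table.states, table.biallelic, table.has_missing
    ):
        if not biall or miss:
            continue
        minor = min(states.values())
        xi[min(minor, n - minor) - 1] += 1
        _ = pos
    return xi


def _observed_clades(aln: Alignment) -> tuple[int, list[frozenset], np.ndarray]:
    """(n, clades, multiplicities) of the observed mutation partitions.

    Uses the complete (gap/N-free) biallelic columns; each column's minor
    allele defines the carriers of one mutation (majority polarization).
    After infinite-sites filtering these carrier sets form a laminar family.
    """
    from ._matrix import biallelic_encoding

    table = segregating_sites(aln)
    positions = [
        p
        for p, biall, miss in zip(table.positions, table.biallelic, table.has_missing)
        if biall and not miss
    ]
    _, code = biallelic_encoding(aln.matrix, positions=positions)
    n = aln.n
    counts: dict[frozenset, int] = {}
    for j in range(code.shape[1]):
        carriers = np.nonzero(code[:, j] == 1)[0]
        if len(carriers) > n / 2:  # defensive: encoding already uses minor=1
            carriers = np.nonzero(code[:, j] == 0)[0]
        clade = frozenset(int(x) for x in carriers)
        counts[clade] = counts.get(clade, 0) + 1
    clades = sorted(counts, key=len)
    for i, a in enumerate(clades):  # laminarity check
        for b in clades[i + 1 :]:
            if a & b and not a <= b:
                raise AlignmentError(
                    "site partitions are not tree-compatible; run "
                    "infinite_sites_filter first"
                )
    return n, clades, np.array([counts[c] for c in clades], dtype=float)


def _sample_constrained_topologies(
    n: int, clades: list[frozenset], size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Importance-sample coalescent topologies consistent with the perfect
    phylogeny defined by the observed mutation clades.

    Proposal: at each coalescence, a uniformly random pair among the pairs
    allowed by the (multifurcating) constraint tree; importance weight is
    prior/proposal = product over steps of allowed_pairs / C(k, 2).

    Returns (start_steps, end_steps, log_weights): for each draw and each
    clade (non-singleton clades first, then the n leaves), the merge-step
    indices between which a lineage subtends exactly that leaf set. Step 0
    is the present; step j is the j-th coalescence.
    """
    multi = [c for c in clades if len(c) > 1]
    m = len(multi)
    # constraint forest: parent = smallest strict superset (root = -1)
    parent_clade = []
    for i, c in enumerate(multi):
        parent = -1
        for j in range(i + 1, m):
            if c < multi[j]:
                parent = j
                break
        parent_clade.append(parent)
    # slots per node: node ids 0..m-1 are clades, m is the root
    slot_node = {}  # leaf or clade -> owning node
    for leaf in range(n):
        owner = m
        for j, c in enumerate(multi):
            if leaf in c:
                owner = j
                break
        slot_node[("leaf", leaf)] = owner
    for i in range(m):
        slot_node[("clade", i)] = parent_clade[i] if parent_clade[i] >= 0 else m

    n_pending0 = [0] * (m + 1)
    init_members: list[list] = [[] for _ in range(m + 1)]
    for slot, owner in slot_node.items():
        if slot[0] == "leaf":
            init_members[owner].append(slot[1])
        else:
            n_pending0[owner] += 1

    start = np.zeros((size, m + n), dtype=np.int32)
    end = np.zeros((size, m + n), dtype=np.int32)
    logw = np.zeros(size)
    log_c2 = np.log([k * (k - 1) / 2.0 for k in range(n, 1, -1)])
    for g in range(size):
        active = [list(x) for x in init_members]  # lineage ids per node
        pending = list(n_pending0)
        node_of = {}
        mark = {}  # lineage id -> column index in start/end
        for leaf in range(n):
            node_of[leaf] = slot_node[("leaf", leaf)]
            mark[leaf] = m + leaf
        nxt = n
        lw = 0.0
        for step in range(1, n):
            weights = [len(a) * (len(a) - 1) / 2.0 for a in active]
            total_allowed = sum(weights)
            lw += log(total_allowed) - log_c2[step - 1]
            r = rng.random() * total_allowed
            node = 0
            acc = 0.0
            for node, w in enumerate(weights):
                acc += w
                if r < acc:
                    break
            pool = active[node]
            i, j = rng.choice(len(pool), size=2, replace=False)
            u, v = pool[i], pool[j]
            for lin in (u, v):
                if lin in mark:
                    end[g, mark[lin]] = step
                    del mark[lin]
            new = nxt
            nxt += 1
            active[node] = [x for x in pool if x not in (u, v)] + [new]
            node_of[new] = node
            if len(active[node]) == 1 and pending[node] == 0 and node != m:
                # clade `node` completed: its lineage now subtends it exactly
                mark[new] = node
                start[g, node] = step
                p = slot_node[("clade", node)]
                active[p].append(new)
                active[node] = []
                pending[p] -= 1
                node_of[new] = p
        logw[g] = lw
        # the final lineage (root) is unmarked by construction
    return start, end, logw


@dataclass
class _ConfigMC:
    """Per-locus Monte-Carlo state shared across all (T, S) cells.

    Holds constrained-topology draws (importance-sampled against the
    perfect phylogeny of the observed configuration) plus the exponential
    intensity increments of the coalescence waiting times. Topology and
    times are independent under the coalescent, so the same draws are
    remapped through each candidate demography's time scale; the full
    likelihood of the observed site configuration is

        P(D | theta, demog) = E_G[ Pois(S; theta/2 L_G)
                                   * S!/prod m_c! * prod_c (l_c/L_G)^{m_c} ]

    with l_c the length of the branch(es) subtending exactly clade c.
    """

    name: str
    S: int
    n: int
    m: np.ndarray  # clade multiplicities (n_clades,)
    cols: np.ndarray  # column index per observed clade into start/end
    start: np.ndarray  # (G, m + n) merge-step indices
    end: np.ndarray
    log_w_topo: np.ndarray  # (G,)
    E: np.ndarray  # (G, n-1) intensity increments
    log_config_const: float

    @classmethod
    def from_alignment(
        cls, name: str, aln: Alignment, size: int, rng: np.random.Generator
    ) -> "_ConfigMC":
        n, clades, mult = _observed_clades(aln)
        multi = [c for c in clades if len(c) > 1]
        start, end, logw = _sample_constrained_topologies(n, multi, size, rng)
        cols = []
        for c in clades:
            if len(c) == 1:
                cols.append(len(multi) + next(iter(c)))
            else:
                cols.append(multi.index(c))
        ks = np.arange(n, 1, -1)
        rates = ks * (ks - 1) / 2.0
        E = rng.exponential(1.0 / rates, size=(size, n - 1))
        S = int(mult.sum())
        const = special.gammaln(S + 1) - special.gammaln(mult + 1).sum()
        return cls(
            name=name,
            S=S,
            n=n,
            m=mult,
            cols=np.array(cols, dtype=int),
            start=start,
            end=end,
            log_w_topo=logw,
            E=E,
            log_config_const=float(const),
        )

    def cell_weights(self, demog: Demography) -> tuple[np.ndarray, np.ndarray]:
        """(total lengths, theta-free log-weights) per genealogy draw."""
        u = np.cumsum(self.E, axis=1)
        real = demog.real_times(u.ravel()).reshape(u.shape)
        prev = np.hstack([np.zeros((real.shape[0], 1)), real[:, :-1]])
        ks = np.arange(self.n, 1, -1)
        total = ((real - prev) * ks).sum(axis=1)
        if self.S == 0:
            return total, self.log_w_topo.copy()
        T_full = np.hstack([np.zeros((real.shape[0], 1)), real])  # step -> time
        rows = np.arange(real.shape[0])[:, None]
        l_c = (
            np.take_along_axis(T_full, self.end[:, self.cols], axis=1)
            - np.take_along_axis(T_full, self.start[:, self.cols], axis=1)
        )
        with np.errstate(divide="ignore"):
            log_l = np.where(l_c > 0, np.log(np.maximum(l_c, 1e-300)), -np.inf)
        _ = rows
        logw = (
            self.log_w_topo
            + log_l @ self.m
            - self.S * np.log(np.maximum(total, 1e-300))
            + self.log_config_const
        )
        return total, logw


# -- singleton-summary machinery --------------------------------------------

@dataclass
class SiteConfig:
    """Lightweight per-locus data summary for the demographic likelihood:
    sample size, segregating-site count, and folded singleton count."""

    name: str
    n: int
    S: int
    n_singletons: int

    @classmethod
    def from_alignment(cls, aln: Alignment, name: str = "") -> "SiteConfig":
        xi = folded_sfs(aln)
        return cls(
            name=name or aln.name,
            n=aln.n,
            S=int(xi.sum()),
            n_singletons=int(xi[0]) if len(xi) else 0,
        )


def _topology_class_counts(
    n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Subtree-size histograms per coalescence interval for ``size`` random
    exchangeable topologies: C[g, k, s-1] = lineages subtending s leaves
    during the interval in which n-k lineages remain. Topology is
    independent of the time scale, so these counts are reused under every
    candidate demography.
    """
    C = np.zeros((size, n - 1, n - 1), dtype=np.int16)
    for g in range(size):
        sizes = [1] * n
        for k in range(n - 1):
            for s in sizes:
                C[g, k, s - 1] += 1
            i, j = rng.choice(len(sizes), size=2, replace=False)
            merged = sizes[i] + sizes[j]
            sizes = [x for idx, x in enumerate(sizes) if idx not in (i, j)]
            sizes.append(merged)
    return C


@dataclass
class _SingletonMC:
    """Monte-Carlo state for the (S, singleton count) summary likelihood.

    Conditionally on a genealogy, S is Poisson in the total length and the
    folded singleton count is binomial in the fraction of length on branches
    subtending 1 or n-1 leaves. The singleton fraction carries the
    star-tree signature of recent contractions while keeping the MC weights
    well-conditioned — the full site-configuration likelihood (see
    :class:`_ConfigMC`) is exact but its naive estimator degenerates beyond
    a handful of segregating sites.
    """

    config: SiteConfig
    C: np.ndarray  # (G, n-1, n-1) class counts
    E: np.ndarray  # (G, n-1) intensity increments

    @classmethod
    def build(cls, config: SiteConfig, size: int, rng: np.random.Generator):
        n = config.n
        C = _topology_class_counts(n, size, rng)
        ks = np.arange(n, 1, -1)
        E = rng.exponential(1.0 / (ks * (ks - 1) / 2.0), size=(size, n - 1))
        return cls(config=config, C=C, E=E)

    def cell_weights(self, demog: Demography) -> tuple[np.ndarray, np.ndarray]:
        """(total lengths, theta-free log-weights) per genealogy draw."""
        u = np.cumsum(self.E, axis=1)
        real = demog.real_times(u.ravel()).reshape(u.shape)
        prev = np.hstack([np.zeros((real.shape[0], 1)), real[:, :-1]])
        dur = real - prev
        class_len = np.einsum("gk,gks->gs", dur, self.C.astype(float))
        total = class_len.sum(axis=1)
        n, S = self.config.n, self.config.S
        if S == 0:
            return total, np.zeros(len(total))
        single = class_len[:, 0] + class_len[:, n - 2]
        p1 = np.clip(single / np.maximum(total, 1e-300), 1e-12, 1.0 - 1e-12)
        logw = stats.binom.logpmf(self.config.n_singletons, S, p1)
        return total, logw


def contraction_loglik(
    aln_or_S,
    theta: float,
    T_event: float,
    S_event: float,
    n_genealogy_samples: int = 20000,
    seed=None,
    n: int | None = None,
    summary: str | None = None,
) -> tuple[float, float]:
    """Monte-Carlo log-likelihood of the observed site configuration.

    The demography is constant-size with an instantaneous coalescence burst
    of strength ``S_event`` at time ``T_event`` (units of 2N generations);
    ``theta`` is per locus. Three data summaries are available:

    * ``'singletons'`` (default for alignments): the (S, folded singleton
      count) summary; stable importance weights at any S.
    * ``'config'``: the full site configuration, integrated by importance
      sampling over genealogies consistent with the data's perfect
      phylogeny. Exact, but the estimator needs a large sample budget
      beyond a handful of segregating sites — intended for small S.
    * ``'S'`` (default for a raw integer S with ``n``): the bare
      segregating-site count, comparable with the analytic
      :func:`segregating_sites_pmf` at S_event = 0.

    Returns (lnL, Monte-Carlo standard error of lnL).
    """
    if theta <= 0 or T_event < 0 or S_event < 0:
        raise ValueError("parameters must be non-negative (theta > 0)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    demog = (
        Demography.contraction(T_event, S_event)
        if S_event > 0
        else Demography.constant()
    )
    if isinstance(aln_or_S, Alignment):
        if aln_or_S.n < 3:
            raise AlignmentError("degenerate data: fewer than 3 sequences")
        summary = summary or "singletons"
        if summary == "config":
            mc = _ConfigMC.from_alignment("", aln_or_S, n_genealogy_samples, rng)
            lengths, logw = mc.cell_weights(demog)
            return _mc_lnl(mc.S, theta, lengths, logw)
        if summary == "singletons":
            smc = _SingletonMC.build(
                SiteConfig.from_alignment(aln_or_S), n_genealogy_samples, rng
            )
            lengths, logw = smc.cell_weights(demog)
            return _mc_lnl(smc.config.S, theta, lengths, logw)
        S_obs = segregating_sites(aln_or_S).S
        n = aln_or_S.n
    else:
        S_obs = int(aln_or_S)
        if n is None:
            raise ValueError("pass n when supplying a raw S count")
        if (summary or "S") != "S":
            raise ValueError(f"summary={summary!r} needs an Alignment")
    lengths = genealogy_lengths(n, demog, size=n_genealogy_samples, rng=rng)
    return _mc_lnl(S_obs, theta, lengths)


# ---------------------------------------------------------------------------
# Three-model comparison (M1 constant / M2 bottleneck / M3 sweep)
# ---------------------------------------------------------------------------

@dataclass
class ThreeModelSettings:
    T_grid: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.5, 2.5, 4.0)
    S_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    theta_bounds: tuple[float, float] = (1e-3, 30.0)
    n_genealogies: int = 1000
    seed: int = 0
    alpha: float = 0.05
    #: empirical critical values for the 2*dlnL statistics, keyed by
    #: "M2/M1" / "M3/M1" / "M3/M2"; when set they replace the chi-square
    #: thresholds in the model decision (see calibrate_critical_values)
    critical_values: dict[str, float] | None = None


@dataclass
class DemographicFit:
    model_id: str  # M1 | M2 | M3
    theta: dict[str, float]
    lnL: float
    lnL_per_locus: dict[str, float]
    n_params: int
    shared_TS: tuple[float, float] | None = None  # M2
    per_locus_TS: dict[str, tuple[float, float]] | None = None  # M3


@dataclass
class ThreeModelResult:
    fits: dict[str, DemographicFit]
    lrt: dict[str, tuple[float, int, float]]  # comparison -> (stat, df, p)
    alpha: float = 0.05
    critical_values: dict[str, float] | None = None

    def _significant(self, comparison: str) -> bool:
        stat, _, p = self.lrt[comparison]
        if self.critical_values is not None:
            return stat > self.critical_values[comparison]
        return p < self.alpha

    @property
    def best_model(self) -> str:
        """Decision rule: a sweep signal beyond any shared bottleneck picks
        M3; otherwise a shared departure picks M2; otherwise a departure of
        the sweep model from constant size picks M3; else M1.

        The chi-square thresholds are approximate for single-genealogy
        (no-recombination) loci with boundary parameters; empirical
        critical values from calibrate_critical_values are preferred.
        """
        if self._significant("M3/M2"):
            return "M3"
        if self._significant("M2/M1"):
            return "M2"
        if self._significant("M3/M1"):
            return "M3"
        return "M1"


def _profile_theta(
    S_obs: int,
    lengths: np.ndarray,
    bounds: tuple[float, float],
    log_extra: np.ndarray | float = 0.0,
) -> tuple[float, float]:
    """(max lnL, argmax theta) over theta for fixed genealogy draws."""

    def neg(log_th: float) -> float:
        return -_mc_lnl(S_obs, exp(log_th), lengths, log_extra)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(log(bounds[0]), log(bounds[1])), method="bounded"
    )
    return -float(res.fun), float(exp(res.x))


def fit_three_models(
    loci: dict[str, Alignment] | list[Alignment],
    settings: ThreeModelSettings | None = None,
) -> ThreeModelResult:
    """Fit and compare M1 / M2 / M3 on >= 2 infinite-sites-filtered loci.

    For every locus and every (T, S) cell of the grid, the per-locus theta
    is profiled out against shared Monte-Carlo genealogy draws. M1 is the
    S = 0 cell, M2 maximizes the summed profile over one shared cell, M3
    sums each locus's own best cell, so lnL(M3) >= lnL(M2) >= lnL(M1) holds
    exactly on the grid. LRT df are the parameter-count differences (chi2
    approximate because (T, S) sit on the boundary under the null).
    """
    st = settings or ThreeModelSettings()
    if isinstance(loci, list):
        loci = {
            getattr(x, "name", "") or f"locus{i + 1}": x for i, x in enumerate(loci)
        }
    if len(loci) < 2:
        raise ValueError("need >= 2 loci")
    names = list(loci)

    root = np.random.default_rng(st.seed)
    mcs = {}
    for name, item in loci.items():
        if isinstance(item, Alignment):
            if item.n < 3:
                raise AlignmentError(f"locus {name}: fewer than 3 sequences")
            config = SiteConfig.from_alignment(item, name)
        else:
            config = item
        mcs[name] = _SingletonMC.build(
            config, st.n_genealogies, np.random.default_rng(root.integers(2**63))
        )

    cells = [(T, S) for T in st.T_grid for S in st.S_grid]
    # profile lnL and theta per locus per cell; topology/time draws are shared
    # across cells (common random numbers), which makes the M1/M2/M3 nesting
    # inequalities exact on the grid
    prof: dict[str, dict[tuple[float, float], tuple[float, float]]] = {}
    for name in names:
        mc = mcs[name]
        prof[name] = {}
        for T, S_ev in cells:
            demog = (
                Demography.contraction(T, S_ev) if S_ev > 0 else Demography.constant()
            )
            lengths, logw = mc.cell_weights(demog)
            prof[name][(T, S_ev)] = _profile_theta(
                mc.config.S, lengths, st.theta_bounds, logw
            )

    null_cell = (st.T_grid[0], 0.0)

    # M1: constant size
    m1_per = {name: prof[name][null_cell][0] for name in names}
    m1 = DemographicFit(
        model_id="M1",
        theta={name: prof[name][null_cell][1] for name in names},
        lnL=sum(m1_per.values()),
        lnL_per_locus=m1_per,
        n_params=len(names),
    )

    # M2: one shared (T, S)
    best_cell, best_sum = null_cell, -np.inf
    for cell in cells:
        total = sum(prof[name][cell][0] for name in names)
        if total > best_sum:
            best_cell, best_sum = cell, total
    m2_per = {name: prof[name][best_cell][0] for name in names}
    m2 = DemographicFit(
        model_id="M2",
        theta={name: prof[name][best_cell][1] for name in names},
        lnL=best_sum,
        lnL_per_locus=m2_per,
        n_params=len(names) + 2,
        shared_TS=best_cell,
    )

    # M3: per-locus (T, S)
    m3_theta, m3_per, m3_TS = {}, {}, {}
    for name in names:
        cell = max(prof[name], key=lambda c: prof[name][c][0])
        m3_per[name] = prof[name][cell][0]
        m3_theta[name] = prof[name][cell][1]
        m3_TS[name] = cell
    m3 = DemographicFit(
        model_id="M3",
        theta=m3_theta,
        lnL=sum(m3_per.values()),
        lnL_per_locus=m3_per,
        n_params=3 * len(names),
        per_locus_TS=m3_TS,
    )

    def _lrt(l0: float, l1: float, df: int) -> tuple[float, int, float]:
        stat = max(2.0 * (l1 - l0), 0.0)
        return stat, df, float(stats.chi2.sf(stat, df))

    nl = len(names)
    lrt_table = {
        "M2/M1": _lrt(m1.lnL, m2.lnL, 2),
        "M3/M1": _lrt(m1.lnL, m3.lnL, 2 * nl),
        "M3/M2": _lrt(m2.lnL, m3.lnL, 2 * nl - 2),
    }
    return ThreeModelResult(
        fits={"M1": m1, "M2": m2, "M3": m3},
        lrt=lrt_table,
        alpha=st.alpha,
        critical_values=st.critical_values,
    )


def _simulate_site_config(
    name: str, n: int, theta_locus: float, rng: np.random.Generator
) -> SiteConfig:
    """One neutral constant-size (S, singleton) draw for calibration."""
    tree = simulate_genealogy(n, None, rng)
    bl = tree.branch_lengths()
    total = bl.sum()
    S = int(rng.poisson(theta_locus / 2.0 * total))
    if S == 0:
        return SiteConfig(name, n, 0, 0)
    under = tree.leaves_under()
    sizes = np.array([len(u) for u in under])
    single = bl[(sizes == 1) | (sizes == n - 1)].sum()
    x1 = int(rng.binomial(S, single / total))
    return SiteConfig(name, n, S, x1)


def calibrate_critical_values(
    loci,
    settings: ThreeModelSettings | None = None,
    n_null: int = 40,
    seed: int = 0,
) -> dict[str, float]:
    """Parametric-bootstrap critical values for the three-model LRTs.

    Simulates ``n_null`` neutral constant-size datasets matched to the
    observed loci (same sample sizes; theta at the per-locus Watterson
    estimate), refits the three models on each, and returns the empirical
    (1 - alpha) quantiles of the 2*dlnL statistics. Recommended over the
    chi-square thresholds: with a single non-recombining genealogy per
    locus the asymptotic approximation is unreliable.
    """
    from .diversity import harmonic

    st = settings or ThreeModelSettings()
    if isinstance(loci, list):
        loci = {
            getattr(x, "name", "") or f"locus{i + 1}": x for i, x in enumerate(loci)
        }
    configs = {
        name: (
            SiteConfig.from_alignment(item, name)
            if isinstance(item, Alignment)
            else item
        )
        for name, item in loci.items()
    }
    rng = np.random.default_rng(seed)
    stats_null = {"M2/M1": [], "M3/M1": [], "M3/M2": []}
    for b in range(n_null):
        null_loci = {}
        for name, cfg in configs.items():
            theta_locus = max(cfg.S, 1) / harmonic(cfg.n)
            null_loci[name] = _simulate_site_config(name, cfg.n, theta_locus, rng)
        sub = ThreeModelSettings(
            T_grid=st.T_grid,
            S_grid=st.S_grid,
            theta_bounds=st.theta_bounds,
            n_genealogies=st.n_genealogies,
            seed=int(rng.integers(2**31)),
            alpha=st.alpha,
        )
        res = fit_three_models(null_loci, sub)
        for key in stats_null:
            stats_null[key].append(res.lrt[key][0])
    return {
        key: float(np.quantile(vals, 1.0 - st.alpha))
        for key, vals in stats_null.items()
    }
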