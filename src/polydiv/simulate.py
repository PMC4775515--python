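"""Coalescent synthetic-data generator.

Produces codon-aware multilocus alignments for one or two sister species
under the scenarios the analysis pipeline must detect: constant size, sudden
expansion, shared bottleneck, locus-specific sweep (modeled as a private
instantaneous contraction or polymorphism thinning), and two ancient
balanced allelic classes.

Conventions
-----------
Time is measured in coalescent units of 2N generations. ``theta`` arguments
are per site (4N mu); the per-locus rate is ``theta * L`` and mutations fall
on the genealogy as a Poisson process of rate ``theta * L / 2`` per lineage
per unit time, so that ``E[S] = theta * L * a_{n-1}`` under constant size.

Mutations follow the infinite-sites model mapped onto a finite codon
sequence: each mutation takes a previously untouched position, chosen among
4-fold degenerate third positions (synonymous) with probability
``syn_fraction`` and among nonsynonymous-capable positions otherwise; no
internal stop codons are ever introduced. This keeps the analytic coalescent
expectations exact while producing alignments the full codon-aware pipeline
can ingest.

All randomness flows through ``numpy.random.Generator``; a fixed seed fixes
the output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import codon as _codon
from .alignment import Alignment

__all__ = [
    "Demography",
    "Tree",
    "ScenarioSpec",
    "simulate_genealogy",
    "genealogy_lengths",
    "drop_mutations",
    "simulate_alignment",
    "simulate_two_species",
    "simulate_balanced_lineages",
    "random_coding_sequence",
    "pair_genotypes",
]


# ---------------------------------------------------------------------------
# Demography: piecewise-constant sizes + instantaneous coalescence bursts
# ---------------------------------------------------------------------------

@dataclass
class Demography:
    """Size history as seen backward in time.

    ``epochs`` is a list of (start_time, relative_size): the population has
    the given relative size from that time (backward) until the next epoch
    start. ``events`` is a list of (time, added_intensity): at the given
    time, ``added_intensity`` units of extra coalescent intensity are
    compressed into an instant (an instantaneous bottleneck/sweep burst of
    strength S).
    """

    epochs: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(s <= 0 for _, s in self.epochs):
            raise ValueError("relative sizes must be positive")
        if any(t < 0 or s < 0 for t, s in self.events):
            raise ValueError("event times and strengths must be >= 0")
        self.events = sorted(self.events)

    @classmethod
    def constant(cls, size: float = 1.0) -> "Demography":
        return cls(epochs=[(0.0, size)])

    @classmethod
    def contraction(cls, T: float, S: float, size: float = 1.0) -> "Demography":
        """Instantaneous coalescence burst of strength S at time T."""
        return cls(epochs=[(0.0, size)], events=[(T, S)])

    @classmethod
    def sudden_expansion(cls, t: float, ratio: float) -> "Demography":
        """Size 1 from the present back to ``t``, then 1/ratio (ratio>1 grows)."""
        return cls(epochs=[(0.0, 1.0), (t, 1.0 / ratio)])

    def _size_at(self, t: float) -> float:
        size = self.epochs[0][1]
        for start, s in self.epochs:
            if start <= t:
                size = s
        return size

    def _segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-linear map intensity -> time.

        Returns arrays (u_start, t_start, slope): for u in the segment
        beginning at u_start, time = t_start + (u - u_start) * slope. Event
        bursts appear as zero-slope segments of width equal to their
        strength (intensity passes, time stands still).
        """
        u_starts = [0.0]
        t_starts = [0.0]
        slopes = [self._size_at(0.0)]
        # events at time zero absorb intensity immediately
        u = 0.0
        t_prev = 0.0
        breakpoints = sorted(
            {t for t, _ in self.epochs} | {t for t, _ in self.events}
        )
        for t in breakpoints:
            if t > t_prev:
                u += (t - t_prev) / self._size_at(t_prev)
                t_prev = t
            burst = sum(s for te, s in self.events if te == t)
            if burst > 0:
                u_starts.append(u)
                t_starts.append(t)
                slopes.append(0.0)
                u += burst
            u_starts.append(u)
            t_starts.append(t)
            slopes.append(self._size_at(t))
        return np.array(u_starts), np.array(t_starts), np.array(slopes)

    def real_times(self, u: np.ndarray) -> np.ndarray:
        """Map cumulative coalescent intensities to real times (vectorized)."""
        u_starts, t_starts, slopes = self._segments()
        u = np.asarray(u, dtype=float)
        idx = np.clip(
            np.searchsorted(u_starts, u, side="right") - 1, 0, len(u_starts) - 1
        )
        return t_starts[idx] + np.maximum(u - u_starts[idx], 0.0) * slopes[idx]


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Binary coalescent genealogy: nodes 0..n-1 are leaves."""

    parent: np.ndarray  # parent index per node, -1 at root
    time: np.ndarray  # node times (real time, units of 2N)
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def leaves_under(self) -> list[np.ndarray]:
        """Leaf-index array below each node."""
        sets: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for leaf in range(self.n_leaves):
            sets[leaf].add(leaf)
        order = np.argsort(self.time)
        for v in order:
            p = self.parent[v]
            if p >= 0:
                sets[p] |= sets[v]
        return [np.array(sorted(s), dtype=int) for s in sets]

    def pairwise_times(self) -> np.ndarray:
        """Coalescence time for every leaf pair (condensed order)."""
        under = self.leaves_under()
        n = self.n_leaves
        tmat = np.zeros((n, n))
        order = np.argsort(self.time)
        for v in order:
            leaves = under[v]
            if len(leaves) < 2:
                continue
            sub = np.ix_(leaves, leaves)
            mask = tmat[sub] == 0.0
            block = tmat[sub]
            block[mask] = self.time[v]
            tmat[sub] = block
        np.fill_diagonal(tmat, 0.0)
        iu = np.triu_indices(n, 1)
        return tmat[iu]


def _coalesce_intensities(n: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative intensities of the n-1 coalescence events."""
    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    return np.cumsum(rng.exponential(1.0 / rates))


def simulate_genealogy(
    n: int,
    demography: Demography | None = None,
    seed=None,
) -> Tree:
    """Exchangeable n-coalescent under the given size history."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    demography = demography or Demography.constant()
    times = demography.real_times(_coalesce_intensities(n, rng))
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    nxt = n
    for t in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active[i] = nxt
        del active[j]
        nxt += 1
    return Tree(parent=parent, time=node_time, n_leaves=n)


def genealogy_lengths(
    n: int,
    demography: Demography | None = None,
    size: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Total branch lengths of ``size`` independent genealogies (vectorized).

    Used by the Monte-Carlo coalescent likelihood, where only the total tree
    length matters for the distribution of the segregating-site count.
    """
    rng = rng or np.random.default_rng()
    demography = demography or Demography.constant()
    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    intervals = rng.exponential(1.0 / rates, size=(size, n - 1))
    u = np.cumsum(intervals, axis=1)
    real = demography.real_times(u.ravel()).reshape(u.shape)
    prev = np.hstack([np.zeros((size, 1)), real[:, :-1]])
    return ((real - prev) * ks).sum(axis=1)


# ---------------------------------------------------------------------------
# Mutation dropping (infinite sites on a codon sequence)
# ---------------------------------------------------------------------------

def random_coding_sequence(
    L: int, rng: np.random.Generator, table_id: int = 1, offset: int = 0
) -> str:
    """Random sequence of length L whose in-frame codons are stop-free."""
    stops = _codon.stop_codons(table_id)
    codons = [c for c in (a + b + c_ for a in "ACGT" for b in "ACGT" for c_ in "ACGT") if c not in stops]
    head = "".join(rng.choice(list("ACGT"), size=offset))
    n_codons = (L - offset) // 3
    body = "".join(rng.choice(codons, size=n_codons))
    tail_len = L - offset - 3 * n_codons
    tail = "".join(rng.choice(list("ACGT"), size=tail_len))
    return head + body + tail


def _mutation_pools(
    seq: str, offset: int, table_id: int
) -> tuple[list[tuple[int, list[str]]], list[tuple[int, list[str]]]]:
    """(synonymous, nonsynonymous) pools of (position, valid target bases)."""
    stops = _codon.stop_codons(table_id)
    syn_pool, nonsyn_pool = [], []
    n_codons = (len(seq) - offset) // 3
    for ci in range(n_codons):
        start = offset + 3 * ci
        cdn = seq[start : start + 3]
        for pos_in in range(3):
            pos = start + pos_in
            syn_targets, nonsyn_targets = [], []
            for b in "ACGT":
                if b == seq[pos]:
                    continue
                alt = cdn[:pos_in] + b + cdn[pos_in + 1 :]
                if alt in stops:
                    continue
                if _codon.translate_codon(alt, table_id) == _codon.translate_codon(
                    cdn, table_id
                ):
                    syn_targets.append(b)
                else:
                    nonsyn_targets.append(b)
            if len(syn_targets) == 3:  # 4-fold degenerate position
                syn_pool.append((pos, syn_targets))
            elif nonsyn_targets:
                nonsyn_pool.append((pos, nonsyn_targets))
    return syn_pool, nonsyn_pool


def drop_mutations(
    tree: Tree,
    theta: float,
    L: int,
    rng: np.random.Generator | None = None,
    syn_fraction: float = 0.7,
    reading_frame_offset: int = 0,
    table_id: int = 1,
    branch_rate_scale: np.ndarray | None = None,
    ancestral: str | None = None,
    labels: list[str] | None = None,
    species: list[str] | None = None,
) -> Alignment:
    """Drop infinite-sites mutations on a genealogy and emit an alignment.

    ``theta`` is per site; the Poisson mutation count has mean
    ``theta * L / 2 * total_branch_length`` (optionally modulated per branch
    by ``branch_rate_scale``, used for polymorphism thinning/inflation in
    sweep and balancing scenarios).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = rng or np.random.default_rng()
    bl = tree.branch_lengths()
    if branch_rate_scale is not None:
        bl = bl * branch_rate_scale
    rate = theta * L / 2.0 * bl.sum()
    n_mut = rng.poisson(rate)
    anc = ancestral or random_coding_sequence(L, rng, table_id, reading_frame_offset)
    syn_pool, nonsyn_pool = _mutation_pools(anc, reading_frame_offset, table_id)
    rng.shuffle(syn_pool)
    rng.shuffle(nonsyn_pool)
    under = tree.leaves_under()
    n = tree.n_leaves
    matrix = np.array([list(anc)] * n, dtype="<U1")
    probs = bl / bl.sum() if bl.sum() > 0 else None
    for _ in range(n_mut):
        if probs is None:
            break
        branch = rng.choice(tree.n_nodes, p=probs)
        want_syn = rng.random() < syn_fraction
        pool = syn_pool if want_syn else nonsyn_pool
        if not pool:
            pool = nonsyn_pool if want_syn else syn_pool
        if not pool:
            raise ValueError("L too small: mutation site pool exhausted")
        pos, targets = pool.pop()
        matrix[under[branch], pos] = rng.choice(targets)
    labels = labels or [f"sim{i + 1}_1" for i in range(n)]
    species = species or ["sim"] * n
    return Alignment(
        labels=labels,
        species=species,
        individuals=[lbl.split("_")[0] for lbl in labels],
        alleles=[1] * n,
        matrix=matrix,
        reading_frame_offset=reading_frame_offset,
    )


def simulate_alignment(
    n: int,
    L: int,
    theta: float,
    demography: Demography | None = None,
    seed=None,
    syn_fraction: float = 0.7,
    table_id: int = 1,
) -> Alignment:
    """One-species constant/bottleneck/expansion sample in one call."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = simulate_genealogy(n, demography, rng)
    return drop_mutations(
        tree, theta, L, rng, syn_fraction=syn_fraction, table_id=table_id
    )


# ---------------------------------------------------------------------------
# Two-species isolation model
# ---------------------------------------------------------------------------

def _coalesce_until(
    active: list[int],
    t0: float,
    t_max: float,
    parent: np.ndarray,
    node_time: np.ndarray,
    next_node: int,
    rng: np.random.Generator,
    size: float = 1.0,
) -> tuple[list[int], int, float]:
    """Coalesce ``active`` lineages from t0 forward (backward in time) until
    t_max (or MRCA); returns (remaining lineages, next node id, time)."""
    t = t0
    while len(active) > 1:
        k = len(active)
        wait = rng.exponential(size / (k * (k - 1) / 2.0))
        if t + wait > t_max:
            return active, next_node, t_max
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        node_time[next_node] = t
        active[i] = next_node
        del active[j]
        next_node += 1
    return active, next_node, t


def simulate_two_species_tree(
    n_a: int, n_b: int, split_T: float, rng: np.random.Generator
) -> tuple[Tree, np.ndarray]:
    """Isolation-model genealogy; returns (tree, species code 0/1 per leaf)."""
    if split_T <= 0:
        raise ValueError("species_split_T must be > 0")
    n = n_a + n_b
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    nxt = n
    act_a, nxt, _ = _coalesce_until(
        list(range(n_a)), 0.0, split_T, parent, node_time, nxt, rng
    )
    act_b, nxt, _ = _coalesce_until(
        list(range(n_a, n)), 0.0, split_T, parent, node_time, nxt, rng
    )
    merged = act_a + act_b
    merged, nxt, _ = _coalesce_until(
        merged, split_T, np.inf, parent, node_time, nxt, rng
    )
    used = nxt
    return (
        Tree(parent=parent[:used], time=node_time[:used], n_leaves=n),
        np.array([0] * n_a + [1] * n_b),
    )


def _branch_scales(
    tree: Tree, species_code: np.ndarray, scale_a: float, scale_b: float
) -> np.ndarray:
    """Per-branch rate multipliers scaling each species' private polymorphism.

    A branch whose descendant leaves are a proper, single-species subset
    produces within-species polymorphism; those branches get that species'
    scale factor. Branches feeding fixed differences are left untouched.
    """
    under = tree.leaves_under()
    n_a = int((species_code == 0).sum())
    n_b = int((species_code == 1).sum())
    scales = np.ones(tree.n_nodes)
    for v in range(tree.n_nodes):
        leaves = under[v]
        if len(leaves) == 0 or tree.parent[v] < 0:
            continue
        sp = set(species_code[leaves])
        if sp == {0} and len(leaves) < n_a:
            scales[v] = scale_a
        elif sp == {1} and len(leaves) < n_b:
            scales[v] = scale_b
    return scales


@dataclass
class ScenarioSpec:
    """Declarative multilocus two-species scenario (JSON-serializable)."""

    n_per_species: int = 20
    L: int = 600
    theta: list[float] = field(default_factory=lambda: [0.01])
    species_split_T: float = 5.0
    syn_fraction: float = 0.7
    seed: int = 0
    #: per-locus polymorphism scaling (species_a_scale, species_b_scale);
    #: 1.0 = neutral, <1 emulates a sweep, >1 a balanced-lineage excess
    polymorphism_scale: list[tuple[float, float]] | None = None
    table_id: int = 1

    def manifest(self) -> str:
        return json.dumps(self.__dict__, default=list, sort_keys=True, indent=1)


def simulate_two_species(spec: ScenarioSpec) -> list[tuple[Alignment, Alignment]]:
    """Per-locus (species A, species B) alignment pairs under the scenario."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_species
    out = []
    scales = spec.polymorphism_scale or [(1.0, 1.0)] * len(spec.theta)
    for locus, theta in enumerate(spec.theta):
        tree, code = simulate_two_species_tree(n, n, spec.species_split_T, rng)
        sc_a, sc_b = scales[locus]
        branch_scale = _branch_scales(tree, code, sc_a, sc_b)
        labels = [f"EC{i + 1:02d}_All1" for i in range(n)] + [
            f"ES{i + 1:02d}_All1" for i in range(n)
        ]
        species = ["Euc"] * n + ["Eus"] * n
        aln = drop_mutations(
            tree,
            theta,
            spec.L,
            rng,
            syn_fraction=spec.syn_fraction,
            table_id=spec.table_id,
            branch_rate_scale=branch_scale,
            labels=labels,
            species=species,
        )
        aln.name = f"locus{locus + 1}"
        parts = aln.by_species()
        out.append((parts["Euc"], parts["Eus"]))
    return out


# ---------------------------------------------------------------------------
# Two balanced allelic classes (structured coalescent)
# ---------------------------------------------------------------------------

def simulate_balanced_lineages(
    n_per_class: int,
    L: int,
    theta: float,
    exchange_rate: float,
    seed=None,
    syn_fraction: float = 0.7,
    table_id: int = 1,
) -> tuple[Alignment, np.ndarray]:
    """Structured coalescent with two allelic classes of equal frequency.

    ``exchange_rate`` is the per-lineage class-exchange rate in units of 2N
    generations; small values produce two deeply diverged allelic clades with
    intermediate-frequency linked variants (positive Tajima's D, bimodal
    mismatch spectrum). Returns (alignment, class code per sequence).
    """
    if exchange_rate < 0:
        raise ValueError("exchange rate must be >= 0")
    m = max(exchange_rate, 1e-9)  # m=0 would never find a common ancestor
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 2 * n_per_class
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    deme = {i: (0 if i < n_per_class else 1) for i in range(n)}
    active = list(range(n))
    nxt = n
    t = 0.0
    while len(active) > 1:
        k0 = [v for v in active if deme[v] == 0]
        k1 = [v for v in active if deme[v] == 1]
        # each class holds half the population: pair rate within a class of
        # relative size 1/2 is C(k,2) / (1/2)
        r_coal0 = len(k0) * (len(k0) - 1)  # = C(k,2)/0.5
        r_coal1 = len(k1) * (len(k1) - 1)
        r_mig = m * len(active)
        total = r_coal0 + r_coal1 + r_mig
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < r_coal0 or u < r_coal0 + r_coal1:
            pool = k0 if u < r_coal0 else k1
            a, b = rng.choice(pool, size=2, replace=False)
            parent[a] = parent[b] = nxt
            node_time[nxt] = t
            deme[nxt] = deme[a]
            active = [v for v in active if v not in (a, b)] + [nxt]
            nxt += 1
        else:
            v = active[rng.integers(len(active))]
            deme[v] = 1 - deme[v]
    tree = Tree(parent=parent[:nxt], time=node_time[:nxt], n_leaves=n)
    labels = [f"BL{i + 1:02d}_All1" for i in range(n)]
    aln = drop_mutations(
        tree,
        theta,
        L,
        rng,
        syn_fraction=syn_fraction,
        table_id=table_id,
        labels=labels,
        species=["sim"] * n,
    )
    return aln, np.array([0] * n_per_class + [1] * n_per_class)


def pair_genotypes(
    class_code: np.ndarray, het_fraction: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw diploid genotype counts pairing alleles across/within classes.

    With probability ``het_fraction`` an individual pairs one allele from
    each class (heterozygote at the class-diagnostic system); otherwise both
    alleles come from the same (random) class. Returns (n_AA, n_Aa, n_aa).
    """
    n = len(class_code) // 2
    n_het = int(rng.binomial(n, het_fraction))
    n_hom = n - n_het
    n_aa_hom = int(rng.binomial(n_hom, 0.5))
    return n_hom - n_aa_hom, n_het, n_aa_hom
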