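import numpy as np
import pytest

from polydiv.alignment import segregating_sites
from polydiv.diversity import harmonic, jc_divergence, nei_gojobori_within, nucleotide_diversity, tajimas_d
from polydiv.selection import heterozygote_excess_test
from polydiv.simulate import (
    Demography,
    ScenarioSpec,
    drop_mutations,
    genealogy_lengths,
    pair_genotypes,
    random_coding_sequence,
    simulate_alignment,
    simulate_balanced_lineages,
    simulate_genealogy,
    simulate_two_species,
)


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

def test_pairwise_coalescence_time_n2():
    lens = genealogy_lengths(2, None, size=20000, rng=np.random.default_rng(1))
    # total length of an n=2 tree is 2 * T2; E[T2] = 1 in units of 2N
    assert np.mean(lens) / 2 == pytest.approx(1.0, rel=0.05)


def test_total_length_n20():
    lens = genealogy_lengths(20, None, size=20000, rng=np.random.default_rng(2))
    assert np.mean(lens) == pytest.approx(2 * harmonic(20), rel=0.02)


def test_tmrca_limit():
    rng = np.random.default_rng(3)
    tm = [simulate_genealogy(16, None, rng).tmrca() for _ in range(2000)]
    assert np.mean(tm) == pytest.approx(2 * (1 - 1 / 16), rel=0.05)


def test_bottleneck_collapses_pairwise_time_variance():
    rng = np.random.default_rng(4)
    strong = Demography.contraction(0.1, 50.0)
    var_b = np.var(
        np.concatenate(
            [simulate_genealogy(10, strong, rng).pairwise_times() for _ in range(150)]
        )
    )
    var_c = np.var(
        np.concatenate(
            [simulate_genealogy(10, None, rng).pairwise_times() for _ in range(150)]
        )
    )
    assert var_b < var_c / 5  # near-star genealogies


def test_expansion_shortens_deep_branches():
    rng = np.random.default_rng(5)
    d = Demography.sudden_expansion(t=0.2, ratio=100)
    tm = np.mean([simulate_genealogy(10, d, rng).tmrca() for _ in range(400)])
    tm_const = np.mean([simulate_genealogy(10, None, rng).tmrca() for _ in range(400)])
    assert tm < tm_const


# ---------------------------------------------------------------------------
# mutation dropping
# ---------------------------------------------------------------------------

def test_theta_zero_monomorphic():
    aln = simulate_alignment(8, 300, 0.0, seed=1)
    assert segregating_sites(aln).S == 0


def test_expected_segregating_sites():
    """E[S] = theta_locus * a_{n-1} within 3% (lengths exact, 10^4 draws)."""
    n, L, theta = 20, 600, 0.01
    lens = genealogy_lengths(n, None, size=10000, rng=np.random.default_rng(6))
    # E[S | tree] = theta*L/2 * total length; Poisson noise is mean-preserving
    es = np.mean(theta * L / 2.0 * lens)
    assert es == pytest.approx(theta * L * harmonic(n), rel=0.03)


def test_realized_S_matches_watterson_expectation():
    n, L, theta = 15, 600, 0.01
    rng = np.random.default_rng(7)
    S = [segregating_sites(simulate_alignment(n, L, theta, seed=rng)).S for _ in range(300)]
    assert np.mean(S) == pytest.approx(theta * L * harmonic(n), rel=0.08)


def test_syn_fraction_one_kills_nonsynonymous_diversity():
    rng = np.random.default_rng(8)
    for _ in range(5):
        aln = simulate_alignment(8, 450, 0.02, seed=rng, syn_fraction=1.0)
        assert nei_gojobori_within(aln).pn == 0.0


def test_no_internal_stops_in_output():
    from polydiv import codon as cd

    aln = simulate_alignment(10, 300, 0.05, seed=9)
    for i in range(aln.n):
        for ci in range(aln.n_codons):
            assert aln.codon_at(i, ci) not in cd.stop_codons(1)


def test_mutation_pool_exhaustion_raises():
    tree = simulate_genealogy(10, None, np.random.default_rng(10))
    with pytest.raises(ValueError, match="L too small"):
        drop_mutations(tree, 50.0, 9, np.random.default_rng(0))


def test_random_coding_sequence_stop_free():
    from polydiv import codon as cd

    seq = random_coding_sequence(120, np.random.default_rng(11))
    for ci in range(40):
        assert seq[3 * ci : 3 * ci + 3] not in cd.stop_codons(1)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_full_determinism_under_seed(tmp_path):
    spec = ScenarioSpec(n_per_species=6, L=120, theta=[0.01, 0.02], seed=99)
    p1 = simulate_two_species(spec)
    p2 = simulate_two_species(spec)
    for (a1, b1), (a2, b2) in zip(p1, p2):
        assert [a1.sequence(i) for i in range(a1.n)] == [
            a2.sequence(i) for i in range(a2.n)
        ]
        assert [b1.sequence(i) for i in range(b1.n)] == [
            b2.sequence(i) for i in range(b2.n)
        ]
    f1, f2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    p1[0][0].to_fasta(f1)
    p2[0][0].to_fasta(f2)
    assert f1.read_bytes() == f2.read_bytes()


# ---------------------------------------------------------------------------
# two-species model
# ---------------------------------------------------------------------------

def test_tiny_split_leaves_no_fixed_differences():
    fixed = []
    for r in range(10):
        spec = ScenarioSpec(
            n_per_species=8, L=300, theta=[0.01], species_split_T=1e-6, seed=200 + r
        )
        (a, b), = simulate_two_species(spec)
        fixed.append(len(jc_divergence(a, b).fixed_differences))
    assert np.mean(fixed) < 1.0


def test_divergence_grows_with_split_depth():
    k = {}
    for T in (1.0, 8.0):
        spec = ScenarioSpec(n_per_species=8, L=600, theta=[0.01], species_split_T=T, seed=33)
        (a, b), = simulate_two_species(spec)
        k[T] = jc_divergence(a, b).K_raw
    assert k[8.0] > k[1.0]


def test_polymorphism_thinning_reduces_within_species_S():
    S_neutral, S_thin = [], []
    for r in range(15):
        for scale, sink in ((1.0, S_neutral), (0.1, S_thin)):
            spec = ScenarioSpec(
                n_per_species=10,
                L=600,
                theta=[0.015],
                species_split_T=5.0,
                seed=400 + r,
                polymorphism_scale=[(1.0, scale)],
            )
            (a, b), = simulate_two_species(spec)
            sink.append(segregating_sites(b).S)
    assert np.mean(S_thin) < np.mean(S_neutral) / 3


def test_species_stats_against_msprime_oracle():
    """Within-species diversity of the isolation model vs an independent
    coalescent simulator (moment agreement at matched parameters)."""
    msprime = pytest.importorskip("msprime")
    n, L, theta_site, reps = 10, 800, 0.01, 250
    pis = []
    for r in range(reps):
        spec = ScenarioSpec(
            n_per_species=n, L=L, theta=[theta_site], species_split_T=6.0, seed=600 + r
        )
        (a, b), = simulate_two_species(spec)
        pis.append(nucleotide_diversity(b))
    oracle = []
    for i, ts in enumerate(
        msprime.sim_ancestry(
            samples=n, ploidy=1, sequence_length=L, num_replicates=reps, random_seed=5
        )
    ):
        mts = msprime.sim_mutations(
            ts, rate=theta_site / 2, random_seed=900 + i, discrete_genome=False
        )
        oracle.append(mts.diversity(span_normalise=True))
    assert np.mean(pis) == pytest.approx(np.mean(oracle), rel=0.10)


# ---------------------------------------------------------------------------
# balanced lineages
# ---------------------------------------------------------------------------

def test_high_exchange_looks_panmictic():
    Ds = []
    for r in range(60):
        aln, _ = simulate_balanced_lineages(8, 600, 0.01, 50.0, seed=700 + r)
        Ds.append(tajimas_d(aln))
    assert abs(np.nanmean(Ds)) < 0.35


def test_low_exchange_shifts_tajima_positive_and_bimodal():
    from polydiv.demography import mismatch_observed

    Ds, bimodal = [], 0
    reps = 40
    for r in range(reps):
        aln, code = simulate_balanced_lineages(8, 600, 0.01, 0.05, seed=800 + r)
        Ds.append(tajimas_d(aln))
        spec = mismatch_observed(aln)
        # bimodality: a dip between two local maxima
        peaks = [
            i
            for i in range(1, len(spec) - 1)
            if spec[i] >= spec[i - 1] and spec[i] >= spec[i + 1] and spec[i] > 0.02
        ]
        if len(peaks) >= 2 or (len(spec) > 2 and spec[0] > 0.02 and np.argmax(spec[1:]) > 1):
            bimodal += 1
    assert np.nanmean(Ds) > 0.75
    assert bimodal / reps > 0.5


def test_genotype_pairing_drives_heterozygote_excess():
    rng = np.random.default_rng(12)
    _, code = simulate_balanced_lineages(12, 120, 0.005, 0.1, seed=13)
    n_AA, n_Aa, n_aa = pair_genotypes(code, 1.0, rng)
    assert n_Aa == 12
    assert heterozygote_excess_test(n_AA, n_Aa, n_aa) < 0.01
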