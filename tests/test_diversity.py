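import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_alignment
from polydiv import codon as cd
from polydiv.alignment import Alignment, AlignmentError
from polydiv.diversity import (
    fixed_aa_replacements,
    harmonic,
    haplotype_diversity,
    jc_correct,
    jc_divergence,
    locus_summary,
    nei_gojobori_between,
    nei_gojobori_within,
    nucleotide_diversity,
    sliding_window,
    tajimas_d,
    watterson_theta,
)


# ---------------------------------------------------------------------------
# watterson_theta
# ---------------------------------------------------------------------------

def test_watterson_n2():
    theta, _ = watterson_theta(2, 3, 100)
    assert theta == pytest.approx(0.03)  # a_1 = 1


def test_watterson_no_variation():
    theta, sd = watterson_theta(4, 0, 500)
    assert theta == 0.0 and sd == 0.0


def test_watterson_published_value():
    # n=26, S=16, L=892 -> 0.0047 per site
    theta, sd = watterson_theta(26, 16, 892)
    assert theta == pytest.approx(0.0047, abs=5e-5)
    assert sd > 0  # printed SDs mix conventions; only the estimate is pinned


def test_watterson_rejects_n1():
    with pytest.raises(ValueError):
        watterson_theta(1, 0, 100)


# ---------------------------------------------------------------------------
# nucleotide_diversity
# ---------------------------------------------------------------------------

def test_pi_two_sequences():
    aln = Alignment.from_sequences(["A" * 100, "A" * 99 + "T"])
    assert nucleotide_diversity(aln) == pytest.approx(0.01)


def test_pi_identical_zero():
    aln = Alignment.from_sequences(["ACGTACGT"] * 6)
    assert nucleotide_diversity(aln) == 0.0


def test_pi_matches_brute_force(rng):
    for _ in range(15):
        aln = random_alignment(rng, n=8, L=50)
        n = aln.n
        total = 0.0
        npairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                d = np.mean(aln.matrix[i] != aln.matrix[j])
                total += d
                npairs += 1
        assert nucleotide_diversity(aln) == pytest.approx(total / npairs)


# ---------------------------------------------------------------------------
# haplotype_diversity
# ---------------------------------------------------------------------------

def test_hd_all_distinct(rng):
    seqs = list({"".join(rng.choice(list("ACGT"), 25)) for _ in range(12)})[:10]
    hd, _ = haplotype_diversity(Alignment.from_sequences(seqs))
    assert hd == pytest.approx(1.0)


def test_hd_monomorphic():
    hd, sd = haplotype_diversity(Alignment.from_sequences(["ACGT"] * 8))
    assert hd == 0.0 and sd == 0.0


def test_hd_formula():
    # 3 + 1 split of n=4: Hd = 4/3 * (1 - (9+1)/16) = 0.5
    aln = Alignment.from_sequences(["AAAA", "AAAA", "AAAA", "AAAT"])
    hd, _ = haplotype_diversity(aln)
    assert hd == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# tajimas_d
# ---------------------------------------------------------------------------

def test_tajima_zero_when_pi_equals_watterson():
    # n=4 with 8 singleton and 3 doubleton sites: mean pairwise differences
    # k = 6 equals S/a_3 = 11/(11/6), so the numerator vanishes exactly
    aln = Alignment.from_sequences(
        ["TTAAAAAATTT", "AATTAAAATTT", "AAAATTAAAAA", "AAAAAATTAAA"]
    )
    assert tajimas_d(aln) == pytest.approx(0.0, abs=1e-12)


def test_tajima_undefined_for_pairs():
    aln = Alignment.from_sequences(["AAAAAAAAAA", "TTTAAAAAAA"])
    assert np.isnan(tajimas_d(aln))


def test_tajima_undefined_without_variation():
    aln = Alignment.from_sequences(["ACGT"] * 4)
    assert np.isnan(tajimas_d(aln))


def test_tajima_negative_for_singleton_excess():
    # 10 sequences, 6 singleton sites -> excess of rare variants
    base = "A" * 30
    seqs = [base] * 4
    for i in range(6):
        seqs.append(base[:i] + "T" + base[i + 1 :])
    aln = Alignment.from_sequences(seqs)
    assert tajimas_d(aln) < 0


def test_tajima_null_mean_matches_msprime_oracle():
    """Mean D of our simulator within 0.1 of an independent coalescent's."""
    msprime = pytest.importorskip("msprime")
    from polydiv.simulate import simulate_alignment

    n, L, theta_site, reps = 10, 1000, 0.005, 400
    oracle = []
    for i, ts in enumerate(
        msprime.sim_ancestry(
            samples=n, ploidy=1, sequence_length=L, num_replicates=reps, random_seed=11
        )
    ):
        mts = msprime.sim_mutations(
            ts, rate=theta_site / 2, random_seed=1000 + i, discrete_genome=False
        )
        oracle.append(mts.Tajimas_D())
    rng = np.random.default_rng(2)
    mine = [
        tajimas_d(simulate_alignment(n, L, theta_site, seed=rng)) for _ in range(reps)
    ]
    assert abs(np.nanmean(mine) - np.nanmean(oracle)) < 0.1


# ---------------------------------------------------------------------------
# jc_divergence
# ---------------------------------------------------------------------------

def test_jc_identical_groups():
    a = Alignment.from_sequences(["ACGTAA"] * 3)
    b = Alignment.from_sequences(["ACGTAA"] * 2)
    res = jc_divergence(a, b)
    assert res.K_raw == 0.0 and res.K_JC == 0.0


def test_jc_closed_form():
    assert jc_correct(0.10) == pytest.approx(0.10732, abs=1e-4)


def test_jc_undefined_beyond_three_quarters():
    with pytest.raises(ValueError, match="JC undefined"):
        jc_correct(0.80)


def test_jc_symmetric_and_dominates_raw(rng):
    for _ in range(10):
        whole = random_alignment(rng, n=9, L=60)
        a = whole.subset(range(4))
        b = whole.subset(range(4, 9))
        r1 = jc_divergence(a, b)
        r2 = jc_divergence(b, a)
        assert r1.K_raw == pytest.approx(r2.K_raw)
        assert r1.K_JC == pytest.approx(r2.K_JC)
        assert r1.K_JC >= r1.K_raw


def test_fixed_differences_enumerated():
    a = Alignment.from_sequences(["ATGAAA"] * 3)  # M K
    b = Alignment.from_sequences(["ATGGAA"] * 3)  # M E
    res = jc_divergence(a, b)
    assert len(res.fixed_differences) == 1
    fd = res.fixed_differences[0]
    assert fd.position == 3
    assert fd.syn_class == "nonsynonymous"
    assert fd.aa_change == "K2E"


# ---------------------------------------------------------------------------
# Nei-Gojobori
# ---------------------------------------------------------------------------

def test_ng_synonymous_pair():
    sd, nd = cd.pathway_differences("ATT", "ATC")  # both Ile
    assert (sd, nd) == (1.0, 0.0)


def test_ng_met_has_no_synonymous_sites():
    s, n = cd.syn_nonsyn_sites("ATG")
    assert s == 0.0 and n == 3.0


def test_ng_two_step_pathway_average():
    # TTT(F) vs GTA(V): pathways via GTT(V) and TTA(L) -> sd=0.5, nd=1.5
    sd, nd = cd.pathway_differences("TTT", "GTA")
    assert sd == pytest.approx(0.5)
    assert nd == pytest.approx(1.5)


@given(st.integers(0, 2**20))
@settings(max_examples=30, deadline=None)
def test_ng_sites_sum_to_three_per_codon(seed):
    rng = np.random.default_rng(seed)
    stops = cd.stop_codons(1)
    codons = [c for c in (a + b + c2 for a in "ACGT" for b in "ACGT" for c2 in "ACGT") if c not in stops]
    cdn = rng.choice(codons)
    s, n = cd.syn_nonsyn_sites(str(cdn))
    assert s + n == pytest.approx(3.0)


def test_ng_within_and_between(rng):
    a = Alignment.from_sequences(["ATTGAA", "ATCGAA"])  # 1 syn difference
    res = nei_gojobori_within(a)
    assert res.syn_diffs == pytest.approx(1.0)
    assert res.nonsyn_diffs == 0.0
    assert res.pn == 0.0
    b = Alignment.from_sequences(["ATTAAA", "ATTAAA"])
    between = nei_gojobori_between(a, b)
    assert between.nonsyn_diffs > 0  # GAA(E) vs AAA(K)


def test_ng_internal_stop_raises():
    a = Alignment.from_sequences(["TAAAAA", "TAAAAA"])
    with pytest.raises(AlignmentError, match="stop"):
        nei_gojobori_within(a)


def test_fixed_aa_replacements_counts():
    a = Alignment.from_sequences(["ATGAAAGGG"] * 4)  # M K G
    b = Alignment.from_sequences(["ATGGAAGGC"] * 4)  # M E G (3rd codon syn)
    reps = fixed_aa_replacements(a, b)
    assert reps == [(2, "K", "E")]


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def test_window_degenerate_tiling_equals_global():
    rng = np.random.default_rng(5)
    aln = random_alignment(rng, n=6, L=60)
    prof = sliding_window("pi", aln.L, aln.L, aln)
    assert len(prof.values) == 1
    assert prof.values[0] == pytest.approx(nucleotide_diversity(aln))


def test_window_flat_profile_on_uniform_divergence():
    a = Alignment.from_sequences(["AC" * 30] * 3)
    b = Alignment.from_sequences(["GC" * 30] * 3)  # every odd column differs
    prof = sliding_window("K", 20, 20, a, b)
    assert all(v == pytest.approx(0.5) for v in prof.values)


def test_window_zero_denominator_flagged():
    a = Alignment.from_sequences(["ATGAAA", "ATGAAA", "ATGAAG"])  # K->K? AAA/AAG syn
    prof = sliding_window("pia_pis", 3, 3, a)
    assert "zero-denominator" in prof.flags


def test_window_larger_than_L_rejected(tiny_aln):
    with pytest.raises(ValueError):
        sliding_window("pi", 100, 10, tiny_aln)


# ---------------------------------------------------------------------------
# locus summary + moment calibration
# ---------------------------------------------------------------------------

def test_locus_summary_fields(tiny_aln):
    s = locus_summary(tiny_aln, name="toy", species="Euc")
    assert s.S == 1 and s.n == 4 and s.L == 12
    assert s.theta_w > 0 and 0 <= s.Hd <= 1


def test_theta_estimators_converge_on_simulated_data():
    """E[theta_w] and E[pi] both approach the simulated theta (<5% error)."""
    from polydiv.alignment import segregating_sites
    from polydiv.simulate import simulate_alignment

    n, L, theta, reps = 12, 900, 0.008, 350
    rng = np.random.default_rng(77)
    tw, pi = [], []
    for _ in range(reps):
        aln = simulate_alignment(n, L, theta, seed=rng)
        tw.append(watterson_theta(n, segregating_sites(aln).S, L)[0])
        pi.append(nucleotide_diversity(aln))
    assert np.mean(tw) == pytest.approx(theta, rel=0.05)
    assert np.mean(pi) == pytest.approx(theta, rel=0.05)
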