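import numpy as np
import pytest

from polydiv.alignment import Alignment, infinite_sites_filter, segregating_sites
from polydiv.demography import (
    ThreeModelSettings,
    contraction_loglik,
    date_expansion,
    exponential_growth_time,
    fit_expansion,
    fit_three_models,
    mismatch_expected_constant,
    mismatch_expected_expansion,
    mismatch_observed,
    pairwise_difference_counts,
    raggedness,
    segregating_sites_pmf,
)
from polydiv.diversity import nucleotide_diversity
from polydiv.simulate import Demography, drop_mutations, simulate_alignment, simulate_genealogy


# ---------------------------------------------------------------------------
# observed spectra
# ---------------------------------------------------------------------------

def test_mismatch_identical_is_point_mass_at_zero():
    aln = Alignment.from_sequences(["ACGT"] * 5)
    spec = mismatch_observed(aln)
    assert spec[0] == 1.0 and spec.sum() == pytest.approx(1.0)


def test_mismatch_two_sequences_point_mass():
    aln = Alignment.from_sequences(["AAAAAAAAAA", "TTTTTAAAAA"])
    spec = mismatch_observed(aln)
    assert spec[5] == 1.0


def test_mismatch_mean_equals_mean_pairwise_differences(rng):
    aln = simulate_alignment(10, 400, 0.02, seed=rng)
    spec = mismatch_observed(aln)
    mean = float(np.sum(np.arange(len(spec)) * spec))
    k_mean = float(np.mean(pairwise_difference_counts(aln)))
    assert mean == pytest.approx(k_mean)
    # with no missing data this equals pi * L
    assert mean == pytest.approx(nucleotide_diversity(aln) * aln.L)


# ---------------------------------------------------------------------------
# expected spectra
# ---------------------------------------------------------------------------

def test_constant_spectrum_theta_one_halving():
    f = mismatch_expected_constant(1.0, 30, normalize=False)
    expect = 0.5 ** (np.arange(31) + 1)
    assert f == pytest.approx(expect)


def test_constant_spectrum_limit_theta_zero():
    f = mismatch_expected_constant(1e-12, 10)
    assert f[0] == pytest.approx(1.0)


def test_constant_spectrum_sums_to_one_analytically():
    for theta in (0.3, 2.0, 11.0):
        f = mismatch_expected_constant(theta, 2000, normalize=False)
        assert f.sum() == pytest.approx(1.0, abs=1e-6)


def test_expansion_nests_constant_at_tau_zero():
    # tau = 0: the recent epoch has zero duration, leaving the ancestral
    # (pre-expansion) geometric spectrum at theta0
    f = mismatch_expected_expansion(0.7, 50.0, 0.0, 40, normalize=False)
    g = mismatch_expected_constant(0.7, 40, normalize=False)
    assert f == pytest.approx(g)


def test_expansion_wave_centered_near_tau():
    tau = 12.0
    f = mismatch_expected_expansion(0.01, 500.0, tau, 60)
    mode = int(np.argmax(f))
    assert abs(mode - tau) <= 3  # Poisson-like wave around tau
    mean = np.sum(np.arange(len(f)) * f)
    assert mean == pytest.approx(tau, rel=0.25)


def test_expansion_spectrum_sums_to_one():
    f = mismatch_expected_expansion(0.5, 40.0, 6.0, 3000, normalize=False)
    assert f.sum() == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_point_mass_gives_tau_zero():
    aln = Alignment.from_sequences(["ACGTACGT"] * 6)
    fit = fit_expansion(aln)
    assert fit.tau == 0.0


def test_fit_recovers_tau_on_expansion_data():
    rng = np.random.default_rng(5)
    taus = []
    for _ in range(40):
        demog = Demography.sudden_expansion(t=0.25, ratio=100)
        aln = simulate_alignment(25, 900, 0.02, demog, seed=rng)
        taus.append(fit_expansion(aln).tau)
    # theta_locus = 18, event at 0.25 -> tau = theta * t = 4.5 mutational units
    assert np.mean(taus) == pytest.approx(4.5, rel=0.30)


def test_expansion_fit_beats_constant_on_expansion_data():
    rng = np.random.default_rng(6)
    wins = 0
    for _ in range(20):
        demog = Demography.sudden_expansion(t=0.3, ratio=100)
        aln = simulate_alignment(20, 800, 0.02, demog, seed=rng)
        fit = fit_expansion(aln)
        if fit.sse_expansion < fit.sse_constant:
            wins += 1
    assert wins >= 15


def test_expansion_fit_offers_little_on_constant_data():
    rng = np.random.default_rng(7)
    gains_constant = []
    gains_expansion = []
    for _ in range(15):
        aln_c = simulate_alignment(20, 800, 0.01, seed=rng)
        f_c = fit_expansion(aln_c)
        gains_constant.append(f_c.sse_constant - f_c.sse_expansion)
        demog = Demography.sudden_expansion(t=0.3, ratio=100)
        aln_e = simulate_alignment(20, 800, 0.01, demog, seed=rng)
        f_e = fit_expansion(aln_e)
        gains_expansion.append(f_e.sse_constant - f_e.sse_expansion)
    assert np.median(gains_expansion) > np.median(gains_constant)


def test_raggedness_flat_vs_spiky():
    assert raggedness(np.ones(10) / 10) < raggedness(np.array([0.5, 0.0, 0.5]))


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

def test_date_expansion_arithmetic():
    # tau=2, 1%/My, L=1000: u = 1e-5/yr, t = 2 / (2e-5) = 1e5 years
    assert date_expansion(2.0, 0.01, 1000) == pytest.approx(1e5)


def test_date_expansion_halves_with_doubled_length():
    t1 = date_expansion(3.0, 0.02, 500)
    t2 = date_expansion(3.0, 0.02, 1000)
    assert t2 == pytest.approx(t1 / 2)


def test_exponential_growth_time():
    assert exponential_growth_time(np.e, 1.0) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# coalescent likelihood
# ---------------------------------------------------------------------------

def test_pmf_sums_to_one():
    p = segregating_sites_pmf(np.arange(400), 8, 5.0)
    assert p.sum() == pytest.approx(1.0, abs=1e-6)


def test_contraction_loglik_nests_constant_against_exact_oracle():
    """S_event = 0 must match the analytic constant-size P(S) (n<=8, S<=6)."""
    for n, S, theta in [(6, 3, 4.0), (8, 6, 5.0), (5, 2, 2.0)]:
        lnl, se = contraction_loglik(S, theta, 0.0, 0.0, 40000, seed=1, n=n)
        exact = np.log(segregating_sites_pmf(S, n, theta))
        assert abs(lnl - exact) < 3 * max(se, 1e-4)


def test_contraction_loglik_seed_consistency():
    """Disjoint seed sets agree within 3 reported MC standard errors."""
    aln = simulate_alignment(10, 500, 0.02, seed=3)
    l1, se1 = contraction_loglik(aln, 10.0, 0.1, 1.0, 8000, seed=100)
    l2, se2 = contraction_loglik(aln, 10.0, 0.1, 1.0, 8000, seed=200)
    assert abs(l1 - l2) < 3 * np.hypot(se1, se2)


def test_contraction_detected_against_constant():
    """LnL near the true (T,S) beats S=0 in >= 80% of contracted datasets."""
    rng = np.random.default_rng(9)
    theta_site, L, n = 0.03, 700, 15
    theta_locus = theta_site * L
    wins = 0
    reps = 50
    for _ in range(reps):
        demog = Demography.contraction(0.05, 2.0)
        tree = simulate_genealogy(n, demog, rng)
        aln = drop_mutations(tree, theta_site, L, rng)
        l_true, _ = contraction_loglik(aln, theta_locus, 0.05, 2.0, 3000, seed=rng)
        l_null, _ = contraction_loglik(aln, theta_locus, 0.0, 0.0, 3000, seed=rng)
        if l_true > l_null:
            wins += 1
    assert wins / reps >= 0.80


def test_contraction_loglik_rejects_bad_input():
    with pytest.raises(ValueError):
        contraction_loglik(5, -1.0, 0.0, 0.0, 100, n=8)
    aln = Alignment.from_sequences(["ACGT", "ACGA"])
    from polydiv.alignment import AlignmentError

    with pytest.raises(AlignmentError, match="degenerate"):
        contraction_loglik(aln, 1.0, 0.0, 0.0, 100)


# ---------------------------------------------------------------------------
# three-model comparison
# ---------------------------------------------------------------------------

def _loci(demogs, theta=0.03, L=700, n=15, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for i, d in enumerate(demogs):
        tree = simulate_genealogy(n, d, rng)
        aln = drop_mutations(tree, theta, L, rng)
        aln.name = f"l{i}"
        flt, _, _ = infinite_sites_filter(aln)
        out[f"l{i}"] = flt
    return out


def test_three_models_nesting_and_params():
    st = ThreeModelSettings(n_genealogies=300, seed=5)
    loci = _loci([None] * 3, seed=21)
    res = fit_three_models(loci, st)
    m1, m2, m3 = (res.fits[m] for m in ("M1", "M2", "M3"))
    assert m3.lnL >= m2.lnL >= m1.lnL
    assert (m1.n_params, m2.n_params, m3.n_params) == (3, 5, 9)
    assert res.lrt["M2/M1"][1] == 2
    assert res.lrt["M3/M1"][1] == 6


def test_three_models_needs_two_loci():
    loci = _loci([None], seed=22)
    with pytest.raises(ValueError):
        fit_three_models(loci, ThreeModelSettings(n_genealogies=100))
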