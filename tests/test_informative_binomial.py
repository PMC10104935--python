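"""Encompassing-prior Bayes factors, predictive distributions, and HDRs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from sevbayes import (
    ENCOMPASSING,
    BinomialDesign,
    BinomialOutcome,
    IntervalHypothesis,
    bf_lattice,
    bf_vs_encompassing,
    classify_bf,
    hdr_complement,
    posterior_region_mass,
    prior_predictive,
    prior_region_mass,
)
from sevbayes.exceptions import DegenerateHypothesisError, DomainError


def quadrature_marginal(h: IntervalHypothesis, d: BinomialDesign, y: BinomialOutcome):
    """Independent oracle: p(y|H) by adaptive quadrature over each arm's prior."""
    value = 1.0
    for (lo, hi), n, s in zip(h.regions, d.sizes, (y.s_a, y.s_b)):
        integrand = lambda th: stats.binom.pmf(s, n, th) / (hi - lo)
        arm, _ = integrate.quad(integrand, lo, hi)
        value *= arm
    return value


class TestRegionMasses:
    def test_vague_occupies_quarter(self, h_vague):
        assert prior_region_mass(h_vague) == pytest.approx(0.25)

    def test_specific_occupies_one_percent(self, h_specific):
        assert prior_region_mass(h_specific) == pytest.approx(0.01)

    def test_encompassing_occupies_everything(self):
        assert prior_region_mass(ENCOMPASSING) == 1.0

    def test_point_hypothesis_rejected(self):
        h = IntervalHypothesis("point", (0.3, 0.3), (0.5, 0.9))
        with pytest.raises(DegenerateHypothesisError):
            prior_region_mass(h)

    def test_posterior_mass_of_encompassing_is_one(self, design_20, aligned_20):
        assert posterior_region_mass(ENCOMPASSING, design_20, aligned_20) == pytest.approx(1.0)

    def test_posterior_mass_from_beta_cdfs(self, h_vague, design_20, aligned_20):
        # direct Beta(6,16) x Beta(16,6) oracle for the aligned N=20 outcome
        expected = (stats.beta(6, 16).cdf(0.5) - stats.beta(6, 16).cdf(0.0)) * (
            stats.beta(16, 6).cdf(1.0) - stats.beta(16, 6).cdf(0.5)
        )
        got = posterior_region_mass(h_vague, design_20, aligned_20)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got / 0.25 == pytest.approx(3.89, abs=0.01)

    def test_out_of_range_successes_rejected(self, h_vague, design_4):
        with pytest.raises(DomainError):
            posterior_region_mass(h_vague, design_4, BinomialOutcome(5, 0))


class TestBayesFactor:
    @pytest.mark.parametrize(
        "hyp, design, outcome, expected",
        [
            ("h_specific", "design_20", "aligned_20", 16.53),
            ("h_specific", "design_4", "aligned_4", 4.37),
            ("h_vague", "design_20", "aligned_20", 3.89),
            ("h_vague", "design_4", "aligned_4", 2.64),
        ],
    )
    def test_worked_scenarios(self, hyp, design, outcome, expected, request):
        res = bf_vs_encompassing(
            request.getfixturevalue(hyp),
            request.getfixturevalue(design),
            request.getfixturevalue(outcome),
        )
        assert res.bf == pytest.approx(expected, abs=0.01)
        assert res.log_bf == pytest.approx(np.log(res.bf))

    def test_encompassing_vs_itself_is_one(self, design_20, aligned_20):
        res = bf_vs_encompassing(ENCOMPASSING, design_20, aligned_20)
        assert res.bf == pytest.approx(1.0, rel=1e-12)

    def test_specific_beats_vague_on_aligned_data(
        self, h_specific, h_vague, design_20, design_4, aligned_20, aligned_4
    ):
        """When the data align, the nested (more specific) hypothesis earns
        the larger Bayes factor, at both sample sizes."""
        assert (
            bf_vs_encompassing(h_specific, design_20, aligned_20).bf
            > bf_vs_encompassing(h_vague, design_20, aligned_20).bf
        )
        assert (
            bf_vs_encompassing(h_specific, design_4, aligned_4).bf
            > bf_vs_encompassing(h_vague, design_4, aligned_4).bf
        )

    def test_mass_ratio_equals_marginal_ratio(self, h_specific, design_20, aligned_20):
        res = bf_vs_encompassing(h_specific, design_20, aligned_20)
        assert res.bf == pytest.approx(
            res.marginal_constrained / res.marginal_encompassing, rel=1e-6
        )

    def test_marginal_against_quadrature_oracle(self, h_specific, design_20, aligned_20):
        oracle = quadrature_marginal(h_specific, design_20, aligned_20)
        res = bf_vs_encompassing(h_specific, design_20, aligned_20)
        assert res.marginal_constrained == pytest.approx(oracle, rel=1e-8)

    def test_marginal_against_monte_carlo_oracle(self, h_specific, design_20, rng):
        """Sampling theta from the truncated-uniform prior reproduces the
        quadrature marginal within 3 standard errors at 1e5 draws."""
        n_draws = 100_000
        (lo_a, hi_a), (lo_b, hi_b) = h_specific.regions
        th_a = rng.uniform(lo_a, hi_a, n_draws)
        th_b = rng.uniform(lo_b, hi_b, n_draws)
        draws = stats.binom.pmf(5, 20, th_a) * stats.binom.pmf(15, 20, th_b)
        mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(n_draws)
        exact = bf_vs_encompassing(
            h_specific, design_20, BinomialOutcome(5, 15)
        ).marginal_constrained
        assert abs(mc - exact) < 3 * se


class TestPriorPredictive:
    def test_uniform_single_trial_is_laplace(self):
        pred = prior_predictive(ENCOMPASSING, BinomialDesign(1, 1))
        np.testing.assert_allclose(pred.marginal_a, [0.5, 0.5])
        np.testing.assert_allclose(pred.marginal_b, [0.5, 0.5])

    def test_joint_pmf_sums_to_one(self, h_specific, h_vague, design_20):
        for h in (h_specific, h_vague, ENCOMPASSING):
            pred = prior_predictive(h, design_20)
            assert pred.pmf.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(pred.pmf >= 0)

    def test_marginals_consistent_with_joint(self, h_vague, design_20):
        pred = prior_predictive(h_vague, design_20)
        np.testing.assert_allclose(pred.pmf.sum(axis=1), pred.marginal_a, atol=1e-12)
        np.testing.assert_allclose(pred.pmf.sum(axis=0), pred.marginal_b, atol=1e-12)

    def test_specific_mode_at_quarter_of_n(self, h_specific, design_20):
        pred = prior_predictive(h_specific, design_20)
        assert int(np.argmax(pred.marginal_a)) == 5

    def test_vague_high_counts_implausible(self, h_vague, design_20):
        # arm A predicts theta_A <= 0.5, so 14+ successes carry under 1% mass
        pred = prior_predictive(h_vague, design_20)
        assert pred.marginal_a[14:].sum() < 0.01

    def test_matches_enumeration_oracle(self, h_specific):
        # brute-force Simpson integration over theta on a fine grid, N=4
        n = 4
        lo, hi = h_specific.region_a
        th = np.linspace(lo, hi, 4001)
        oracle = [
            integrate.simpson(stats.binom.pmf(s, n, th) / (hi - lo), x=th)
            for s in range(n + 1)
        ]
        pred = prior_predictive(h_specific, BinomialDesign(n, n))
        np.testing.assert_allclose(pred.marginal_a, oracle, rtol=1e-8)


class TestHdrComplement:
    def test_vague_hypothesis_99(self, h_vague, design_20):
        """The vague hypothesis still rules out plausible outcomes: 14..20
        successes on arm A and 0..6 on arm B sit outside its 99% HDR."""
        comp = hdr_complement(h_vague, design_20, 0.99)
        assert comp["A"] == list(range(14, 21))
        assert comp["B"] == list(range(0, 7))

    def test_specific_hypothesis_99(self, h_specific, design_20):
        # frozen from the exact greedy HDR on the beta-binomial marginal:
        # {1..10} already holds 99.03% on arm A, so 0 and 11..20 fall outside
        comp = hdr_complement(h_specific, design_20, 0.99)
        assert comp["A"] == [0] + list(range(11, 21))
        assert comp["B"] == list(range(0, 10)) + [20]

    def test_tied_support_enters_together(self):
        # uniform predictive on a single trial: both outcomes tie at 1/2, so
        # a 50% HDR must include both and the complement is empty
        comp = hdr_complement(ENCOMPASSING, BinomialDesign(1, 1), 0.5)
        assert comp == {"A": [], "B": []}

    def test_hdr_mass_reaches_coverage_minimally(self, h_specific, design_20):
        coverage = 0.99
        pred = prior_predictive(h_specific, design_20)
        comp = set(hdr_complement(h_specific, design_20, coverage)["A"])
        hdr = [s for s in range(21) if s not in comp]
        mass = pred.marginal_a[hdr].sum()
        assert mass >= coverage
        smallest = min(hdr, key=lambda s: pred.marginal_a[s])
        assert mass - pred.marginal_a[smallest] < coverage

    @pytest.mark.parametrize("coverage", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_coverage_rejected(self, h_vague, design_20, coverage):
        with pytest.raises(DomainError):
            hdr_complement(h_vague, design_20, coverage)


class TestBfLattice:
    def test_encompassing_lattice_is_flat(self, design_4):
        np.testing.assert_allclose(bf_lattice(ENCOMPASSING, design_4), 1.0)

    def test_entry_matches_pointwise_bf(self, h_vague, design_20, aligned_20):
        lat = bf_lattice(h_vague, design_20)
        assert lat[5, 15] == pytest.approx(3.89, abs=0.01)

    def test_specificity_bounds_the_evidence(self, h_specific, h_vague, design_20):
        """No outcome can produce more evidence than 1/(prior region mass)."""
        for h in (h_specific, h_vague):
            bound = 1.0 / prior_region_mass(h)
            assert bf_lattice(h, design_20).max() <= bound + 1e-9


class TestClassifyBf:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (150.0, "Extreme evidence for H1"),
            (50.0, "Very strong evidence for H1"),
            (16.53, "Strong evidence for H1"),
            (4.37, "Moderate evidence for H1"),
            (2.64, "Anecdotal evidence for H1"),
            (1.0, "No evidence for either hypothesis"),
            (0.5, "Anecdotal evidence for H0"),
            (0.2, "Moderate evidence for H0"),
            (0.05, "Strong evidence for H0"),
            (0.02, "Very strong evidence for H0"),
            (0.005, "Extreme evidence for H0"),
        ],
    )
    def test_bands(self, bf, label):
        assert classify_bf(bf) == label

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_rejected(self, bad):
        with pytest.raises(DomainError):
            classify_bf(bad)


@st.composite
def intervals(draw):
    lo = draw(st.floats(0.0, 0.9))
    width = draw(st.floats(0.02, 1.0))
    return (lo, min(lo + width, 1.0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    region_a=intervals(),
    region_b=intervals(),
    n_a=st.integers(1, 12),
    n_b=st.integers(1, 12),
    data=st.data(),
)
def test_bf_identity_and_bound_on_random_instances(region_a, region_b, n_a, n_b, data):
    """For arbitrary box hypotheses and outcomes, the region-mass ratio equals
    the marginal-likelihood ratio (quadrature oracle, 1e-6 relative) and never
    exceeds one over the hypothesis's specificity."""
    h = IntervalHypothesis("H", region_a, region_b)
    d = BinomialDesign(n_a, n_b)
    y = BinomialOutcome(
        data.draw(st.integers(0, n_a)), data.draw(st.integers(0, n_b))
    )
    res = bf_vs_encompassing(h, d, y)
    assert res.bf <= 1.0 / prior_region_mass(h) + 1e-9
    oracle_bf = quadrature_marginal(h, d, y) / res.marginal_encompassing
    if oracle_bf > 1e-12:
        assert res.bf == pytest.approx(oracle_bf, rel=1e-6)
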