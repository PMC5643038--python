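"""Stress-strength interference and Bayes updating with injury evidence."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from liftbn import (
    ConfigurationError,
    DiscreteFactor,
    InferenceError,
    InjuryEvidence,
    StrengthModel,
    build_discrete_network,
    condition_on_injury,
    discrete_posterior_mean,
    eliminate,
    injury_probability,
    posterior_summary,
    simulate,
    summarize,
)
from tests.conftest import SEED, make_sample_set

INV_SQRT_PI = 1.0 / math.sqrt(math.pi)


@pytest.fixture(scope="module")
def toy_gaussian():
    """C ~ N(0,1) draws against S ~ N(0,1): closed-form posterior means."""
    rng = np.random.default_rng(SEED)
    return make_sample_set(rng.normal(size=200_000), seed=SEED)


@pytest.fixture(scope="module")
def carbon_samples(carbon_scenario):
    return simulate(carbon_scenario, "both")


def _weighted_se(samples, field):
    x, w = samples.field(field), samples.weights
    mean = np.sum(w * x) / np.sum(w)
    return math.sqrt(np.sum((w * (x - mean)) ** 2)) / np.sum(w)


def test_injury_probability_normal_cdf():
    """Deterministic compression 3315.2 N vs strength N(5448, 2366)."""
    samples = make_sample_set(np.full(10, 3315.2))
    expected = float(norm.cdf((3315.2 - 5448.0) / 2366.0))
    assert injury_probability(samples, StrengthModel()) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.1836, abs=5e-4)


def test_unbreakable_disc_has_zero_injury_probability():
    samples = make_sample_set(np.full(10, 3315.2))
    assert injury_probability(samples, StrengthModel(mean=1e9, sd=1.0)) == pytest.approx(0.0, abs=1e-300)


def test_symmetric_load_about_strength_mean_gives_half():
    """Compression symmetric about mu_s with sigma_s -> 0 behaves like a
    coin flip on which side of the mean each draw falls."""
    samples = make_sample_set(np.array([5447.0, 5449.0] * 50))
    assert injury_probability(samples, StrengthModel(mean=5448.0, sd=1e-6)) == pytest.approx(0.5)


def test_no_evidence_leaves_weights_unchanged(toy_gaussian):
    out = condition_on_injury(toy_gaussian, StrengthModel(0.0, 1.0), InjuryEvidence.none())
    np.testing.assert_array_equal(out.weights, toy_gaussian.weights)


def test_toy_gaussian_posterior_means(toy_gaussian):
    """C,S ~ iid N(0,1): E[C | C>S] = 1/sqrt(pi), E[C | C<S] = -1/sqrt(pi);
    the importance-weighted estimates agree within Monte Carlo error."""
    strength = StrengthModel(mean=0.0, sd=1.0)
    for evidence, sign in ((InjuryEvidence.true(), 1.0), (InjuryEvidence.false(), -1.0)):
        conditioned = condition_on_injury(toy_gaussian, strength, evidence)
        se = _weighted_se(conditioned, "compression")
        mean = summarize(conditioned, "compression").mean
        assert mean == pytest.approx(sign * INV_SQRT_PI, abs=4 * se)
        assert se < 0.01


def test_posterior_ordering(carbon_samples):
    """E[C | injury] > E[C] > E[C | no injury]."""
    strength = StrengthModel()
    prior = summarize(carbon_samples, "compression").mean
    up = posterior_summary(carbon_samples, strength, InjuryEvidence.true(), "compression").mean
    down = posterior_summary(carbon_samples, strength, InjuryEvidence.false(), "compression").mean
    assert down < prior < up


@pytest.mark.parametrize("field", ["compression", "shear"])
def test_law_of_total_expectation(carbon_samples, field):
    """P(I)E[X|I] + (1-P(I))E[X|not I] = E[X] on one sample set — for shear
    too, which is how descendant evidence propagates along the trek."""
    strength = StrengthModel()
    p = injury_probability(carbon_samples, strength)
    e_true = posterior_summary(carbon_samples, strength, InjuryEvidence.true(), field).mean
    e_false = posterior_summary(carbon_samples, strength, InjuryEvidence.false(), field).mean
    e_prior = summarize(carbon_samples, field).mean
    assert p * e_true + (1 - p) * e_false == pytest.approx(e_prior, rel=1e-9)


def test_injury_evidence_raises_shear(carbon_samples):
    """Shear and compression are positively associated across draws, so
    injury evidence must raise the shear posterior mean."""
    c = carbon_samples.field("compression")
    s = carbon_samples.field("shear")
    assert np.cov(c, s)[0, 1] > 0
    strength = StrengthModel()
    up = posterior_summary(carbon_samples, strength, InjuryEvidence.true(), "shear").mean
    down = posterior_summary(carbon_samples, strength, InjuryEvidence.false(), "shear").mean
    assert up > down


def test_certain_evidence_is_a_no_op():
    """If every draw exceeds a near-deterministic strength, injury=true
    carries no information."""
    samples = make_sample_set(np.linspace(100.0, 200.0, 1000))
    conditioned = condition_on_injury(samples, StrengthModel(mean=50.0, sd=1e-9), InjuryEvidence.true())
    summary = summarize(conditioned, "compression")
    unconditioned = summarize(samples, "compression")
    assert summary.mean == pytest.approx(unconditioned.mean, rel=1e-12)
    assert summary.effective_sample_size == pytest.approx(1000.0)


def test_impossible_evidence_raises():
    samples = make_sample_set(np.full(100, 1000.0))
    with pytest.raises(InferenceError):
        condition_on_injury(samples, StrengthModel(mean=-1e9, sd=1.0), InjuryEvidence.false())


def test_severely_informative_evidence_warns():
    values = np.concatenate([np.zeros(999), [10.0]])
    samples = make_sample_set(values)
    with pytest.warns(UserWarning, match="effective sample size"):
        condition_on_injury(samples, StrengthModel(mean=5.0, sd=0.1), InjuryEvidence.true())


def test_strength_sampling_mode_agrees_with_analytic(toy_gaussian):
    strength = StrengthModel(mean=0.0, sd=1.0)
    # strength stream must be independent of the compression draws
    sampled = condition_on_injury(
        toy_gaussian, strength, InjuryEvidence.true(), sample_strength=True, rng=SEED + 1
    )
    assert set(np.unique(sampled.weights)) == {0.0, 1.0}
    mean = summarize(sampled, "compression").mean
    se = _weighted_se(sampled, "compression")
    assert mean == pytest.approx(INV_SQRT_PI, abs=5 * se)


def test_invalid_evidence_status_rejected():
    with pytest.raises(ConfigurationError):
        InjuryEvidence("maybe")


# --- discrete verifier network ---------------------------------------------


def test_discrete_factor_invariants():
    with pytest.raises(ConfigurationError):
        DiscreteFactor(("a",), np.array([0.5, -0.1]))
    with pytest.raises(ConfigurationError):
        DiscreteFactor(("a",), np.array([[0.5, 0.5]]))
    with pytest.raises(ConfigurationError):
        DiscreteFactor(("a",), np.array([0.5, 0.5]), bin_edges={"a": np.array([0.0, 0.0, 1.0])})
    factor = DiscreteFactor(("a",), np.array([2.0, 6.0])).normalized()
    np.testing.assert_allclose(factor.table, [0.25, 0.75])


def test_network_factors_normalize_and_marginalize(carbon_samples):
    strength = StrengthModel()
    f_c, f_ic = build_discrete_network(carbon_samples, strength, bins=50)
    assert f_c.table.sum() == pytest.approx(1.0, rel=1e-12)
    np.testing.assert_allclose(f_ic.table.sum(axis=1), 1.0, rtol=1e-12)  # CPT rows
    # marginal P(injury) from the binned network matches the exact estimator
    p_binned = float((f_c.table * f_ic.table[:, 1]).sum())
    p_exact = injury_probability(carbon_samples, strength)
    assert p_binned == pytest.approx(p_exact, abs=0.01)


def test_bins_below_ten_rejected(carbon_samples):
    with pytest.raises(ConfigurationError):
        build_discrete_network(carbon_samples, StrengthModel(), bins=5)


def test_eliminate_recovers_prior_without_evidence(carbon_samples):
    strength = StrengthModel()
    factors = build_discrete_network(carbon_samples, strength, bins=40)
    posterior = eliminate(factors, {}, "compression")
    mean = float(np.sum(posterior.table * posterior.bin_values["compression"]))
    assert mean == pytest.approx(summarize(carbon_samples, "compression").mean, rel=1e-9)


def test_eliminate_two_node_chain_hand_calculation():
    """P(A)=(0.3,0.7), P(B|A) rows (0.9,0.1)/(0.2,0.8):
    P(A=1|B=1) = 0.56/0.59 by direct Bayes arithmetic."""
    f_a = DiscreteFactor(("A",), np.array([0.3, 0.7]))
    f_ba = DiscreteFactor(("A", "B"), np.array([[0.9, 0.1], [0.2, 0.8]]))
    posterior = eliminate([f_a, f_ba], {"B": 1}, "A")
    np.testing.assert_allclose(posterior.table, [0.03 / 0.59, 0.56 / 0.59], rtol=1e-12)
    prior = eliminate([f_a, f_ba], {}, "A")
    np.testing.assert_allclose(prior.table, [0.3, 0.7], rtol=1e-12)


def test_eliminate_validates_variables(carbon_samples):
    factors = build_discrete_network(carbon_samples, StrengthModel(), bins=20)
    with pytest.raises(ConfigurationError):
        eliminate(factors, {}, "torque")
    with pytest.raises(ConfigurationError):
        eliminate(factors, {"shoulder": 1}, "compression")


def test_discrete_posterior_converges_to_importance_weighting(carbon_samples):
    """Refining the bins drives the discrete posterior mean toward the
    exact importance-weighted value."""
    strength = StrengthModel()
    exact = posterior_summary(carbon_samples, strength, InjuryEvidence.true(), "compression").mean
    errors = [
        abs(discrete_posterior_mean(carbon_samples, strength, InjuryEvidence.true(), bins) - exact)
        for bins in (10, 30, 100)
    ]
    assert errors[2] < errors[1] < errors[0]
    assert errors[2] < 30.0  # within bin tolerance at 100 bins
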