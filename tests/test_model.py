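"""KDE likelihoods, shank posteriors, hyperparameter fit and predictive."""

import numpy as np
import pytest
from scipy.stats import norm

from seegwm.model import (ClassDensity, ModelArtifact, ModelParameters,
                          ParameterPosterior, class_densities, classify,
                          contact_log_likelihood, fit_parameter_posterior,
                          loo_kde_log_likelihood, marginal_probabilities,
                          posterior_predictive, shank_log_posterior)
from seegwm.synthetic import GeneratorConfig, sample_features, sample_labelings
from conftest import make_record


def test_contact_likelihood_single_kernel_closed_form():
    den = ClassDensity(points=[[0.0, 5.0]], alpha=(1.0, 1.0))
    got = contact_log_likelihood(den, 0.0, (4.5, 5.5))
    expect = np.log(norm.pdf(0.0) * (norm.cdf(0.5) - norm.cdf(-0.5)))
    assert np.isclose(got, expect, rtol=1e-12)


def test_infinite_interval_marginalises_depth():
    rng = np.random.default_rng(0)
    den = ClassDensity(points=rng.normal(size=(20, 2)), alpha=(0.4, 0.7))
    s = 0.3
    got = contact_log_likelihood(den, s, (-np.inf, np.inf))
    # 1-D KDE in s alone
    expect = np.log(np.mean(norm.pdf(s, den.points[:, 0], 0.4)))
    assert np.isclose(got, expect, rtol=1e-10)


def test_duplicated_training_points_do_not_change_density():
    pt = [[0.2, 3.0]]
    one = ClassDensity(points=pt, alpha=(0.5, 1.0))
    two = ClassDensity(points=pt * 2, alpha=(0.5, 1.0))
    assert np.isclose(contact_log_likelihood(one, 0.0, (2.5, 3.5)),
                      contact_log_likelihood(two, 0.0, (2.5, 3.5)))


def test_density_integrates_to_one():
    rng = np.random.default_rng(1)
    den = ClassDensity(points=rng.normal(0, 1, size=(15, 2)),
                       alpha=(0.3, 0.5))
    g = np.linspace(-6, 6, 301)
    xx, yy = np.meshgrid(g, g)
    vals = np.exp(den.log_density(xx.ravel(), yy.ravel()))
    integral = vals.sum() * (g[1] - g[0]) ** 2
    assert abs(integral - 1.0) < 1e-3
    assert np.all(np.exp(den.log_density(den.points[:, 0],
                                         den.points[:, 1])) > 0)


def test_inverted_interval_rejected():
    den = ClassDensity(points=[[0.0, 0.0]], alpha=(1.0, 1.0))
    with pytest.raises(ValueError):
        contact_log_likelihood(den, 0.0, (1.0, 1.0))


def _toy_densities(rng, n_gm=25, n_wm=25):
    gm = ClassDensity(np.column_stack([rng.normal(0.4, 0.5, n_gm),
                                       rng.uniform(0, 9, n_gm)]),
                      alpha=(0.3, 1.0), tag="gm")
    wm = ClassDensity(np.column_stack([rng.normal(-0.8, 0.5, n_wm),
                                       rng.uniform(0, 9, n_wm)]),
                      alpha=(0.3, 1.0), tag="wm")
    return gm, wm


def test_single_contact_posterior_is_two_class_bayes():
    rng = np.random.default_rng(2)
    gm, wm = _toy_densities(rng)
    rec = make_record([-0.2], depth=[4.0])
    params = ModelParameters(alpha1=(0.3, 0.3), alpha2=(1.0, 1.0), beta=5.0)
    p = marginal_probabilities(rec, params, gm, wm)
    iv = rec.depth_intervals[0]
    lw = np.exp(contact_log_likelihood(wm, -0.2, iv))
    lg = np.exp(contact_log_likelihood(gm, -0.2, iv))
    assert np.isclose(p[0], lw / (lw + lg), rtol=1e-12)


def test_shank_posterior_matches_enumeration():
    from scipy.special import logsumexp

    from seegwm.chain import enumerate_labelings

    rng = np.random.default_rng(3)
    gm, wm = _toy_densities(rng)
    rec = make_record(rng.normal(0, 1, 3))
    params = ModelParameters(alpha1=(0.3, 0.3), alpha2=(1.0, 1.0), beta=1.2)
    labs = enumerate_labelings(3)
    logps = [shank_log_posterior(rec, z, params, gm, wm) for z in labs]
    assert np.isclose(logsumexp(logps), 0.0, atol=1e-10)
    # marginals from the enumerated posterior match forward-backward
    w = np.exp(logps)
    marg = w @ (labs > 0)
    assert np.allclose(marginal_probabilities(rec, params, gm, wm), marg,
                       rtol=1e-10)


def test_beta_zero_reduces_to_independent_bayes():
    rng = np.random.default_rng(4)
    gm, wm = _toy_densities(rng)
    rec = make_record(rng.normal(0, 1, 8))
    params = ModelParameters(alpha1=(0.3, 0.3), alpha2=(1.0, 1.0), beta=0.0)
    p = marginal_probabilities(rec, params, gm, wm)
    iv = rec.depth_intervals
    for i in range(len(rec)):
        lw = np.exp(contact_log_likelihood(wm, rec.s[i], iv[i]))
        lg = np.exp(contact_log_likelihood(gm, rec.s[i], iv[i]))
        assert np.isclose(p[i], lw / (lw + lg), rtol=1e-10)


def test_large_beta_forces_whole_shank_consensus():
    rng = np.random.default_rng(5)
    gm, wm = _toy_densities(rng)
    rec = make_record(rng.normal(-0.5, 0.6, 10))
    params = ModelParameters(alpha1=(0.3, 0.3), alpha2=(1.0, 1.0), beta=50.0)
    p = marginal_probabilities(rec, params, gm, wm)
    assert p.max() - p.min() < 1e-6


def test_label_swap_symmetry():
    rng = np.random.default_rng(6)
    gm, wm = _toy_densities(rng)
    rec = make_record(rng.normal(0, 1, 7))
    params = ModelParameters(alpha1=(0.3, 0.3), alpha2=(1.0, 1.0), beta=2.0)
    p = marginal_probabilities(rec, params, gm, wm)
    p_swapped = marginal_probabilities(rec, params, wm, gm)
    assert np.allclose(p_swapped, 1.0 - p, atol=1e-12)


def test_raising_white_likelihood_raises_white_marginal():
    from seegwm.chain import chain_marginals

    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(2, 9)
        node = rng.normal(size=(n, 2))
        beta = rng.uniform(0, 4)
        j = rng.integers(n)
        base = chain_marginals(beta, node)[j]
        node[j, 1] += rng.uniform(0.1, 2.0)
        assert chain_marginals(beta, node)[j] >= base - 1e-12


# ---------------------------------------------------------------------------
# hyperparameter posterior and predictive
# ---------------------------------------------------------------------------

def _labeled_cohort(n_shanks=40, seed=8):
    cfg = GeneratorConfig(beta_true=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    labs = sample_labelings(cfg, rng, n_shanks=n_shanks)
    return sample_features(labs, cfg, rng)


def test_fit_requires_both_classes():
    recs = [make_record([0.1, 0.2], labels=[-1, -1])]
    with pytest.raises(ValueError):
        fit_parameter_posterior(recs)


def test_flat_hyperprior_limit_recovers_ml_gridpoint():
    recs = _labeled_cohort()
    grid = np.geomspace(0.01, 2.0, 40)
    post = fit_parameter_posterior(recs, hyper_rate=1e-9, alpha_grid=grid)
    from seegwm.model import class_points
    gm_pts, _ = class_points(recs)
    ll = np.array([loo_kde_log_likelihood(gm_pts, a, 1.0) for a in grid])
    ml = grid[int(np.argmax(ll))]
    # posterior mean within two (log-spaced) grid steps of the ML point
    ratio = grid[1] / grid[0]
    assert ml / ratio ** 2 < post.mean[1] < ml * ratio ** 2


def test_degenerate_posterior_equals_point_estimate_marginals():
    recs = _labeled_cohort()
    post = fit_parameter_posterior(recs)
    point = ParameterPosterior(mean=post.mean, sd=np.zeros(3),
                               alpha2=post.alpha2)
    rec = recs[0]
    p_pred = posterior_predictive(rec, point, recs, n_samples=5,
                                  rng=np.random.default_rng(0))
    params = point.mean_parameters()
    gm, wm = class_densities(recs, params)
    assert np.allclose(p_pred, marginal_probabilities(rec, params, gm, wm),
                       rtol=1e-12)


def test_predictive_is_deterministic_given_seed():
    recs = _labeled_cohort()
    post = fit_parameter_posterior(recs)
    a = posterior_predictive(recs[0], post, recs, n_samples=30,
                             rng=np.random.default_rng(77))
    b = posterior_predictive(recs[0], post, recs, n_samples=30,
                             rng=np.random.default_rng(77))
    assert np.array_equal(a, b)


def test_predictive_monte_carlo_consistency():
    recs = _labeled_cohort(n_shanks=20)
    post = fit_parameter_posterior(recs)
    rec = recs[0]
    small = posterior_predictive(rec, post, recs, n_samples=100,
                                 rng=np.random.default_rng(1))
    draws = [posterior_predictive(rec, post, recs, n_samples=100,
                                  rng=np.random.default_rng(100 + i))
             for i in range(10)]
    big = np.mean(draws, axis=0)
    se = np.std(draws, axis=0, ddof=1) / np.sqrt(10)
    # per-contact difference bounded by ~3 x the 100-sample Monte-Carlo SE
    assert np.all(np.abs(small - big) <= 3 * np.sqrt(10) * se + 1e-3)
    assert np.all((big >= 0) & (big <= 1))


def test_posterior_samples_positive_and_reproducible():
    post = ParameterPosterior(mean=np.array([0.1, 0.1, 0.5]),
                              sd=np.array([0.2, 0.2, 1.0]))
    a = post.sample(200, np.random.default_rng(3))
    b = post.sample(200, np.random.default_rng(3))
    assert np.array_equal(a, b)
    assert np.all(a > 0)


def test_classify_threshold_and_confidence():
    labels, conf = classify([0.5, 0.9, 0.25], threshold=0.5)
    assert labels[0] == -1 and conf[0] == 0.0        # tie -> gray
    assert labels[1] == 1 and np.isclose(conf[1], 0.8)
    labels2, conf2 = classify([0.25], threshold=0.2)
    assert labels2[0] == 1 and np.isclose(conf2[0], 0.5)


def test_artifact_roundtrip(tmp_path):
    recs = _labeled_cohort(n_shanks=15)
    art = ModelArtifact.fit(recs)
    path = tmp_path / "model.json"
    art.save(path)
    back = ModelArtifact.load(path)
    assert np.allclose(back.posterior.mean, art.posterior.mean)
    assert np.allclose(back.gm_points, art.gm_points)
    rec = recs[0]
    p1 = art.predict(rec, n_samples=20, rng=np.random.default_rng(5))
    p2 = back.predict(rec, n_samples=20, rng=np.random.default_rng(5))
    assert np.array_equal(p1, p2)
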