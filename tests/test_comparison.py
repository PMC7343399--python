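import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from fidtol import loo_elpd, psis_smooth, stacking_weights
from fidtol.comparison import _gpd_fit, compare_identity_models


# ------------------------------------------------------------------ PSIS


def test_uniform_weights_for_equal_ratios():
    w, khat = psis_smooth(np.zeros(1000))
    assert np.allclose(w, 1 / 1000)
    assert np.isnan(khat)  # degenerate-tail sentinel


def test_gpd_fit_recovers_shape():
    x = stats.genpareto.rvs(c=0.4, scale=1.0, size=4000, random_state=1)
    k, sigma = _gpd_fit(np.sort(x))
    assert abs(k - 0.4) < 0.1
    assert sigma > 0


def test_psis_khat_recovers_generating_shape():
    """Importance ratios with a generalized-Pareto tail of shape 0.4."""
    r = stats.genpareto.rvs(c=0.4, loc=1.0, scale=1.0, size=50_000, random_state=2)
    w, khat = psis_smooth(np.log(r))
    assert abs(khat - 0.4) < 0.1
    assert w.sum() == pytest.approx(1.0)
    assert (w >= 0).all()


def test_psis_weights_permutation_equivariant():
    rng = np.random.default_rng(3)
    lr = rng.standard_normal(500)
    perm = rng.permutation(500)
    w1, k1 = psis_smooth(lr)
    w2, k2 = psis_smooth(lr[perm])
    np.testing.assert_allclose(w2, w1[perm], rtol=1e-12)
    assert k1 == k2


# ------------------------------------------------------------------- LOO


def test_loo_single_observation_matches_quadrature_oracle():
    """y ~ N(theta, 1), theta ~ N(0, 0.2^2): leaving the single observation
    out, the LOO predictive equals the prior predictive N(0, 1.04)."""
    y = 1.3
    rng = np.random.default_rng(4)
    post_var = 1.0 / (1.0 / 0.04 + 1.0)
    theta = rng.normal(y * post_var, np.sqrt(post_var), size=100_000)  # exact posterior
    ll = stats.norm.logpdf(y, loc=theta, scale=1.0)[:, None]
    res = loo_elpd(ll)
    expected = stats.norm.logpdf(y, loc=0.0, scale=np.sqrt(1.04))
    assert res.elpd == pytest.approx(expected, abs=1e-3)
    assert res.n_obs == 1


def test_loo_additivity_under_duplication(small_vod_fit):
    ll = small_vod_fit.pointwise_loglik()[:, :25]
    base = loo_elpd(ll)
    doubled = loo_elpd(np.hstack([ll, ll]))
    assert doubled.elpd == pytest.approx(2 * base.elpd, rel=1e-10)
    np.testing.assert_allclose(doubled.elpd_pointwise[:25], base.elpd_pointwise)


@pytest.fixture(scope="module")
def low_leverage_fit():
    """Well-specified fit on a deliberately low-leverage design (narrow
    start-distance band, few neighbours), where PSIS is reliable for every
    left-out observation."""
    import warnings

    from fidtol import SamplerSettings, SimulationConfig, ToleranceModel, simulate_dataset
    from fidtol.config import CovariateFrequencies

    cfg = SimulationConfig(
        n_individuals=24, trials_per_observer=8, n_dates=16, seed=3,
        sd_range_m=(8.0, 14.0),
        covariate_frequencies=CovariateFrequencies(neighbor_mean=1.0),
    )
    trials, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ToleranceModel(trials, "vod").fit(
            SamplerSettings(chains=2, iterations=1700, warmup=500, seed=3, min_ess=1, max_rhat=10)
        )


def test_loo_well_specified_fit_has_no_high_khat(low_leverage_fit):
    res = loo_elpd(low_leverage_fit)
    assert res.n_high_k == 0
    assert np.all(np.isfinite(res.pareto_k[np.isfinite(res.pareto_k)]))
    assert res.elpd == pytest.approx(res.elpd_pointwise.sum())


def test_loo_cross_checked_against_arviz(low_leverage_fit):
    import arviz as az

    ours = loo_elpd(low_leverage_fit)
    idata = az.from_dict(
        posterior={"sigma": low_leverage_fit.draws["sigma_vod"]},
        log_likelihood={"y": low_leverage_fit.draws["loglik_vod"]},
    )
    ref = az.loo(idata, pointwise=True)
    assert ours.elpd == pytest.approx(float(ref.elpd_loo), abs=0.3)
    np.testing.assert_allclose(ours.elpd_pointwise, np.asarray(ref.loo_i.values), atol=0.08)
    pk = np.asarray(ref.pareto_k.values, float)
    finite = np.isfinite(ours.pareto_k)
    assert np.abs(ours.pareto_k[finite] - pk[finite]).mean() < 0.1
    assert np.corrcoef(ours.pareto_k[finite], pk[finite])[0, 1] > 0.8


def test_loo_requires_pointwise_matrix():
    with pytest.raises(ValueError):
        loo_elpd(np.zeros((10, 0)))


# -------------------------------------------------------------- stacking


def test_stacking_dominant_model_gets_weight_one():
    rng = np.random.default_rng(5)
    base = rng.normal(-1.0, 0.3, size=60)
    w = stacking_weights([base + 0.5, base])  # model 0 better everywhere
    assert w[0] > 0.999
    assert w.sum() == pytest.approx(1.0)


def test_stacking_tie_rule_uniform():
    elpd = np.random.default_rng(6).normal(size=40)
    w = stacking_weights([elpd, elpd.copy()])
    np.testing.assert_allclose(w, [0.5, 0.5])


def test_stacking_three_models_matches_grid_search():
    rng = np.random.default_rng(7)
    lpd = rng.normal(-1, 0.8, size=(50, 3))
    w = stacking_weights([lpd[:, k] for k in range(3)])

    def objective(wvec):
        return np.sum(logsumexp(lpd + np.log(np.maximum(wvec, 1e-300)), axis=1))

    # exhaustive simplex grid (step 0.001), vectorized in chunks
    c = lpd.max(axis=1, keepdims=True)
    dens = np.exp(lpd - c)
    grid = np.round(np.arange(0, 1.0005, 0.001), 3)
    best, best_w = -np.inf, None
    for w1 in grid:
        w2 = grid[grid <= 1.0 - w1 + 1e-12]
        W = np.column_stack([np.full_like(w2, w1), w2, 1.0 - w1 - w2])
        vals = np.log(np.clip(dens @ W.T, 1e-300, None)).sum(axis=0)
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_w = vals[i], W[i]
    assert np.max(np.abs(w - best_w)) < 0.01
    # local optimality: no pure-model vertex beats the returned weights
    assert objective(w) >= max(objective(np.eye(3)[k]) for k in range(3)) - 1e-9


def test_stacking_rejects_mismatched_observations():
    with pytest.raises(ValueError):
        stacking_weights([np.zeros(10), np.zeros(11)])


def test_identity_comparison_report(small_trials, quick_settings, small_vod_fit):
    trials, _ = small_trials
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = compare_identity_models(trials, response="vod", settings=quick_settings, fit_with=small_vod_fit)
    assert comp.weight_with + comp.weight_without == pytest.approx(1.0)
    d = comp.to_dict()
    assert set(d) == {"response", "with_identity", "without_identity"}
    assert d["with_identity"]["n_obs"] == len(trials)
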