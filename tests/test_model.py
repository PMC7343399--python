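import warnings

import numpy as np
import pytest

from fidtol import (
    BivariateToleranceModel,
    SamplerSettings,
    SimulationConfig,
    ToleranceModel,
    simulate_dataset,
    split_by_trial_parity,
)
from fidtol.config import VOD_FIXED_TERMS
from fidtol.model import ConvergenceWarning, ToleranceResults, _BlockInfo


def _synthetic_results(beta_by_chain, sigma=0.3, n_rows=40, seed=0, min_ess=0.0, max_rhat=10.0, quiet=True):
    """Build a ToleranceResults directly from given fixed-effect draws."""
    rng = np.random.default_rng(seed)
    chains, kept, p = beta_by_chain.shape
    assert p == len(VOD_FIXED_TERMS)
    X = np.column_stack(
        [
            np.ones(n_rows),
            rng.uniform(0, 20, n_rows),  # VODD
            rng.integers(0, 2, n_rows),
            rng.integers(0, 2, n_rows),
            rng.integers(0, 2, n_rows),
            rng.integers(0, 2, n_rows),
            rng.poisson(1.5, n_rows),
            rng.integers(0, 2, n_rows),
            rng.integers(0, 2, n_rows),
            rng.integers(0, 2, n_rows),
            rng.integers(1, 13, n_rows),
            np.zeros(n_rows),
        ]
    ).astype(float)
    draws = {
        "beta_vod": beta_by_chain,
        "sigma_vod": np.full((chains, kept), sigma),
    }
    info = _BlockInfo(
        name="vod", x_names=VOD_FIXED_TERMS, z_names=(), n_obs=n_rows, n_dates=0,
        u_offset=0, q=0, X=X, Z=None,
    )
    settings = SamplerSettings(
        chains=chains, iterations=kept + 1, warmup=1, seed=0, min_ess=min_ess, max_rhat=max_rhat
    )
    if not quiet:
        return ToleranceResults(draws, [info], (), settings, [])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ToleranceResults(draws, [info], (), settings, [])


def test_summary_table_layout(small_vod_fit):
    s = small_vod_fit.summary()
    pop = s[s.group == "Population-level"]
    assert len(pop) == 12  # intercept + 11 terms including the interaction
    assert list(pop["parameter"]) == list(VOD_FIXED_TERMS)
    # sd(Intercept) appears under both the date and the individual group
    sd_groups = s[s.parameter == "sd(Intercept)"]["group"].tolist()
    assert any(g.startswith("Date") for g in sd_groups)
    assert any(g.startswith("Individual identity") for g in sd_groups)
    assert (s["l-95% CI"] <= s["u-95% CI"]).all()
    assert set(["Estimate", "Est. error", "Rhat", "Bulk_ESS", "Tail_ESS"]) <= set(s.columns)


def test_draw_count_contract(small_vod_fit, quick_settings):
    assert small_vod_fit.n_draws == quick_settings.chains * quick_settings.kept
    ll = small_vod_fit.pointwise_loglik()
    assert ll.shape == (small_vod_fit.n_draws, small_vod_fit.blocks[0].n_obs)


def test_convergence_flag_iff_thresholds():
    rng = np.random.default_rng(1)
    good = _synthetic_results(rng.standard_normal((2, 400, 12)), min_ess=50, max_rhat=1.05)
    assert good.converged
    stuck = np.zeros((2, 400, 12))
    stuck[1] += 5.0  # chains disagree -> Rhat blows up
    with pytest.warns(ConvergenceWarning):
        bad = _synthetic_results(
            stuck + 0.01 * rng.standard_normal((2, 400, 12)), min_ess=50, max_rhat=1.05, quiet=False
        )
    assert not bad.converged
    assert np.isfinite(bad.diagnostics["rhat"]).all()


def test_conditional_effects_parallel_when_interaction_zero():
    """With the interaction coefficient at zero the two observers' trial
    curves are parallel on the log scale."""
    beta = np.zeros((1, 1, 12))
    beta[..., 0] = 1.0  # intercept
    beta[..., 9] = -0.3  # observer offset
    beta[..., 10] = -0.05  # trial slope
    beta[..., 11] = 0.0  # interaction
    res = _synthetic_results(beta)
    eff = res.conditional_effects()
    fam = eff[eff.observer == "familiar"].sort_values("value")
    unf = eff[eff.observer == "unfamiliar"].sort_values("value")
    gaps = np.log(unf["estimate"].to_numpy()) - np.log(fam["estimate"].to_numpy())
    assert np.allclose(gaps, gaps[0], atol=1e-10)
    # single draw: band collapses onto the estimate
    assert np.allclose(eff["lower"], eff["estimate"]) and np.allclose(eff["upper"], eff["estimate"])


def test_conditional_effects_recovers_monotone_trend():
    """A strongly decreasing generative trial effect shows up as a
    decreasing fitted conditional-effect curve."""
    beta_vod = dict(SimulationConfig().beta_vod)
    beta_vod["Trial number"] = -0.12
    beta_vod["Unfamiliar observer (AB): Trial number"] = 0.0
    cfg = SimulationConfig(
        n_individuals=10, trials_per_observer=6, n_dates=8, beta_vod=beta_vod,
        individual_sds_vod=(0.1, 0.01, 0.01, 0.001, 0.001), seed=17,
    )
    trials, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ToleranceModel(trials, "vod").fit(
            SamplerSettings(chains=2, iterations=500, warmup=200, seed=3, min_ess=1, max_rhat=10)
        )
    eff = fit.conditional_effects()
    fam = eff[eff.observer == "familiar"].sort_values("value")["estimate"].to_numpy()
    assert np.all(np.diff(fam) < 0)


def test_unknown_term_raises(small_vod_fit):
    with pytest.raises(ValueError, match="not in model terms"):
        small_vod_fit.conditional_effects("Moon phase")


def test_bivariate_agrees_with_univariate(small_trials, quick_settings):
    trials, _ = small_trials
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni = ToleranceModel(trials, "vod").fit(quick_settings)
        biv = BivariateToleranceModel(trials).fit(quick_settings)
    su = uni.summary().query("group == 'Population-level'").set_index("parameter")
    sb = biv.summary().query("group == 'Population-level' and response == 'vod'").set_index("parameter")
    for name in VOD_FIXED_TERMS:
        mc = np.hypot(su.loc[name, "Est. error"], sb.loc[name, "Est. error"])
        assert abs(su.loc[name, "Estimate"] - sb.loc[name, "Estimate"]) < 0.9 * mc + 0.02, name


def test_bivariate_on_disjoint_row_sets(small_trials, quick_settings):
    trials, _ = small_trials
    even, odd = split_by_trial_parity(trials)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = BivariateToleranceModel(vod_data=even, fid_data=odd).fit(quick_settings)
    assert len(fit.blocks) == 2
    assert fit.blocks[0].n_obs == len(even) and fit.blocks[1].n_obs == len(odd)
    from fidtol import among_individual_correlation

    corr = among_individual_correlation(fit)
    assert np.all(np.abs(corr.samples) <= 1.0)


def test_tidy_draws_long_format(small_vod_fit):
    tidy = small_vod_fit.tidy_draws()
    assert set(tidy.columns) == {"chain", "draw", "parameter", "value"}
    per_param = tidy.groupby("parameter").size()
    assert (per_param == small_vod_fit.n_draws).all()
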