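import warnings

import numpy as np
import pytest

from fidtol import (
    SamplerSettings,
    SimulationConfig,
    ToleranceModel,
    conditional_modes,
    enhanced_icc,
    hdi,
    simulate_dataset,
    variance_components,
)
from fidtol.variance import VarianceComponents


# ---------------------------------------------------------------- HDI


def test_hdi_constant_samples():
    assert hdi([2.0] * 10) == (2.0, 2.0)


def test_hdi_matches_normal_quantiles():
    x = np.random.default_rng(0).standard_normal(1_000_000)
    lo, hi = hdi(x, 0.95)
    assert abs(lo + 1.96) < 0.02 and abs(hi - 1.96) < 0.02


def test_hdi_contains_required_mass():
    x = np.random.default_rng(1).exponential(size=5001)
    lo, hi = hdi(x, 0.9)
    inside = np.mean((x >= lo) & (x <= hi))
    assert inside >= np.ceil(0.9 * x.size) / x.size - 1e-12
    # skewed distribution: HDI hugs the mode, narrower than the central interval
    q = np.quantile(x, [0.05, 0.95])
    assert (hi - lo) <= (q[1] - q[0])


def test_hdi_cross_checked_against_arviz():
    import arviz as az

    x = np.random.default_rng(2).gamma(3.0, size=20000)
    lo, hi = hdi(x, 0.95)
    ref = az.hdi(x, hdi_prob=0.95)
    assert abs(lo - ref[0]) < 0.05 and abs(hi - ref[1]) < 0.05


def test_hdi_input_validation():
    with pytest.raises(ValueError):
        hdi([1.0])
    with pytest.raises(ValueError):
        hdi([1.0, 2.0], mass=1.5)


# ------------------------------------------------- variance components / ICC


def _const_components(v_ind, v_date, v_fixed, v_res, n=100):
    one = np.ones(n)
    return VarianceComponents(v_ind * one, v_date * one, v_fixed * one, v_res * one, "vod")


def test_icc_closed_form_ratio():
    icc = enhanced_icc(_const_components(0.5, 0.25, 0.0, 0.25))
    assert np.allclose(icc.samples, 0.5)
    assert icc.mean == pytest.approx(0.5)
    assert (icc.hdi_low, icc.hdi_high) == (0.5, 0.5)


def test_icc_zero_individual_variance():
    icc = enhanced_icc(_const_components(0.0, 0.1, 0.2, 0.3))
    assert np.allclose(icc.samples, 0.0)


def test_icc_denominator_options():
    comp = _const_components(0.4, 0.1, 0.3, 0.2)
    full = enhanced_icc(comp).mean
    no_fixed = enhanced_icc(comp, include_fixed=False).mean
    no_both = enhanced_icc(comp, include_fixed=False, include_date=False).mean
    assert full == pytest.approx(0.4 / 1.0)
    assert no_fixed == pytest.approx(0.4 / 0.7)
    assert no_both == pytest.approx(0.4 / 0.6)
    assert full < no_fixed < no_both


def test_icc_excludes_zero_denominator_draws():
    comp = _const_components(0.0, 0.0, 0.0, 0.0, n=10)
    comp.v_individual[5:] = 0.3
    comp.v_residual[5:] = 0.1
    icc = enhanced_icc(comp)
    assert icc.n_excluded == 5
    assert np.allclose(icc.samples, 0.75)


def test_quadratic_form_oracle(small_vod_fit, small_trials):
    """Design-averaged individual variance equals a hand-computed z'Sigma z."""
    trials, _ = small_trials
    vc = variance_components(small_vod_fit)
    b = small_vod_fit.blocks[0]
    s = small_vod_fit.draws["sd_ind"].reshape(-1, 5)
    C = small_vod_fit.draws["corr_ind"].reshape(-1, 5, 5)
    for idx in (0, len(s) // 2):
        Sigma = C[idx] * np.outer(s[idx], s[idx])
        manual = np.mean([z @ Sigma @ z for z in b.Z])
        assert abs(manual - vc.v_individual[idx]) < 1e-10


def test_single_draw_quadratic_form_hand_value():
    """One fabricated draw: intercept SD 0.3, slope SD 0.1, corr 0.5."""
    s = np.array([0.3, 0.1])
    C = np.array([[1.0, 0.5], [0.5, 1.0]])
    Sigma = C * np.outer(s, s)
    rows = np.array([[1.0, 2.0], [1.0, 5.0], [1.0, 11.0]])
    expected = np.mean([z @ Sigma @ z for z in rows])
    # direct expansion: s0^2 + 2*z1*rho*s0*s1 + z1^2*s1^2 averaged
    manual = np.mean([0.09 + 2 * z1 * 0.5 * 0.03 + z1**2 * 0.01 for z1 in (2, 5, 11)])
    assert expected == pytest.approx(manual, abs=1e-12)


def test_intercept_only_variant(small_vod_fit):
    vc = variance_components(small_vod_fit, intercept_only=True)
    s0 = small_vod_fit.draws["sd_ind"].reshape(-1, 5)[:, 0]
    np.testing.assert_allclose(vc.v_individual, s0**2, rtol=1e-12)


def test_icc_invariant_under_response_rescaling(small_trials, quick_settings):
    """Multiplying all distances by a constant shifts the log-scale intercept
    but leaves the ICC unchanged within MC error."""
    trials, _ = small_trials
    scaled = trials.copy()
    for c in ("sd_m", "vod_m", "fid_m", "vodd_m", "vodi_m"):
        scaled[c] = scaled[c] * 2.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = ToleranceModel(trials, "fid").fit(quick_settings)
        f2 = ToleranceModel(scaled, "fid").fit(quick_settings)
    # the envelope covariate also scales; compare intercept-only ICC which is
    # unaffected by covariate-scale bookkeeping
    i1 = enhanced_icc(variance_components(f1, intercept_only=True), include_fixed=False)
    i2 = enhanced_icc(variance_components(f2, intercept_only=True), include_fixed=False)
    assert abs(i1.mean - i2.mean) < 0.12


def test_missing_individual_block_raises(small_trials, quick_settings):
    trials, _ = small_trials
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ToleranceModel(trials, "vod", include_individual=False).fit(quick_settings)
    with pytest.raises(ValueError, match="individual"):
        variance_components(fit)


# ------------------------------------------------------- conditional modes


def test_conditional_modes_count_and_centering(small_vod_fit, small_trials):
    trials, _ = small_trials
    modes = conditional_modes(small_vod_fit)
    assert len(modes) == trials["individual_id"].nunique()
    assert abs(modes["vod_mode"].mean()) < 0.15  # zero-mean random effects


def test_conditional_modes_track_true_intercepts():
    """With strong individual signal, estimated deviations rank-correlate
    with the simulator's true latent intercepts."""
    from scipy.stats import spearmanr

    cfg = SimulationConfig(
        n_individuals=20, trials_per_observer=8, n_dates=12,
        individual_sds_vod=(0.5, 0.02, 0.05, 0.005, 0.005), sigma_vod=0.25, seed=31,
    )
    trials, truth = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ToleranceModel(trials, "vod").fit(
            SamplerSettings(chains=2, iterations=600, warmup=200, seed=3, min_ess=1, max_rhat=10)
        )
    modes = conditional_modes(fit).set_index("individual_id")
    rho = spearmanr(modes["vod_mode"], truth.individual_effects["vod_Intercept"]).statistic
    assert rho >= 0.8


def test_mode_estimator_option(small_vod_fit):
    kde = conditional_modes(small_vod_fit, estimator="mode")
    mean = conditional_modes(small_vod_fit, estimator="mean")
    assert len(kde) == len(mean)
    assert np.corrcoef(kde["vod_mode"], mean["vod_mode"])[0, 1] > 0.9
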