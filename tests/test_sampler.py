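"""Engine-level checks: slice sampler, priors, likelihood, and an
independent ensemble-sampler oracle for the full posterior."""

import numpy as np
import pytest
from scipy import stats

from fidtol import SamplerSettings, SimulationConfig, ToleranceModel, sample_prior, simulate_dataset
from fidtol.sampler import BlockData, run_gibbs, slice_sample


def test_slice_sampler_targets_standard_normal():
    rng = np.random.default_rng(0)
    x, draws = 0.0, []
    logf = lambda v: -0.5 * v * v
    for _ in range(4000):
        x = slice_sample(logf, x, rng)
        draws.append(x)
    draws = np.asarray(draws[500:])
    assert abs(draws.mean()) < 0.08
    assert abs(draws.std() - 1.0) < 0.08


def test_prior_sampling_matches_priors():
    """With no observations the engine's conditionals reduce to the priors."""
    fit = sample_prior("vod", SamplerSettings(chains=2, iterations=2500, warmup=300, seed=11, min_ess=1, max_rhat=10))
    beta = fit.beta_draws()
    assert abs(beta.mean()) < 6.0  # N(0, 100) elementwise
    assert abs(beta.std() - 100.0) < 8.0
    s = fit.draws["sd_ind"].reshape(-1, 5)
    # half-Student-t(3, 10): compare a central quantile (tails are heavy)
    med = np.median(s)
    expected_med = 10.0 * stats.t.ppf(0.75, df=3)  # median of |t3| * scale
    assert abs(med - expected_med) / expected_med < 0.25
    sig = fit.draws["sigma_vod"].reshape(-1)
    assert abs(np.median(sig) - 2.5 * stats.t.ppf(0.75, df=3)) < 1.2


def test_near_deterministic_limit_recovers_coefficients():
    """Tiny noise, no random effects: posterior means land on the truth."""
    eye = [[1.0 if i == j else 0.0 for j in range(5)] for i in range(5)]
    cfg = SimulationConfig(
        n_individuals=12,
        trials_per_observer=4,
        n_dates=8,
        sd_date=0.0,
        individual_sds_vod=(0,) * 5,
        individual_sds_fid=(0,) * 5,
        individual_corr_vod=eye,
        individual_corr_fid=eye,
        cross_response_corr=0.0,
        sigma_vod=0.05,
        sigma_fid=0.05,
        seed=9,
    )
    trials, truth = simulate_dataset(cfg)
    fit = ToleranceModel(trials, "vod").fit(
        SamplerSettings(chains=2, iterations=600, warmup=200, seed=3, min_ess=1, max_rhat=10)
    )
    summ = fit.summary()
    pop = summ[summ.group == "Population-level"].set_index("parameter")
    for name, true_val in truth.beta_vod.items():
        est, err = pop.loc[name, "Estimate"], pop.loc[name, "Est. error"]
        assert abs(est - true_val) < 3 * err + 0.02, name


def test_pointwise_loglik_matches_scipy_lognormal(small_vod_fit, small_trials):
    trials, _ = small_trials
    ll = small_vod_fit.pointwise_loglik()
    # reconstruct a handful of draws' densities independently
    beta = small_vod_fit.beta_draws()
    sigma = small_vod_fit.draws["sigma_vod"].reshape(-1)
    b = small_vod_fit.blocks[0]
    d = small_vod_fit.draws["d_vod"].reshape(-1, small_vod_fit.draws["d_vod"].shape[-1])
    u = small_vod_fit.draws["u"].reshape(-1, *small_vod_fit.draws["u"].shape[-2:])
    from fidtol.design import ModelSpec, build_design_matrices

    dm = build_design_matrices(trials, ModelSpec.vod())
    y = trials["vod_m"].to_numpy()
    for s in (0, ll.shape[0] // 2, ll.shape[0] - 1):
        mu = dm.X @ beta[s] + d[s][dm.date_index] + np.einsum("ij,ij->i", dm.Z, u[s][dm.ind_index])
        expected = stats.lognorm.logpdf(y, s=sigma[s], scale=np.exp(mu))
        np.testing.assert_allclose(ll[s], expected, atol=1e-8)


def test_row_permutation_leaves_posterior_unchanged(small_trials, quick_settings):
    """Shuffling row order changes no posterior summary beyond MC error."""
    trials, _ = small_trials
    rng = np.random.default_rng(0)
    shuffled = trials.sample(frac=1.0, random_state=5).reset_index(drop=True)
    f1 = ToleranceModel(trials, "vod").fit(quick_settings)
    f2 = ToleranceModel(shuffled, "vod").fit(quick_settings)
    s1 = f1.summary().set_index(["group", "parameter"])
    s2 = f2.summary().set_index(["group", "parameter"])
    pop = [i for i in s1.index if i[0] == "Population-level"]
    for idx in pop:
        mc = np.hypot(s1.loc[idx, "Est. error"], s2.loc[idx, "Est. error"])
        assert abs(s1.loc[idx, "Estimate"] - s2.loc[idx, "Estimate"]) < 0.75 * mc + 0.02


def test_posterior_matches_marginalized_ensemble_oracle():
    """Dual-route check of the engine's stationary distribution.

    A small two-response intercept-only mixed model admits an analytically
    marginalized posterior (individual effects integrated out), which an
    affine-invariant ensemble sampler can sample reliably.  The Gibbs
    engine must agree on the among-individual correlation posterior.
    """
    import emcee

    rng = np.random.default_rng(3)
    G, T = 24, 6
    s_v, s_f, r_true = 0.4, 0.6, 0.8
    sig_v, sig_f = 0.3, 0.35
    cov = np.array([[s_v**2, r_true * s_v * s_f], [r_true * s_v * s_f, s_f**2]])
    u = rng.multivariate_normal([0, 0], cov, size=G)
    g = np.repeat(np.arange(G), T)
    yv = 1.0 + u[g, 0] + sig_v * rng.standard_normal(G * T)
    yf = 0.5 + u[g, 1] + sig_f * rng.standard_normal(G * T)

    def blk(name, w):
        n = len(w)
        return BlockData(
            name=name,
            y=np.exp(w),
            X=np.ones((n, 1)),
            x_names=("Intercept",),
            Z=np.ones((n, 1)),
            z_names=("Intercept",),
            ind_index=g.copy(),
            date_index=None,
            n_dates=0,
        )

    draws = run_gibbs([blk("a", yv), blk("b", yf)], n_ind=G, chains=2, iterations=2200, warmup=500, seed=5)
    r_gibbs = draws["corr_ind"][:, :, 0, 1].reshape(-1)

    ybar_v = yv.reshape(G, T).mean(1)
    ybar_f = yf.reshape(G, T).mean(1)
    ss_v = ((yv.reshape(G, T) - ybar_v[:, None]) ** 2).sum()
    ss_f = ((yf.reshape(G, T) - ybar_f[:, None]) ** 2).sum()

    def ht(x, df, sc):
        return -0.5 * (df + 1) * np.log1p(x * x / (df * sc * sc))

    def logpost(th):
        bv, bf, lsv, lsf, lSv, lSf, z = th
        sv, sf, Sv, Sf = np.exp([lsv, lsf, lSv, lSf])
        rho = np.tanh(z)
        C = np.array([[Sv**2 + sv**2 / T, rho * Sv * Sf], [rho * Sv * Sf, Sf**2 + sf**2 / T]])
        sign, ld = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf
        d = np.stack([ybar_v - bv, ybar_f - bf], axis=1)
        quad = np.einsum("gi,ij,gj->", d, np.linalg.inv(C), d)
        ll = (
            -0.5 * G * ld
            - 0.5 * quad
            - G * (T - 1) * np.log(sv)
            - 0.5 * ss_v / sv**2
            - G * (T - 1) * np.log(sf)
            - 0.5 * ss_f / sf**2
        )
        lp = (
            -(bv**2 + bf**2) / (2 * 100**2)
            + ht(sv, 3, 2.5) + lsv + ht(sf, 3, 2.5) + lsf
            + ht(Sv, 3, 10) + lSv + ht(Sf, 3, 10) + lSf
            + np.log1p(-rho**2)  # d rho / d z Jacobian; LKJ(1) on 2x2 is flat
        )
        return ll + lp

    p0 = np.array([1.0, 0.5, np.log(0.3), np.log(0.35), np.log(0.4), np.log(0.6), np.arctanh(0.7)])
    walkers = p0 + 0.05 * rng.standard_normal((24, 7))
    sampler = emcee.EnsembleSampler(24, 7, logpost)
    sampler.run_mcmc(walkers, 2500, progress=False)
    r_oracle = np.tanh(sampler.get_chain(discard=800, thin=4, flat=True)[:, 6])

    assert abs(r_gibbs.mean() - r_oracle.mean()) < 0.05
    for q in (0.1, 0.5, 0.9):
        assert abs(np.quantile(r_gibbs, q) - np.quantile(r_oracle, q)) < 0.07
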