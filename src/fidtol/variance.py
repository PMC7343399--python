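"""Variance decomposition: repeatability (ICC), among-individual correlation,
conditional modes and highest-density intervals.

All variance components live on the latent (log) scale, where the log-normal
mixed model is Gaussian and SDs square to variances directly.  Per posterior
draw:

* ``V_fixed``  — population variance of the fixed-effect linear predictor
  X beta over the fitted rows;
* ``V_individual`` — design-averaged variance contributed by the individual
  block, ``mean_i z_i' Sigma z_i``: random slopes contribute through the
  observed covariate values (an intercept-only variant is available, which
  reduces to sd(Intercept)^2);
* ``V_date`` — date-intercept variance tau^2;
* ``V_residual`` — sigma^2.

The enhanced-agreement ICC for individual identity is the per-draw ratio
``V_individual / (V_individual + V_date + V_fixed + V_residual)``; the date
and fixed-effect terms can be dropped from the denominator via options,
giving the classical ``V_ind / (V_ind + V_res)`` agreement repeatability in
the intercept-only, individual-and-residual variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ToleranceResults


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` samples."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("hdi requires at least 2 finite samples")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class VarianceComponents:
    """Per-draw variance partition of one response on the latent scale."""

    v_individual: np.ndarray
    v_date: np.ndarray
    v_fixed: np.ndarray
    v_residual: np.ndarray
    response: str

    @property
    def n_draws(self) -> int:
        return self.v_individual.size


@dataclass
class IntervalSummary:
    """Posterior samples of a scalar with mean and HDI."""

    samples: np.ndarray
    mean: float
    hdi_low: float
    hdi_high: float
    n_excluded: int
    label: str

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean": self.mean,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "n_draws": int(self.samples.size),
            "n_excluded": self.n_excluded,
        }


ICCResult = IntervalSummary


def variance_components(
    fit: ToleranceResults,
    response: str | None = None,
    intercept_only: bool = False,
) -> VarianceComponents:
    """Extract per-draw variance components for one response of a fit."""
    b = fit._block(response)
    if b.q == 0 or "sd_ind" not in fit.draws:
        raise ValueError("fit has no individual random-effect block")
    beta = fit.beta_draws(b.name if len(fit.blocks) > 1 else None)  # (S, p)
    if b.n_obs:
        lin = beta @ b.X.T
        v_fixed = lin.var(axis=1)  # population variance over fitted rows
    else:
        v_fixed = np.zeros(beta.shape[0])

    cols = slice(b.u_offset, b.u_offset + b.q)
    s = fit.draws["sd_ind"].reshape(-1, fit.draws["sd_ind"].shape[-1])[:, cols]
    corr = fit.draws["corr_ind"].reshape(-1, *fit.draws["corr_ind"].shape[-2:])[:, cols, cols]
    sigma_mat = corr * s[:, :, None] * s[:, None, :]  # (S, q, q)
    if intercept_only or b.n_obs == 0:
        v_ind = sigma_mat[:, 0, 0]
    else:
        zbar = b.Z.T @ b.Z / b.n_obs  # (q, q) average z z'
        v_ind = np.einsum("sjk,jk->s", sigma_mat, zbar)

    key = f"tau_{b.name}"
    if key in fit.draws:
        v_date = fit.draws[key].reshape(-1) ** 2
    else:
        v_date = np.zeros_like(v_ind)
    v_res = fit.draws[f"sigma_{b.name}"].reshape(-1) ** 2
    return VarianceComponents(v_ind, v_date, v_fixed, v_res, response=b.name)


def enhanced_icc(
    components: VarianceComponents,
    include_fixed: bool = True,
    include_date: bool = True,
    mass: float = 0.95,
) -> IntervalSummary:
    """Repeatability of individual identity from a variance partition.

    Per draw, ICC = V_individual / (V_individual + V_date + V_fixed +
    V_residual); the date and fixed terms are included by default (enhanced
    agreement).  Draws with an all-zero denominator are excluded and counted
    rather than propagated as NaN.
    """
    if components.n_draws == 0:
        raise ValueError("empty variance components")
    denom = components.v_individual + components.v_residual
    if include_date:
        denom = denom + components.v_date
    if include_fixed:
        denom = denom + components.v_fixed
    ok = denom > 0
    icc = components.v_individual[ok] / denom[ok]
    assert np.all((icc >= 0) & (icc <= 1.0 + 1e-12))
    lo, hi = hdi(icc, mass)
    return IntervalSummary(
        samples=icc,
        mean=float(icc.mean()),
        hdi_low=lo,
        hdi_high=hi,
        n_excluded=int((~ok).sum()),
        label=f"ICC[{components.response}, individual identity]",
    )


def among_individual_correlation(fit: ToleranceResults, mass: float = 0.95) -> IntervalSummary:
    """Among-individual correlation of the two response intercepts.

    From a bivariate fit's individual covariance draws: per draw,
    r = cov(intercept_vod, intercept_fid) / sqrt(var_vod * var_fid) — the
    covariance standardised to [-1, 1].  Zero-variance draws are excluded
    with a count.
    """
    if len(fit.blocks) != 2 or any(b.q == 0 for b in fit.blocks):
        raise ValueError("among-individual correlation requires a bivariate fit with a shared individual block")
    i0 = fit.blocks[0].u_offset
    i1 = fit.blocks[1].u_offset
    qt = fit.draws["sd_ind"].shape[-1]
    s = fit.draws["sd_ind"].reshape(-1, qt)
    corr = fit.draws["corr_ind"].reshape(-1, qt, qt)
    var0 = s[:, i0] ** 2
    var1 = s[:, i1] ** 2
    cov = corr[:, i0, i1] * s[:, i0] * s[:, i1]
    ok = (var0 > 0) & (var1 > 0)
    r = cov[ok] / np.sqrt(var0[ok] * var1[ok])
    assert np.all(np.abs(r) <= 1.0 + 1e-12)
    r = np.clip(r, -1.0, 1.0)
    lo, hi = hdi(r, mass)
    return IntervalSummary(
        samples=r,
        mean=float(r.mean()),
        hdi_low=lo,
        hdi_high=hi,
        n_excluded=int((~ok).sum()),
        label="among-individual correlation (vod, fid)",
    )


def implied_variance_components(config, trials: pd.DataFrame, response: str = "vod"):
    """Variance components implied by a simulation config on an observed design.

    The generative counterpart of :func:`variance_components`: V_fixed is the
    population variance of the true fixed-effect predictor over the given
    rows, V_individual the design-averaged quadratic form of the true
    individual covariance, V_date and V_residual the squared configured SDs.
    Used to compute the ground-truth ICC a fitted posterior should recover.
    """
    from .design import ModelSpec, build_design_matrices

    spec = ModelSpec.vod() if response == "vod" else ModelSpec.fid()
    dm = build_design_matrices(trials, spec)
    beta_map = config.beta_vod if response == "vod" else config.beta_fid
    beta = np.array([beta_map[t] for t in spec.fixed_terms])
    sds = config.individual_sds_vod if response == "vod" else config.individual_sds_fid
    corr = np.array(config.individual_corr_vod if response == "vod" else config.individual_corr_fid)
    sigma = config.sigma_vod if response == "vod" else config.sigma_fid
    cov = corr * np.outer(sds, sds)
    zbar = dm.Z.T @ dm.Z / len(dm.Z)
    one = np.ones(1)
    return VarianceComponents(
        v_individual=one * float((cov * zbar).sum()),
        v_date=one * config.sd_date**2,
        v_fixed=one * float((dm.X @ beta).var()),
        v_residual=one * sigma**2,
        response=response,
    )


def implied_icc(
    config,
    trials: pd.DataFrame,
    response: str = "vod",
    include_fixed: bool = True,
    include_date: bool = True,
    intercept_only: bool = False,
) -> float:
    """Ground-truth ICC implied by a simulation config on an observed design."""
    vc = implied_variance_components(config, trials, response)
    sds = config.individual_sds_vod if response == "vod" else config.individual_sds_fid
    v_ind = sds[0] ** 2 if intercept_only else float(vc.v_individual[0])
    denom = v_ind + float(vc.v_residual[0])
    if include_date:
        denom += float(vc.v_date[0])
    if include_fixed:
        denom += float(vc.v_fixed[0])
    return v_ind / denom


def _kde_mode(samples: np.ndarray) -> float:
    from scipy.stats import gaussian_kde

    if np.ptp(samples) < 1e-12:
        return float(samples[0])
    kde = gaussian_kde(samples)
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def conditional_modes(
    fit: ToleranceResults,
    trait: str | None = None,
    estimator: str = "mean",
) -> pd.DataFrame:
    """Per-individual intercept-deviation estimates (BLUP analogues).

    ``estimator="mean"`` (default) returns the posterior mean of each
    individual's intercept deviation — the stable choice for MCMC output and
    the Gaussian-case equivalent of the conditional mode; ``"mode"`` locates
    the maximum of a kernel-density estimate instead.
    """
    b = fit._block(trait)
    if b.q == 0 or "u" not in fit.draws:
        raise ValueError(f"fit has no individual deviations for trait {trait!r}")
    if estimator not in ("mean", "mode"):
        raise ValueError("estimator must be 'mean' or 'mode'")
    u = fit.draws["u"].reshape(-1, len(fit.ind_levels), fit.draws["u"].shape[-1])
    col = u[:, :, b.u_offset]  # intercept deviations, (S, G)
    if estimator == "mean":
        est = col.mean(axis=0)
    else:
        est = np.array([_kde_mode(col[:, gi]) for gi in range(col.shape[1])])
    return pd.DataFrame({"individual_id": list(fit.ind_levels), f"{b.name}_mode": est})


def conditional_modes_table(fit: ToleranceResults, estimator: str = "mean") -> pd.DataFrame:
    """Paired per-individual VOD/FID estimates from a bivariate fit
    (scatter-ready: one row per individual)."""
    if len(fit.blocks) != 2:
        raise ValueError("paired conditional modes require a bivariate fit")
    vod = conditional_modes(fit, "vod", estimator)
    fid = conditional_modes(fit, "fid", estimator)
    return vod.merge(fid, on="individual_id")
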