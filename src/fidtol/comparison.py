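"""Predictive model comparison: PSIS-LOO and log-score stacking.

Leave-one-out expected log predictive density (elpd) is estimated from the
pointwise log-likelihood matrix by importance sampling with Pareto-smoothed
weights: for each observation the largest importance ratios are replaced by
expected order statistics of a generalized Pareto distribution (GPD) fitted
to the tail, and the fitted shape k-hat flags observations whose
approximation is unreliable (k-hat > 0.7 by convention).

Stacking combines the Bayesian predictive distributions of several models by
maximising the summed log score of the pointwise LOO predictive densities
over the weight simplex — the recommended combination rule in the M-open
setting.  A model that predicts every point better than its competitors
receives weight 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

DEFAULT_KHAT_THRESHOLD = 0.7


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto shape/scale to exceedances (profile-likelihood
    estimator of Zhang & Stephens 2009 with their weak prior regularisation)."""
    x = np.sort(x)
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1, dtype=float) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x).mean(axis=1)
    logl = n * (np.log(-b / k) - k - 1.0)
    with np.errstate(over="ignore"):
        w = 1.0 / np.exp(logl - logl[:, None]).sum(axis=1)
    w[w < 10 * np.finfo(float).eps] = 0.0
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post  # scale from the unregularised shape
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)  # weak-prior smoothing
    return k_post, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_smooth(log_ratios: np.ndarray, tail_fraction: float = 0.2) -> tuple[np.ndarray, float]:
    """Pareto-smooth one observation's importance ratios.

    Returns ``(weights, khat)`` with weights normalised to sum to 1.  The
    tail is the largest ``min(tail_fraction * S, 3 sqrt(S))`` ratios (floor
    5); a degenerate all-equal tail yields uniform unsmoothed weights and a
    NaN ``khat`` sentinel.
    """
    lr = np.asarray(log_ratios, dtype=float).reshape(-1)
    S = lr.size
    if S < 2 or not np.all(np.isfinite(lr)):
        raise ValueError("psis_smooth needs >= 2 finite log-ratios")
    lw = lr - lr.max()
    M = int(np.ceil(min(tail_fraction * S, 3.0 * np.sqrt(S))))
    M = max(M, 5)
    if M >= S or np.ptp(lr) < 1e-14:
        w = np.exp(lw)
        return w / w.sum(), np.nan
    order = np.argsort(lw)
    tail_idx = order[S - M :]
    cutoff = np.exp(lw[order[S - M - 1]])
    exceed = np.exp(lw[tail_idx]) - cutoff
    if np.ptp(exceed) < 1e-14 or exceed.max() <= 0:
        w = np.exp(lw)
        return w / w.sum(), np.nan
    k, sigma = _gpd_fit(exceed[exceed > 0] if np.any(exceed <= 0) else exceed)
    # replace tail by expected order statistics of the fitted GPD
    p = (np.arange(1, M + 1) - 0.5) / M
    smoothed = cutoff + _gpd_quantile(p, k, sigma)
    smoothed = np.minimum(smoothed, 1.0)  # never above the max ratio (=1 after shift)
    ranks = np.argsort(np.argsort(lw[tail_idx]))
    lw[tail_idx] = np.log(smoothed[ranks])
    w = np.exp(lw)
    return w / w.sum(), float(k)


@dataclass
class LooResult:
    """PSIS-LOO summary: pointwise elpd, Pareto k-hat diagnostics, totals."""

    elpd_pointwise: np.ndarray
    pareto_k: np.ndarray
    elpd: float
    se: float
    n_high_k: int
    khat_threshold: float
    n_obs: int
    n_draws: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "elpd_loo": self.elpd,
            "se": self.se,
            "n_obs": self.n_obs,
            "n_draws": self.n_draws,
            "n_khat_above_threshold": self.n_high_k,
            "khat_threshold": self.khat_threshold,
        }


def loo_elpd(fit_or_loglik, response: str | None = None, khat_threshold: float = DEFAULT_KHAT_THRESHOLD,
             label: str = "") -> LooResult:
    """PSIS-LOO from a fitted model (or a draws x observations matrix).

    Importance ratios for observation i are 1/p(y_i | theta_s); after Pareto
    smoothing, elpd_i = log sum_s w_s p(y_i | theta_s).
    """
    if isinstance(fit_or_loglik, np.ndarray):
        ll = fit_or_loglik
    else:
        ll = fit_or_loglik.pointwise_loglik(response)
    if ll.ndim != 2 or ll.shape[1] == 0:
        raise ValueError("pointwise log-likelihood matrix (draws x observations) required")
    S, n = ll.shape
    elpd_i = np.empty(n)
    khat = np.empty(n)
    for i in range(n):
        w, k = psis_smooth(-ll[:, i])
        elpd_i[i] = logsumexp(ll[:, i], b=w)
        khat[i] = k
    finite_k = khat[np.isfinite(khat)]
    n_high = int((finite_k > khat_threshold).sum())
    total = float(elpd_i.sum())
    se = float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    return LooResult(elpd_i, khat, total, se, n_high, khat_threshold, n, S, label)


def stacking_weights(loo_results, gtol: float = 1e-8) -> np.ndarray:
    """Log-score stacking weights over the simplex.

    Maximises ``sum_i log sum_k w_k exp(elpd_ik)`` (a concave problem) via a
    softmax parameterisation.  Models with identical pointwise elpd leave the
    objective flat; the documented tie rule returns uniform weights.
    """
    mats = [r.elpd_pointwise if isinstance(r, LooResult) else np.asarray(r, float) for r in loo_results]
    K = len(mats)
    if K < 2:
        raise ValueError("stacking requires at least two models")
    n = mats[0].size
    if any(m.size != n for m in mats):
        raise ValueError("all models must share the same observation set")
    lpd = np.column_stack(mats)  # (n, K)
    if np.allclose(lpd, lpd[:, [0]], atol=1e-12):
        return np.full(K, 1.0 / K)
    c = lpd.max(axis=1, keepdims=True)
    dens = np.exp(lpd - c)  # (n, K), scaled predictive densities

    def neg_obj(theta):
        w = softmax(np.append(theta, 0.0))
        mix = dens @ w
        f = -np.sum(np.log(mix))
        grad_w = -(dens / mix[:, None]).sum(axis=0)
        jac = -np.outer(w[:-1], w)  # d w_k / d theta_i, shape (K-1, K)
        jac[np.arange(K - 1), np.arange(K - 1)] += w[:-1]
        return f, jac @ grad_w

    best = None
    for start in [np.zeros(K - 1)] + [np.full(K - 1, v) for v in (-2.0, 2.0)]:
        res = minimize(neg_obj, start, jac=True, method="BFGS", options={"gtol": gtol, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    w = softmax(np.append(best.x, 0.0))
    w[w < 1e-12] = 0.0
    return w / w.sum()


@dataclass
class IdentityComparison:
    """Stacking report for the with/without-individual-identity pair."""

    response: str
    loo_with: LooResult
    loo_without: LooResult
    weight_with: float
    weight_without: float

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "with_identity": {**self.loo_with.to_dict(), "weight": self.weight_with},
            "without_identity": {**self.loo_without.to_dict(), "weight": self.weight_without},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def compare_identity_models(
    data,
    response: str = "vod",
    settings=None,
    fit_with=None,
) -> IdentityComparison:
    """Fit the maximal model and its identity-free counterpart; stack them.

    ``fit_with`` may pass an already-fitted maximal model to avoid refitting.
    The returned weights answer whether individual identity is predictive:
    dominance of the with-identity model (weight near 1) indicates it
    predicts held-out trials consistently better.
    """
    from .model import ToleranceModel

    if fit_with is None:
        fit_with = ToleranceModel(data, response=response, include_individual=True).fit(settings)
    fit_without = ToleranceModel(data, response=response, include_individual=False).fit(settings)
    loo_w = loo_elpd(fit_with, label=f"{response} with identity")
    loo_wo = loo_elpd(fit_without, label=f"{response} without identity")
    w = stacking_weights([loo_w, loo_wo])
    return IdentityComparison(response, loo_w, loo_wo, float(w[0]), float(w[1]))
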