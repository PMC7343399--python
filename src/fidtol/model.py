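"""Log-normal hierarchical models for visual-orientation and flight distances.

The public surface follows the Model -> Results convention: construct a
:class:`ToleranceModel` (one response) or :class:`BivariateToleranceModel`
(both responses, shared individual block) from a trial table, call ``fit()``,
and read estimates, uncertainties and diagnostics off the returned
:class:`ToleranceResults`.

Model for response y (VOD or FID, metres), on the log scale:

    log y ~ Normal(X beta + Z u_ind + d_date, sigma)

with treatment-coded fixed effects (envelope covariate, behavioural
compatibility/engagement, habitat, height, neighbour count, neighbour
flight, external events, observer, trial number, observer x trial number), a
date random intercept, and a correlated 5-term individual random-effect
block (intercept, envelope slope, observer, trial number, observer x trial
number).  Priors: Normal(0, 100) on fixed effects, half-Student-t(3, 10) on
random-effect SDs, LKJ(1) on the correlation matrix, half-Student-t(3, 2.5)
on the residual SD.  The bivariate model stacks the VOD and FID blocks on a
shared 10-term individual block, estimating all cross-response correlations
(in particular the correlation of the two intercepts, the convergent-
validity quantity).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SamplerSettings
from .design import DesignMatrices, ModelSpec, build_design_matrices
from .sampler import BETA_PRIOR_SD, RANEF_SD_PRIOR, SIGMA_PRIOR, BlockData, run_gibbs


class ConvergenceWarning(UserWarning):
    pass


def _rhat_ess(series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Split-Rhat and bulk/tail ESS for scalar chains via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={k: v for k, v in series.items()})
        rhat = az.rhat(idata)
        bulk = az.ess(idata, method="bulk")
        tail = az.ess(idata, method="tail")
    rows = []
    for k in series:
        r = float(rhat[k].values)
        rows.append(
            {
                "parameter": k,
                "rhat": r if np.isfinite(r) else 1.0,  # constant series -> no spread
                "ess_bulk": float(bulk[k].values),
                "ess_tail": float(tail[k].values),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class _BlockInfo:
    name: str
    x_names: tuple[str, ...]
    z_names: tuple[str, ...]
    n_obs: int
    n_dates: int
    u_offset: int
    q: int
    X: np.ndarray
    Z: np.ndarray | None
    notes: list[str] = field(default_factory=list)


class ToleranceResults:
    """Posterior draws, diagnostics and summaries for a fitted model.

    Draw arrays are keyed by parameter with leading (chain, draw) dimensions;
    ``pointwise_loglik(response)`` exposes the (draws x observations) log-
    normal log-density matrix used for cross-validation.
    """

    def __init__(
        self,
        draws: dict[str, np.ndarray],
        blocks: list[_BlockInfo],
        ind_levels: tuple[str, ...],
        settings: SamplerSettings,
        notes: list[str],
    ):
        self.draws = draws
        self.blocks = blocks
        self.ind_levels = ind_levels
        self.settings = settings
        self.notes = list(notes)
        self.sampler_meta = {
            "chains": settings.chains,
            "iterations": settings.iterations,
            "warmup": settings.warmup,
            "seed": settings.seed,
            "priors": {
                "fixed": f"Normal(0, {BETA_PRIOR_SD:g})",
                "random_sd": f"half-Student-t(df={RANEF_SD_PRIOR[0]:g}, scale={RANEF_SD_PRIOR[1]:g})",
                "correlation": "LKJ(1)",
                "sigma": f"half-Student-t(df={SIGMA_PRIOR[0]:g}, scale={SIGMA_PRIOR[1]:g})",
            },
            "notes": list(notes),
        }
        self._diagnostics: pd.DataFrame | None = None
        self.converged: bool = False
        self._finalize()

    # -------------------------------------------------------------- internals

    def _block(self, response: str | None) -> _BlockInfo:
        if response is None:
            if len(self.blocks) > 1:
                raise ValueError("response must be given for a bivariate fit ('vod' or 'fid')")
            return self.blocks[0]
        for b in self.blocks:
            if b.name == response:
                return b
        raise ValueError(f"fit has no response {response!r}")

    def _scalar_series(self) -> tuple[dict[str, np.ndarray], list[dict]]:
        """Flatten the monitored parameters into named scalar chains."""
        series: dict[str, np.ndarray] = {}
        meta: list[dict] = []
        multi = len(self.blocks) > 1
        for b in self.blocks:
            tag = f"{b.name}_" if multi else ""
            beta = self.draws[f"beta_{b.name}"]
            for i, nm in enumerate(b.x_names):
                key = f"{tag}{nm}"
                series[key] = beta[:, :, i]
                meta.append({"key": key, "response": b.name, "group": "Population-level", "parameter": nm})
            key = f"{tag}Sigma"
            series[key] = self.draws[f"sigma_{b.name}"]
            meta.append({"key": key, "response": b.name, "group": "Family specific (log-normal)", "parameter": "Sigma"})
            if f"tau_{b.name}" in self.draws:
                key = f"{tag}date_sd(Intercept)"
                series[key] = self.draws[f"tau_{b.name}"]
                meta.append(
                    {"key": key, "response": b.name, "group": f"Date ({b.n_dates} levels)", "parameter": "sd(Intercept)"}
                )
        if "sd_ind" in self.draws:
            qt = self.draws["sd_ind"].shape[-1]
            names = self._u_term_names()
            glabel = f"Individual identity ({len(self.ind_levels)} levels)"
            for k in range(qt):
                key = f"ind_sd({names[k]})"
                series[key] = self.draws["sd_ind"][:, :, k]
                meta.append({"key": key, "response": "", "group": glabel, "parameter": f"sd({names[k]})"})
            for i in range(qt):
                for j in range(i + 1, qt):
                    key = f"ind_cor({names[i]},{names[j]})"
                    series[key] = self.draws["corr_ind"][:, :, i, j]
                    meta.append(
                        {"key": key, "response": "", "group": glabel, "parameter": f"cor({names[i]},{names[j]})"}
                    )
        return series, meta

    def _u_term_names(self) -> list[str]:
        names = []
        multi = len(self.blocks) > 1
        for b in self.blocks:
            for t in b.z_names:
                names.append(f"{b.name}_{t}" if multi else t)
        return names

    def _finalize(self) -> None:
        series, meta = self._scalar_series()
        diag = _rhat_ess(series)
        self._param_meta = meta
        self._diagnostics = diag
        max_rhat = float(diag["rhat"].max()) if len(diag) else 1.0
        min_ess = float(diag["ess_bulk"].min()) if len(diag) else np.inf
        self.converged = bool(max_rhat <= self.settings.max_rhat and min_ess >= self.settings.min_ess)
        if not self.converged:
            msg = (
                f"convergence flag not met: max Rhat={max_rhat:.4f} "
                f"(threshold {self.settings.max_rhat}), min bulk ESS={min_ess:.0f} "
                f"(threshold {self.settings.min_ess:.0f})"
            )
            self.notes.append(msg)
            warnings.warn(msg, ConvergenceWarning, stacklevel=3)

    # -------------------------------------------------------------- public API

    @property
    def n_draws(self) -> int:
        return self.settings.chains * self.settings.kept

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self._diagnostics

    def pointwise_loglik(self, response: str | None = None) -> np.ndarray:
        """(total draws x observations) log-normal log density matrix."""
        b = self._block(response)
        key = f"loglik_{b.name}"
        if key not in self.draws:
            raise ValueError("fit was run without storing the pointwise log-likelihood (store_loglik=False)")
        ll = self.draws[key]
        return ll.reshape(-1, ll.shape[-1])

    def beta_draws(self, response: str | None = None) -> np.ndarray:
        b = self._block(response)
        arr = self.draws[f"beta_{b.name}"]
        return arr.reshape(-1, arr.shape[-1])

    def summary(self) -> pd.DataFrame:
        """Model-summary table: one row per monitored parameter.

        Columns follow the conventional layout: posterior mean (Estimate),
        posterior SD (Est. error), central 95% interval, split-Rhat and
        bulk/tail effective sample sizes.
        """
        series, meta = self._scalar_series()
        diag = self._diagnostics
        rows = []
        for m in meta:
            x = series[m["key"]].reshape(-1)
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append(
                {
                    "response": m["response"],
                    "group": m["group"],
                    "parameter": m["parameter"],
                    "Estimate": float(np.mean(x)),
                    "Est. error": float(np.std(x, ddof=1)),
                    "l-95% CI": float(lo),
                    "u-95% CI": float(hi),
                    "Rhat": float(diag.loc[m["key"], "rhat"]),
                    "Bulk_ESS": float(diag.loc[m["key"], "ess_bulk"]),
                    "Tail_ESS": float(diag.loc[m["key"], "ess_tail"]),
                }
            )
        return pd.DataFrame(rows)

    def conditional_effects(
        self,
        term: str = "Unfamiliar observer (AB): Trial number",
        response: str | None = None,
        grid: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Population-level conditional predictions on the response scale.

        Non-focal covariates are held at their reference level (categorical)
        or observed mean (numeric).  The prediction is the log-normal mean
        ``exp(mu + sigma^2/2)`` per posterior draw; the curve reports its
        posterior mean with 2.5/97.5% quantile bands.  The observer x trial
        interaction produces one curve per observer over the trial grid.
        """
        b = self._block(response)
        if term not in b.x_names:
            raise ValueError(f"term {term!r} not in model terms {list(b.x_names)}")
        names = list(b.x_names)
        base = b.X.mean(axis=0) if b.n_obs else np.zeros(len(names))
        # categoricals (0/1 indicator columns) at reference; intercept stays 1
        for i, nm in enumerate(names):
            col = b.X[:, i] if b.n_obs else np.array([0.0])
            is_indicator = np.all(np.isin(np.unique(col), (0.0, 1.0)))
            if nm != "Intercept" and is_indicator:
                base[i] = 0.0
        base[names.index("Intercept")] = 1.0

        i_obs = names.index("Unfamiliar observer (AB)")
        i_tr = names.index("Trial number")
        i_int = names.index("Unfamiliar observer (AB): Trial number")
        rows = []
        if term == "Unfamiliar observer (AB): Trial number":
            tgrid = np.arange(1, 13, dtype=float) if grid is None else np.asarray(grid, float)
            for ob in (0.0, 1.0):
                for t in tgrid:
                    x = base.copy()
                    x[i_obs], x[i_tr], x[i_int] = ob, t, ob * t
                    rows.append(("unfamiliar" if ob else "familiar", t, x))
        else:
            i_term = names.index(term)
            col = b.X[:, i_term]
            if grid is None:
                uniq = np.unique(col)
                if np.all(np.isin(uniq, (0.0, 1.0))):
                    grid = np.array([0.0, 1.0])
                else:
                    grid = np.linspace(col.min(), col.max(), 50)
            for v in np.asarray(grid, float):
                x = base.copy()
                x[i_term] = v
                if term == "Trial number":
                    x[i_int] = x[i_obs] * v
                rows.append((None, v, x))

        beta = self.beta_draws(b.name if len(self.blocks) > 1 else None)
        sigma = self.draws[f"sigma_{b.name}"].reshape(-1)
        out = []
        for label, v, x in rows:
            mu = beta @ x
            pred = np.exp(mu + 0.5 * sigma**2)
            lo, hi = np.quantile(pred, [0.025, 0.975])
            rec = {"term": term, "value": v, "estimate": float(pred.mean()), "lower": float(lo), "upper": float(hi)}
            if label is not None:
                rec["observer"] = label
            out.append(rec)
        return pd.DataFrame(out)

    def tidy_draws(self, include_deviations: bool = False) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table of the draws."""
        series, _ = self._scalar_series()
        if include_deviations and "u" in self.draws:
            names = self._u_term_names()
            for gi, lev in enumerate(self.ind_levels):
                for k, nm in enumerate(names):
                    series[f"r_ind[{lev},{nm}]"] = self.draws["u"][:, :, gi, k]
        frames = []
        for key, arr in series.items():
            C, K = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), K),
                        "draw": np.tile(np.arange(K), C),
                        "parameter": key,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def diagnostics_json(self) -> str:
        payload = {
            "converged": self.converged,
            "max_rhat": float(self._diagnostics["rhat"].max()) if len(self._diagnostics) else None,
            "min_ess_bulk": float(self._diagnostics["ess_bulk"].min()) if len(self._diagnostics) else None,
            "per_parameter": self._diagnostics.reset_index().to_dict(orient="records"),
            "sampler_meta": self.sampler_meta,
        }
        return json.dumps(payload, indent=2)


def _block_from_matrices(name: str, dm: DesignMatrices, ind_index: np.ndarray | None) -> BlockData:
    return BlockData(
        name=name,
        y=dm.y,
        X=dm.X,
        x_names=dm.x_names,
        Z=dm.Z,
        z_names=dm.z_names,
        ind_index=ind_index,
        date_index=dm.date_index,
        n_dates=len(dm.date_levels),
    )


def _fit_blocks(
    blocks: list[BlockData],
    ind_levels: tuple[str, ...],
    settings: SamplerSettings,
    notes: list[str],
) -> ToleranceResults:
    draws = run_gibbs(
        blocks,
        n_ind=len(ind_levels),
        chains=settings.chains,
        iterations=settings.iterations,
        warmup=settings.warmup,
        seed=settings.seed,
        store_loglik=settings.store_loglik,
    )
    infos = [
        _BlockInfo(
            name=b.name,
            x_names=b.x_names,
            z_names=b.z_names,
            n_obs=b.n,
            n_dates=b.n_dates,
            u_offset=b.u_cols.start,
            q=b.q,
            X=b.X,
            Z=b.Z,
        )
        for b in blocks
    ]
    return ToleranceResults(draws, infos, ind_levels, settings, notes)


class ToleranceModel:
    """Univariate log-normal mixed model for one distance response.

    Parameters
    ----------
    data : trial table (one row per approach trial).
    response : "vod" (visual orientation distance) or "fid" (flight
        initiation distance); picks the matching fixed-effect structure.
    include_individual : drop the correlated individual random-effect block
        when False (the identity-free reference model used in predictive
        stacking).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "vod",
        include_individual: bool = True,
        spec: ModelSpec | None = None,
    ):
        self.spec = spec or (ModelSpec.vod(include_individual) if response == "vod" else ModelSpec.fid(include_individual))
        self.data = data
        self.matrices = build_design_matrices(data, self.spec)

    @classmethod
    def from_csv(cls, path, response: str = "vod", **kwargs) -> "ToleranceModel":
        from .simulate import read_trials

        return cls(read_trials(path), response=response, **kwargs)

    def fit(self, settings: SamplerSettings | None = None) -> ToleranceResults:
        settings = settings or SamplerSettings()
        dm = self.matrices
        block = _block_from_matrices(self.spec.response, dm, dm.ind_index)
        return _fit_blocks([block], dm.ind_levels, settings, list(dm.notes))


class BivariateToleranceModel:
    """Joint model of VOD and FID sharing one individual random-effect block.

    Both responses may be fitted on the same trials (default) or on disjoint
    row sets (``vod_data`` / ``fid_data``, e.g. even/odd trial halves for
    split-half validation); individuals are matched by ``individual_id``
    across the two blocks.
    """

    def __init__(
        self,
        data: pd.DataFrame | None = None,
        *,
        vod_data: pd.DataFrame | None = None,
        fid_data: pd.DataFrame | None = None,
    ):
        if data is not None:
            vod_data = fid_data = data
        if vod_data is None or fid_data is None:
            raise ValueError("provide either `data` or both `vod_data` and `fid_data`")
        self.vod_data, self.fid_data = vod_data, fid_data
        self.vod_spec, self.fid_spec = ModelSpec.vod(), ModelSpec.fid()
        self.m_vod = build_design_matrices(vod_data, self.vod_spec)
        self.m_fid = build_design_matrices(fid_data, self.fid_spec)
        self.ind_levels = tuple(sorted(set(self.m_vod.ind_levels) | set(self.m_fid.ind_levels)))
        lookup = {lev: i for i, lev in enumerate(self.ind_levels)}

        def remap(dm: DesignMatrices) -> np.ndarray:
            return np.array([lookup[dm.ind_levels[i]] for i in dm.ind_index], dtype=np.int64)

        self._ind_vod = remap(self.m_vod)
        self._ind_fid = remap(self.m_fid)

    def fit(self, settings: SamplerSettings | None = None) -> ToleranceResults:
        settings = settings or SamplerSettings()
        blocks = [
            _block_from_matrices("vod", self.m_vod, self._ind_vod),
            _block_from_matrices("fid", self.m_fid, self._ind_fid),
        ]
        notes = list(self.m_vod.notes) + list(self.m_fid.notes)
        return _fit_blocks(blocks, self.ind_levels, settings, notes)


def sample_prior(response: str = "vod", settings: SamplerSettings | None = None) -> ToleranceResults:
    """Sample the model's prior by running the engine with no observations.

    Useful for prior-predictive sanity checks: with an empty dataset the
    conditional updates reduce to the priors themselves.
    """
    settings = settings or SamplerSettings()
    spec = ModelSpec.vod() if response == "vod" else ModelSpec.fid()
    p, q = len(spec.fixed_terms), len(spec.individual_terms)
    block = BlockData(
        name=spec.response,
        y=np.zeros(0),
        X=np.zeros((0, p)),
        x_names=tuple(spec.fixed_terms),
        Z=np.zeros((0, q)),
        z_names=tuple(spec.individual_terms),
        ind_index=np.zeros(0, dtype=np.int64),
        date_index=np.zeros(0, dtype=np.int64),
        n_dates=0,
    )
    return _fit_blocks([block], (), settings, ["prior-only sampling (no data)"])
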