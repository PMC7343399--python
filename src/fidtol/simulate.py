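"""Simulate constrained-envelope approach-trial campaigns.

A trial campaign approaches every individual ``trials_per_observer`` times per
observer, at most twice per individual per sampling date.  Each trial records
a start distance (SD), the distance at which the focal animal visually
orients toward the approaching observer (VOD), and the distance at which it
displaces (FID).  By protocol the three are ordered ``0 < FID <= VOD < SD``
(approaches are not started on animals already looking, hence the strict
upper end).  The derived envelope-control covariates are

    VODD = SD - VOD   (distance covered before visual orientation)
    VODI = VOD - FID  (distance covered between orientation and flight)

which are only defined graphically in field protocols; this algebraic reading
is adopted throughout the package.

Responses are generated on the log scale from the same hierarchical structure
the models in :mod:`fidtol.model` fit: fixed covariate effects, a date random
intercept, and a 10-dimensional correlated individual random-effect block
(intercept, envelope-covariate slope, observer contrast, trial number, and
observer x trial number, per response).

The envelope covariate is a function of the response it predicts
(VODD = SD - VOD), so the generative equation is implicit.  Each row is
produced *exactly self-consistently*: with m the non-envelope linear
predictor, c the (fixed + individual) envelope slope and eps the residual,
the response solves

    log V = m + eps + c * (SD - V),

which has a unique root in (0, SD) whenever eps < log SD - m.  The envelope
is therefore enforced by truncating eps (vectorized rejection sampling with
a retry cap, then inverse-CDF sampling) and solving the fixed point by
bisection; the emitted covariate equals the generative one exactly, so
fitted models see correctly-specified rows rather than error-contaminated
covariates.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    INDIVIDUAL_TERMS_FID,
    INDIVIDUAL_TERMS_VOD,
    SimulationConfig,
)
from .responses import RESPONSE_CATEGORIES

#: Canonical column order of a trial table (CSV contract).
TRIAL_COLUMNS: tuple[str, ...] = (
    "individual_id",
    "date_id",
    "observer",
    "trial_number",
    "sd_m",
    "vod_m",
    "fid_m",
    "vodd_m",
    "vodi_m",
    "compatibility",
    "engaged",
    "habitat",
    "height",
    "n_neighbors",
    "neighbor_fled_first",
    "external_event_5min",
    "response_category",
)

_BASE_DATE = datetime.date(2017, 10, 2)


class SchedulingError(ValueError):
    """Raised when the trial design cannot be scheduled."""


class EnvelopeTruncationError(RuntimeError):
    """Raised when a row's envelope truncation fails numerically."""


@dataclass
class SimulationTruth:
    """Generative truth returned alongside a simulated dataset.

    ``individual_effects`` is keyed by ``individual_id`` with one column per
    latent term (``vod_Intercept`` ... ``fid_ObserverAB:TrialNo``);
    ``date_effects`` holds the per-date intercepts for each response.
    """

    individual_effects: pd.DataFrame
    date_effects: pd.DataFrame
    beta_vod: dict[str, float]
    beta_fid: dict[str, float]
    config: SimulationConfig

    def to_csv(self, path) -> None:
        self.individual_effects.to_csv(path, index=True)


def _date_labels(n_dates: int) -> list[str]:
    return [(_BASE_DATE + datetime.timedelta(days=3 * k)).isoformat() for k in range(n_dates)]


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Build the balanced trial design (no distance responses yet).

    Every individual receives ``trials_per_observer`` trials per observer,
    numbered 1..T per observer; both observers' trial *k* for an individual
    share a sampling date, so no individual exceeds two trials per date.
    Dates are staggered across individuals to spread daily load.
    Deterministic given ``config.seed``.
    """
    T = config.trials_per_observer
    if config.n_dates < T:
        raise SchedulingError(
            f"infeasible schedule: n_dates={config.n_dates} < trials_per_observer={T}; "
            "the two-approaches-per-day cap requires at least one date per trial pair"
        )
    labels = _date_labels(config.n_dates)
    ndigits = max(2, len(str(config.n_individuals)))
    rows = []
    for i in range(config.n_individuals):
        ind = f"ID{i + 1:0{ndigits}d}"
        date_idx = sorted((i + k * max(1, config.n_dates // T)) % config.n_dates for k in range(T))
        for k in range(T):
            for obs in config.observers:
                rows.append((ind, labels[date_idx[k]], obs, k + 1))
    df = pd.DataFrame(rows, columns=["individual_id", "date_id", "observer", "trial_number"])

    rng = np.random.default_rng([config.seed, 0])
    n = len(df)
    freq = config.covariate_frequencies
    compat_levels = ("engaged", "looking", "not_engaged_not_looking")
    probs = np.array([freq.compatibility[c] for c in compat_levels])
    df["sd_m"] = rng.uniform(*config.sd_range_m, size=n)
    df["compatibility"] = np.array(compat_levels)[rng.choice(3, size=n, p=probs / probs.sum())]
    df["engaged"] = df["compatibility"] == "engaged"
    df["habitat"] = np.where(rng.random(n) < freq.p_open, "open", "closed")
    df["height"] = np.where(rng.random(n) < freq.p_ground, "ground", "above_ground")
    df["n_neighbors"] = rng.poisson(freq.neighbor_mean, size=n)
    df["neighbor_fled_first"] = (rng.random(n) < freq.p_neighbor_fled_first) & (df["n_neighbors"] > 0)
    df["external_event_5min"] = rng.random(n) < freq.p_external_event
    return df


def _truncated_noise(
    rng: np.random.Generator,
    sigma: float,
    upper: np.ndarray,
    max_retries: int,
) -> np.ndarray:
    """Draw N(0, sigma) residuals truncated to (-inf, upper) per row.

    Vectorized rejection with a retry cap, then an inverse-CDF fallback for
    rows still violating the bound.  Raises ``EnvelopeTruncationError`` when
    the admissible region has numerically vanishing mass.
    """
    if sigma == 0.0:
        if np.any(upper <= 0):
            bad = int(np.argmax(upper <= 0))
            raise EnvelopeTruncationError(
                f"degenerate draw exceeds envelope at row {bad}: linear predictor is "
                f"{-upper[bad]:.4f} above the log upper bound with sigma=0"
            )
        return np.zeros_like(upper)
    x = sigma * rng.standard_normal(upper.shape)
    bad = x >= upper
    tries = 0
    while bad.any() and tries < max_retries:
        x[bad] = sigma * rng.standard_normal(int(bad.sum()))
        bad = x >= upper
        tries += 1
    if bad.any():
        p_upper = stats.norm.cdf(upper[bad] / sigma)
        if np.any(p_upper <= 1e-300):  # admissible mass numerically vanished
            i = int(np.flatnonzero(bad)[np.argmin(p_upper)])
            raise EnvelopeTruncationError(
                f"truncation failed after {max_retries} retries at row {i}: "
                f"sigma={sigma:.4f}, admissible residual mass {p_upper.min():.3e} "
                f"below bound {upper[i]:.4f}"
            )
        u = rng.uniform(size=p_upper.shape)
        x[bad] = sigma * stats.norm.ppf(u * p_upper)
        x[bad] = np.minimum(x[bad], upper[bad] - 1e-12)
    return x


def _solve_envelope_response(
    m_eps: np.ndarray,
    slope: np.ndarray,
    upper: np.ndarray,
    enforce: bool,
) -> np.ndarray:
    """Solve ``log V = m_eps + slope * (upper - V)`` for V by bisection.

    ``g(V) = log V - m_eps - slope*(upper - V)`` rises from -inf and has
    exactly one sign change below any bracket where g > 0; with the envelope
    enforced ``g(upper) > 0`` by the residual truncation, giving a unique
    root in (0, upper).  Without enforcement (diagnostic mode) the implicit
    equation need not have a solution, so the envelope term is evaluated at
    a one-step draft response instead — exact whenever the envelope slope is
    zero, which is the intended diagnostic configuration.
    """
    if not enforce:
        draft = np.exp(m_eps)
        return np.exp(m_eps + slope * (upper - draft))

    def g(v):
        return np.log(v) - m_eps - slope * (upper - v)

    hi = upper.astype(float).copy()
    lo = np.full_like(hi, 1e-300)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        neg = g(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a full trial table plus the generative truth behind it.

    Returns ``(trials, truth)``.  With ``config.enforce_envelope`` (default)
    every row satisfies ``0 < fid_m <= vod_m < sd_m``; disabling it skips the
    truncation step (diagnostic use only, e.g. moment checks against the
    untruncated log-normal).
    """
    design = build_design(config)
    n = len(design)
    rng_eff = np.random.default_rng([config.seed, 1])
    rng_vod = np.random.default_rng([config.seed, 2])
    rng_fid = np.random.default_rng([config.seed, 3])
    rng_resp = np.random.default_rng([config.seed, 4])

    ind_levels = sorted(design["individual_id"].unique())
    date_levels = sorted(design["date_id"].unique())
    g = pd.Categorical(design["individual_id"], categories=ind_levels).codes
    j = pd.Categorical(design["date_id"], categories=date_levels).codes

    cov = config.joint_individual_cov()
    # u: (G, 10), VOD terms in columns 0-4, FID terms in columns 5-9
    dmax = float(np.max(np.diag(cov)))
    if dmax == 0.0:
        u = np.zeros((len(ind_levels), 10))
    else:
        L = np.linalg.cholesky(cov + (1e-12 * dmax) * np.eye(10))
        u = rng_eff.standard_normal((len(ind_levels), 10)) @ L.T
    d_vod = config.sd_date * rng_eff.standard_normal(len(date_levels))
    d_fid = config.sd_date * rng_eff.standard_normal(len(date_levels))

    obs = (design["observer"] == config.observers[1]).to_numpy(float)
    tr = design["trial_number"].to_numpy(float)
    sd_m = design["sd_m"].to_numpy()
    log_sd = np.log(sd_m)
    inf = np.full(n, np.inf)

    bv = config.beta_vod
    base_vod = (
        bv["Intercept"]
        + bv["Looking"] * (design["compatibility"] == "looking").to_numpy(float)
        + bv["Not engaged not looking"] * (design["compatibility"] == "not_engaged_not_looking").to_numpy(float)
        + bv["Open (Habitat)"] * (design["habitat"] == "open").to_numpy(float)
        + bv["Ground (Height)"] * (design["height"] == "ground").to_numpy(float)
        + bv["Number of neighbors"] * design["n_neighbors"].to_numpy(float)
        + bv["Neighbor flee first"] * design["neighbor_fled_first"].to_numpy(float)
        + bv["External factors within 5 min"] * design["external_event_5min"].to_numpy(float)
        + bv["Unfamiliar observer (AB)"] * obs
        + bv["Trial number"] * tr
        + bv["Unfamiliar observer (AB): Trial number"] * obs * tr
        + u[g, 0] + u[g, 2] * obs + u[g, 3] * tr + u[g, 4] * obs * tr
        + d_vod[j]
    )
    # envelope (V < SD) is equivalent to eps < log SD - base; truncate the
    # residual, then solve the self-consistent response
    eps_bound_v = (log_sd - base_vod) if config.enforce_envelope else inf
    eps_v = _truncated_noise(rng_vod, config.sigma_vod, eps_bound_v, config.max_retries)
    slope_v = bv["VODD"] + u[g, 1]
    vod = _solve_envelope_response(base_vod + eps_v, slope_v, sd_m, config.enforce_envelope)
    vodd = sd_m - vod  # exact by construction

    bf = config.beta_fid
    base_fid = (
        bf["Intercept"]
        + bf["Engaged"] * design["engaged"].to_numpy(float)
        + bf["Open (Habitat)"] * (design["habitat"] == "open").to_numpy(float)
        + bf["Ground (Height)"] * (design["height"] == "ground").to_numpy(float)
        + bf["Number of neighbors"] * design["n_neighbors"].to_numpy(float)
        + bf["Neighbor flee first"] * design["neighbor_fled_first"].to_numpy(float)
        + bf["External factors within 5 min"] * design["external_event_5min"].to_numpy(float)
        + bf["Unfamiliar observer (AB)"] * obs
        + bf["Trial number"] * tr
        + bf["Unfamiliar observer (AB): Trial number"] * obs * tr
        + u[g, 5] + u[g, 7] * obs + u[g, 8] * tr + u[g, 9] * obs * tr
        + d_fid[j]
    )
    eps_bound_f = (np.log(vod) - base_fid) if config.enforce_envelope else inf
    eps_f = _truncated_noise(rng_fid, config.sigma_fid, eps_bound_f, config.max_retries)
    slope_f = bf["VODI"] + u[g, 6]
    fid = _solve_envelope_response(base_fid + eps_f, slope_f, vod, config.enforce_envelope)
    vodi = vod - fid

    probs = np.array([config.covariate_frequencies.response_probs.get(c, 0.0) for c in RESPONSE_CATEGORIES])
    resp = np.array(RESPONSE_CATEGORIES, dtype=object)[rng_resp.choice(len(probs), size=n, p=probs / probs.sum())]

    trials = design.copy()
    trials["vod_m"] = vod
    trials["fid_m"] = fid
    trials["vodd_m"] = vodd
    trials["vodi_m"] = vodi
    trials["response_category"] = resp
    trials = trials[list(TRIAL_COLUMNS)]

    eff_cols = [f"vod_{t}" for t in INDIVIDUAL_TERMS_VOD] + [f"fid_{t}" for t in INDIVIDUAL_TERMS_FID]
    truth = SimulationTruth(
        individual_effects=pd.DataFrame(u, index=pd.Index(ind_levels, name="individual_id"), columns=eff_cols),
        date_effects=pd.DataFrame(
            {"vod": d_vod, "fid": d_fid}, index=pd.Index(date_levels, name="date_id")
        ),
        beta_vod=dict(bv),
        beta_fid=dict(bf),
        config=config,
    )
    return trials, truth


def split_by_trial_parity(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a trial table into (even trial numbers, odd trial numbers).

    Used for split-half validation: the visual-orientation response is then
    analysed on one half and the flight response on the other, removing any
    shared-trial variance between the two measures.
    """
    if len(data) == 0:
        raise ValueError("cannot split an empty trial table")
    even = data["trial_number"] % 2 == 0
    return data[even].copy(), data[~even].copy()


def validate_trials(data: pd.DataFrame) -> None:
    """Check the trial-table invariants; raise ``ValueError`` on violation."""
    missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    if len(data) == 0:
        return
    fid = data["fid_m"].to_numpy(float)
    vod = data["vod_m"].to_numpy(float)
    sd = data["sd_m"].to_numpy(float)
    if not np.all((0 < fid) & (fid <= vod) & (vod < sd)):
        raise ValueError("envelope violated: rows must satisfy 0 < fid_m <= vod_m < sd_m")
    if not np.allclose(data["vodd_m"], sd - vod, atol=1e-8):
        raise ValueError("vodd_m must equal sd_m - vod_m")
    if not np.allclose(data["vodi_m"], vod - fid, atol=1e-8):
        raise ValueError("vodi_m must equal vod_m - fid_m")
    if (data["trial_number"] < 1).any():
        raise ValueError("trial_number must be >= 1")
    dup = data.duplicated(subset=["individual_id", "observer", "trial_number"])
    if dup.any():
        raise ValueError("each (individual, observer) pair may have at most one row per trial_number")
    if ((data["n_neighbors"] == 0) & data["neighbor_fled_first"]).any():
        raise ValueError("neighbor_fled_first must be False when n_neighbors is 0")


def write_trials(data: pd.DataFrame, path) -> None:
    """Write a trial table as CSV in the canonical column order."""
    data[list(TRIAL_COLUMNS)].to_csv(path, index=False, float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "date_id": str, "observer": str})
    validate_trials(df)
    return df[list(TRIAL_COLUMNS)]
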