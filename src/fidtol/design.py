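"""Model specifications and design-matrix construction.

Treatment contrasts with the field-standard references: *engaged* for the
compatibility variable, *closed* habitat, *above_ground* height, and the
familiar observer.  Column names follow the conventional model-summary row
labels so that fitted tables read like the published style (e.g.
``"Unfamiliar observer (AB)"``, ``"Open (Habitat)"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FID_FIXED_TERMS, INDIVIDUAL_TERMS_FID, INDIVIDUAL_TERMS_VOD, VOD_FIXED_TERMS

_CATEGORY_LEVELS = {
    "compatibility": ("engaged", "looking", "not_engaged_not_looking"),
    "habitat": ("closed", "open"),
    "height": ("above_ground", "ground"),
    "observer": ("familiar", "unfamiliar"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one response model (fixed terms + random structure).

    The envelope covariate (VODD for the visual-orientation model, VODI for
    the flight model) enters both as a fixed effect and as an individual-level
    random slope; the individual block additionally carries random observer,
    trial-number, and observer x trial-number terms, all correlated.
    """

    response: str  # "vod" or "fid"
    fixed_terms: tuple[str, ...]
    individual_terms: tuple[str, ...]
    include_individual: bool = True
    include_date: bool = True

    def __post_init__(self):
        if self.response not in ("vod", "fid"):
            raise ValueError("response must be 'vod' or 'fid'")
        expected = VOD_FIXED_TERMS if self.response == "vod" else FID_FIXED_TERMS
        if tuple(self.fixed_terms) != tuple(expected):
            raise ValueError(f"fixed_terms for {self.response} must be {list(expected)}")

    @classmethod
    def vod(cls, include_individual: bool = True) -> "ModelSpec":
        return cls("vod", VOD_FIXED_TERMS, INDIVIDUAL_TERMS_VOD, include_individual)

    @classmethod
    def fid(cls, include_individual: bool = True) -> "ModelSpec":
        return cls("fid", FID_FIXED_TERMS, INDIVIDUAL_TERMS_FID, include_individual)

    @property
    def response_column(self) -> str:
        return f"{self.response}_m"

    @property
    def envelope_column(self) -> str:
        return "vodd_m" if self.response == "vod" else "vodi_m"


@dataclass
class DesignMatrices:
    """Fixed design matrix plus random-effect index structure for one response."""

    X: np.ndarray
    x_names: tuple[str, ...]
    Z: np.ndarray | None
    z_names: tuple[str, ...]
    ind_index: np.ndarray | None
    ind_levels: tuple[str, ...]
    date_index: np.ndarray | None
    date_levels: tuple[str, ...]
    y: np.ndarray
    notes: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def _check_levels(data: pd.DataFrame, column: str) -> None:
    seen = set(data[column].unique())
    allowed = set(_CATEGORY_LEVELS[column])
    unknown = seen - allowed
    if unknown:
        raise ValueError(
            f"unseen category level(s) {sorted(unknown)} in column {column!r}; "
            f"allowed levels: {sorted(allowed)}"
        )


def build_design_matrices(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build the fixed matrix and random-effect indices for a trial table.

    Raises on unseen category levels; constant (no-variation) columns are
    recorded as notes in the returned structure rather than raised, so fit
    metadata can surface them.
    """
    for col in ("compatibility", "habitat", "height", "observer"):
        _check_levels(data, col)
    required = {spec.response_column, spec.envelope_column, "trial_number", "n_neighbors",
                "neighbor_fled_first", "external_event_5min", "individual_id", "date_id"}
    missing = sorted(required - set(data.columns))
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    if data[list(required)].isna().any().any():
        raise ValueError("missing values in model terms are not supported")

    n = len(data)
    obs = (data["observer"] == "unfamiliar").to_numpy(float)
    tr = data["trial_number"].to_numpy(float)
    env = data[spec.envelope_column].to_numpy(float)

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    if spec.response == "vod":
        cols["VODD"] = env
        cols["Looking"] = (data["compatibility"] == "looking").to_numpy(float)
        cols["Not engaged not looking"] = (data["compatibility"] == "not_engaged_not_looking").to_numpy(float)
    else:
        cols["VODI"] = env
        cols["Engaged"] = (data["compatibility"] == "engaged").to_numpy(float)
    cols["Open (Habitat)"] = (data["habitat"] == "open").to_numpy(float)
    cols["Ground (Height)"] = (data["height"] == "ground").to_numpy(float)
    cols["Number of neighbors"] = data["n_neighbors"].to_numpy(float)
    cols["Neighbor flee first"] = data["neighbor_fled_first"].to_numpy(float)
    cols["External factors within 5 min"] = data["external_event_5min"].to_numpy(float)
    cols["Unfamiliar observer (AB)"] = obs
    cols["Trial number"] = tr
    cols["Unfamiliar observer (AB): Trial number"] = obs * tr

    X = np.column_stack([cols[name] for name in spec.fixed_terms])
    notes = [
        f"constant column (no variation): {name}"
        for name in spec.fixed_terms
        if name != "Intercept" and n > 0 and np.ptp(cols[name]) == 0.0
    ]

    date_levels = tuple(sorted(data["date_id"].unique()))
    date_index = pd.Categorical(data["date_id"], categories=date_levels).codes.astype(np.int64)

    if spec.include_individual:
        ind_levels = tuple(sorted(data["individual_id"].unique()))
        ind_index = pd.Categorical(data["individual_id"], categories=ind_levels).codes.astype(np.int64)
        Z = np.column_stack([np.ones(n), env, obs, tr, obs * tr])
        z_names = spec.individual_terms
        counts = np.bincount(ind_index, minlength=len(ind_levels))
        sparse = [ind_levels[i] for i in np.flatnonzero(counts < 2)]
        if sparse:
            notes.append(f"individuals with < 2 rows (retained under partial pooling): {sparse}")
    else:
        ind_levels, ind_index, Z, z_names = (), None, None, ()

    return DesignMatrices(
        X=X,
        x_names=tuple(spec.fixed_terms),
        Z=Z,
        z_names=tuple(z_names),
        ind_index=ind_index,
        ind_levels=ind_levels,
        date_index=date_index if spec.include_date else None,
        date_levels=date_levels if spec.include_date else (),
        y=data[spec.response_column].to_numpy(float),
        notes=notes,
    )
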