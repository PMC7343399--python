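"""Behavioral-response classification for approach trials.

Each completed approach trial ends with the focal animal producing one of
eight stereotyped behavioral responses (alarm bark, flight to refuge, passive
displacement, ...).  Each response maps onto a hypothesized perceived threat
level: whether the approaching observer is being treated as equivalent to a
predator, to a high-ranking social threat, to a minimal threat, or to no
threat at all.  Tallying responses over a trial campaign gives a qualitative
reading of what the observers *are* to the study animals.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Literal

import pandas as pd

ThreatLevel = Literal["yes", "no", "ambiguous"]

ALARM_BARK = "Alarm bark"
FLIGHT_TO_REFUGE = "Flight direct to refuge (rocks, trees, or cliff)"
RAPID_FLIGHT = "Rapid flight/sprinting response"
GECK_DISPLACEMENT = "Displacement with geck/grimace"
PASSIVE_DISPLACEMENT = "Animal passively displaces"
FLINCH = "Flinch/startled before flight"
NOT_DISPLACED = "Animal is not displaced"
NOT_DISPLACED_THREATENS = "Animal is not displaced and threatens observer"

#: The eight recognised response categories, in fixed tally order.
RESPONSE_CATEGORIES: tuple[str, ...] = (
    ALARM_BARK,
    FLIGHT_TO_REFUGE,
    RAPID_FLIGHT,
    GECK_DISPLACEMENT,
    PASSIVE_DISPLACEMENT,
    FLINCH,
    NOT_DISPLACED,
    NOT_DISPLACED_THREATENS,
)


@dataclass(frozen=True)
class ThreatProfile:
    """Hypothesized threat-level interpretation of one response category.

    ``ambiguous`` preserves entries where the interpretation is explicitly
    uncertain rather than collapsing them to yes/no.
    """

    response_category: str
    equivalent_to_predator: ThreatLevel
    equivalent_to_social_threat: ThreatLevel
    minimal_threat: ThreatLevel
    no_threat: ThreatLevel


_PROFILES: dict[str, ThreatProfile] = {
    p.response_category: p
    for p in (
        ThreatProfile(ALARM_BARK, "yes", "no", "no", "no"),
        ThreatProfile(FLIGHT_TO_REFUGE, "yes", "no", "no", "no"),
        ThreatProfile(RAPID_FLIGHT, "yes", "yes", "no", "no"),
        ThreatProfile(GECK_DISPLACEMENT, "no", "yes", "no", "no"),
        ThreatProfile(PASSIVE_DISPLACEMENT, "no", "yes", "yes", "no"),
        ThreatProfile(FLINCH, "ambiguous", "ambiguous", "ambiguous", "ambiguous"),
        ThreatProfile(NOT_DISPLACED, "no", "ambiguous", "no", "yes"),
        ThreatProfile(NOT_DISPLACED_THREATENS, "no", "no", "no", "yes"),
    )
}

_NORMALIZED = {" ".join(k.split()).casefold(): k for k in _PROFILES}


def _canonical(category: str) -> str:
    key = " ".join(str(category).split()).casefold()
    try:
        return _NORMALIZED[key]
    except KeyError:
        raise ValueError(
            f"unknown response category {category!r}; valid categories are: "
            + "; ".join(RESPONSE_CATEGORIES)
        ) from None


def classify_response(category: str) -> ThreatProfile:
    """Return the threat-level profile for one response category.

    The lookup is case- and whitespace-insensitive; unknown labels raise a
    ``ValueError`` listing the valid categories.
    """
    return _PROFILES[_canonical(category)]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class ResponseTally:
    """Per-category counts and percentages over a trial table.

    ``percentages_defined`` is False for an empty table: counts are then all
    zero and the percentage columns are reported as 0 but carry no meaning.
    """

    table: pd.DataFrame
    total: int
    percentages_defined: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def tally_responses(data: pd.DataFrame) -> ResponseTally:
    """Tally response categories with threat-level annotations.

    Every category is reported (zero counts included).  Exact percentages sum
    to 100; the ``percentage`` column is rounded half-up to two decimals to
    match conventional reporting (e.g. 1637 of 1656 -> 98.85).
    """
    counts = dict.fromkeys(RESPONSE_CATEGORIES, 0)
    for cat in data.get("response_category", pd.Series(dtype=object)):
        counts[_canonical(cat)] += 1
    total = int(sum(counts.values()))
    defined = total > 0
    rows = []
    for cat in RESPONSE_CATEGORIES:
        prof = _PROFILES[cat]
        pct_exact = 100.0 * counts[cat] / total if defined else 0.0
        rows.append(
            {
                "response_category": cat,
                "equivalent_to_predator": prof.equivalent_to_predator,
                "equivalent_to_social_threat": prof.equivalent_to_social_threat,
                "minimal_threat": prof.minimal_threat,
                "no_threat": prof.no_threat,
                "count": counts[cat],
                "percentage": _round_half_up(pct_exact) if defined else 0.0,
                "percentage_exact": pct_exact,
            }
        )
    return ResponseTally(table=pd.DataFrame(rows), total=total, percentages_defined=defined)
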