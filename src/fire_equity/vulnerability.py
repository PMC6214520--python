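"""Bivariate vulnerability score, quadrant classification, representation ratios.

Vulnerability V is the Euclidean distance of a tract from the origin of the
adaptive-capacity x hazard plane,

    V = sqrt((AC - AC_min)^2 + (WHP - WHP_min)^2),

so hazard and adaptive deficit receive equal weight and V grows with distance
from the (AC_min, WHP_min) corner.  One split per axis partitions the plane
into four quadrants; representation ratios then compare each race/ethnicity
group's population share inside a quadrant against the share expected if all
groups were distributed alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidConfigError

QUADRANTS = ("A", "B", "C", "D")


@dataclass
class VulnerabilityParams:
    """Origin offsets and quadrant splits for the AC x WHP plane.

    ``ac_min``/``whp_min`` are the coordinates of the plane's origin (the
    observed minima over the analysis subset by default).  ``ac_split`` and
    ``whp_split`` are the quadrant boundaries; points on a boundary take the
    higher class.
    """

    ac_min: float
    whp_min: float
    ac_split: float
    whp_split: float

    def __post_init__(self):
        if self.ac_min > self.ac_split or self.whp_min > self.whp_split:
            raise InvalidConfigError("splits must not be below the origin offsets")

    @classmethod
    def from_data(
        cls,
        ac,
        whp,
        ac_split: float = 0.5,
        whp_split: float | None = None,
        moderate_threshold: float = 0.4,
    ) -> "VulnerabilityParams":
        """Derive origin offsets from observed minima of the filtered subset.

        Default splits: the midpoint of the percent-rank scale for AC, and the
        midpoint between the moderate threshold and 1 for hazard.
        """
        if whp_split is None:
            whp_split = (moderate_threshold + 1.0) / 2.0
        return cls(float(np.min(ac)), float(np.min(whp)), ac_split, whp_split)


def compute_vulnerability(ac, whp, params: VulnerabilityParams) -> np.ndarray:
    """Euclidean distance from the (ac_min, whp_min) origin; vectorized."""
    ac = np.asarray(ac, dtype=float)
    whp = np.asarray(whp, dtype=float)
    if np.any(ac < params.ac_min):
        raise DataError("ac below ac_min: origin offsets misconfigured")
    if np.any(whp < params.whp_min):
        raise DataError("whp below whp_min: origin offsets misconfigured")
    return np.hypot(ac - params.ac_min, whp - params.whp_min)


def assign_quadrant(ac, whp, params: VulnerabilityParams) -> np.ndarray:
    """Label each (ac, whp) point A-D.

    whp >= whp_split is "high fire potential"; ac >= ac_split is "high
    adaptive deficit" (the index is deficit-oriented: high ac = low capacity).
    (high, low) -> A, (high, high) -> B, (moderate, low) -> C,
    (moderate, high) -> D; boundaries are inclusive upward.
    """
    ac = np.atleast_1d(np.asarray(ac, dtype=float))
    whp = np.atleast_1d(np.asarray(whp, dtype=float))
    high_fire = whp >= params.whp_split
    high_deficit = ac >= params.ac_split
    out = np.where(
        high_fire,
        np.where(high_deficit, "B", "A"),
        np.where(high_deficit, "D", "C"),
    )
    return out


def build_vulnerability_table(
    tract_hazard: pd.DataFrame,
    ac_index: pd.DataFrame,
    params: VulnerabilityParams | None = None,
    moderate_threshold: float = 0.4,
) -> tuple[pd.DataFrame, VulnerabilityParams]:
    """Join tract hazard and AC, compute V and quadrants for the filtered set."""
    merged = tract_hazard.merge(ac_index[["tract_id", "ac"]], on="tract_id", how="inner")
    if merged.empty:
        raise DataError("no tracts shared between hazard and adaptive-capacity tables")
    if params is None:
        params = VulnerabilityParams.from_data(
            merged["ac"], merged["whp"], moderate_threshold=moderate_threshold
        )
    merged["v"] = compute_vulnerability(merged["ac"], merged["whp"], params)
    merged["quadrant"] = assign_quadrant(merged["ac"], merged["whp"], params)
    return merged[["tract_id", "ac", "whp", "v", "quadrant"]], params


def representation_ratios(
    records: pd.DataFrame,
    table: pd.DataFrame,
    group_columns: list[str],
    grand_totals: dict[str, float] | None = None,
    total_column: str = "pop_total",
) -> pd.DataFrame:
    """Per-(quadrant, group) representation ratios against the expected share.

    ratio = population of the group living in the quadrant / the group's
    grand-total population (all tracts, not just the analysis subset).  The
    expected share of a quadrant is its total population over the grand total;
    a group with ratio above the expected share is over-represented there.
    """
    if records.empty:
        raise InvalidConfigError("empty vulnerability record set")
    missing = set(records["tract_id"]) - set(table["tract_id"])
    if missing:
        raise DataError(f"tract(s) missing from attribute table: {sorted(missing)[:5]}")
    if grand_totals is None:
        grand_totals = {g: float(table[g].sum()) for g in group_columns}
    for g in group_columns:
        if grand_totals.get(g, 0) <= 0:
            raise InvalidConfigError(f"group {g!r} has non-positive grand total")
    grand_total_pop = float(table[total_column].sum())

    joined = records.merge(table, on="tract_id", how="left")
    rows = []
    for quadrant in QUADRANTS:
        sub = joined[joined["quadrant"] == quadrant]
        q_pop = float(sub[total_column].sum())
        expected = q_pop / grand_total_pop
        for g in group_columns:
            pop = float(sub[g].sum())
            ratio = pop / grand_totals[g]
            rows.append(
                {
                    "quadrant": quadrant,
                    "group": g.removeprefix("pop_"),
                    "population": pop,
                    "ratio": ratio,
                    "expected_share": expected,
                    "overrepresented": ratio > expected,
                }
            )
    return pd.DataFrame(rows)
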