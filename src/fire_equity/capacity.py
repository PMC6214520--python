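"""Percentile-rank adaptive-capacity index over census-style indicators.

The index follows the Flanagan-style social-vulnerability construction: each
of 13 indicators is ranked across tracts, ranks are converted to percentile
ranks, the 13 percentile ranks are summed per tract, and the sums are
percent-ranked again.  The result is a 0–1 index where 0 marks the tracts with
the greatest capacity to absorb and recover from a wildfire and 1 the least.
Because the inputs are only ever used through their ranks, the index is
invariant to any strictly increasing transform of an indicator and to the
affine scale chosen for the intermediate percentile step (0–1 here, 1–100 in
other conventions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError, InvalidConfigError

DOMAINS = (
    "socioeconomic status",
    "language and education",
    "demographics",
    "housing and transportation",
)


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator column: where it lives, which domain, which direction.

    ``direction`` says how the raw value relates to adaptive capacity:
    ``higher_is_worse`` (e.g. % below poverty) feeds the rank directly;
    ``higher_is_better`` (e.g. per-capita income) is negated before ranking so
    that a larger oriented value always means lower adaptive capacity.
    """

    column: str
    name: str
    domain: str
    direction: str = "higher_is_worse"

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise InvalidConfigError(f"unknown domain {self.domain!r}")
        if self.direction not in ("higher_is_worse", "higher_is_better"):
            raise InvalidConfigError(f"unknown direction {self.direction!r}")


#: Default 13-indicator set across the four domains.  A documented stand-in
#: for an ACS-derived list; fully configurable.
DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("ind_01", "pct_below_poverty", "socioeconomic status"),
    IndicatorSpec("ind_02", "pct_unemployed_16plus", "socioeconomic status"),
    IndicatorSpec("ind_03", "per_capita_income", "socioeconomic status", "higher_is_better"),
    IndicatorSpec("ind_04", "pct_no_hs_diploma", "language and education"),
    IndicatorSpec("ind_05", "pct_limited_english", "language and education"),
    IndicatorSpec("ind_06", "pct_age_65_plus", "demographics"),
    IndicatorSpec("ind_07", "pct_age_17_under", "demographics"),
    IndicatorSpec("ind_08", "pct_disabled", "demographics"),
    IndicatorSpec("ind_09", "pct_single_parent", "demographics"),
    IndicatorSpec("ind_10", "pct_mobile_homes", "housing and transportation"),
    IndicatorSpec("ind_11", "pct_multi_unit_housing", "housing and transportation"),
    IndicatorSpec("ind_12", "pct_renters", "housing and transportation"),
    IndicatorSpec("ind_13", "pct_no_vehicle", "housing and transportation"),
)


def percent_rank(values, ids=None) -> np.ndarray:
    """Percent rank (r - 1)/(N - 1) with average ranks for ties.

    Maps the smallest value to 0 and the largest to 1; tied values share the
    mean of the ranks they span.  A constant vector maps to 0.5 everywhere.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidConfigError("percent_rank needs a 1-D vector of length >= 2")
    if np.isnan(x).any():
        i = int(np.flatnonzero(np.isnan(x))[0])
        label = ids[i] if ids is not None else f"index {i}"
        raise DataError(f"missing value in rank input at {label}")
    ranks = rankdata(x, method="average")
    return (ranks - 1.0) / (x.size - 1.0)


def compute_ac_index(
    table: pd.DataFrame,
    specs: tuple[IndicatorSpec, ...] = DEFAULT_INDICATORS,
    id_column: str = "tract_id",
    percentile_scale: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Build the adaptive-capacity index: rank, percentile, sum, re-rank.

    Parameters
    ----------
    table
        One row per tract with an id column and every spec's column present.
    specs
        Indicator definitions; each oriented by its ``direction``.
    percentile_scale
        (low, high) affine scale for the intermediate percentile ranks.  Any
        positive affine map gives the identical final index (the sums are only
        used through their ranks); exposed so that equivalence is testable.

    Returns
    -------
    DataFrame with ``tract_id``, ``ac`` in [0, 1], a ``rank_sum`` column and
    one ``domain_sum_*`` column per domain.
    """
    if len(table) < 2:
        raise DataError("adaptive-capacity index needs at least 2 tracts")
    missing = [s.column for s in specs if s.column not in table.columns]
    if missing:
        raise InvalidConfigError(f"missing indicator column(s): {', '.join(missing)}")
    lo, hi = percentile_scale
    if hi <= lo:
        raise InvalidConfigError("percentile_scale must be increasing")

    ids = table[id_column].astype(str).to_numpy() if id_column in table.columns else None
    n = len(table)
    raw_ranks = np.empty((n, len(specs)))
    for j, spec in enumerate(specs):
        x = table[spec.column].to_numpy(dtype=float)
        if np.unique(x[~np.isnan(x)]).size <= 1:
            warnings.warn(
                f"indicator {spec.column!r} is constant; all tracts tie on it"
            )
        oriented = -x if spec.direction == "higher_is_better" else x
        if np.isnan(oriented).any():
            i = int(np.flatnonzero(np.isnan(oriented))[0])
            label = ids[i] if ids is not None else f"row {i}"
            raise DataError(f"missing value in {spec.column!r} at {label}")
        raw_ranks[:, j] = rankdata(oriented, method="average")

    # Re-rank the *raw* average-rank sums: half-integers are exact in floating
    # point, so ties survive intact and the result is provably identical under
    # any positive affine percentile scale (the scale only changes the
    # reported intermediate sums below, affinely).
    ac = percent_rank(raw_ranks.sum(axis=1), ids)
    pranks = lo + (hi - lo) * (raw_ranks - 1.0) / (n - 1.0)
    rank_sum = pranks.sum(axis=1)
    out = pd.DataFrame({"ac": ac, "rank_sum": rank_sum})
    if ids is not None:
        out.insert(0, "tract_id", ids)
    for domain in DOMAINS:
        cols = [j for j, s in enumerate(specs) if s.domain == domain]
        key = "domain_sum_" + domain.replace(" ", "_")
        out[key] = pranks[:, cols].sum(axis=1) if cols else 0.0
    return out
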