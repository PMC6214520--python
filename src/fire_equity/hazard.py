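"""Hazard raster handling: rescaling, zonal aggregation, and the moderate-plus filter.

The hazard surface is a regular grid of wildfire-hazard values (continuous or
classed) with a nodata/non-burnable mask.  Tract-level exposure is the mean of
the rescaled hazard over raster cells whose centers fall inside the tract
polygon; non-burnable cells enter that mean as 0 by default, matching the
convention that unburnable land anchors the bottom of the hazard scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import DataError, InvalidConfigError

logger = logging.getLogger(__name__)

#: Ordered hazard classes; "non-burnable" is reserved for tracts whose mean is
#: exactly 0 (all contributing cells unburnable).
HAZARD_CLASSES = ("non-burnable", "very low", "low", "moderate", "high", "very high")

#: Uniform boundaries between the five burnable classes on the [0, 1] scale.
DEFAULT_CLASS_BOUNDS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class HazardRaster:
    """A single-band hazard grid with nodata mask and a minimal geotransform.

    ``values[0, 0]`` is the north-west cell (row order top to bottom, ESRI
    ASCII convention).  ``mask`` is True where a cell is nodata/non-burnable.
    """

    values: np.ndarray
    mask: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    crs_label: str = "local"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidConfigError("raster values must be a non-empty 2-D grid")
        if self.mask.shape != self.values.shape:
            raise InvalidConfigError("mask shape must match values shape")
        if self.cellsize <= 0:
            raise InvalidConfigError("cellsize must be positive")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise DataError("non-finite hazard value in unmasked cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (per column) and y (per row, top to bottom) cell-center coordinates."""
        nrows, ncols = self.shape
        xs = self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return xs, ys

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        nrows, ncols = self.shape
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + ncols * self.cellsize,
            self.yllcorner + nrows * self.cellsize,
        )


def read_ascii_grid(path, crs_label: str = "local") -> HazardRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise DataError(f"ASCII grid header missing '{key}'")
    nodata = header.get("nodata_value", -9999.0)
    body = "\n".join(lines[i:])
    values = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise DataError(
            f"ASCII grid body has {values.size} values, expected {nrows * ncols}"
        )
    values = values.reshape(nrows, ncols)
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    return HazardRaster(
        values, mask, header["xllcorner"], header["yllcorner"],
        header["cellsize"], crs_label, nodata,
    )


def write_ascii_grid(raster: HazardRaster, path) -> None:
    """Write an ESRI ASCII grid (.asc); masked cells become the nodata value."""
    nrows, ncols = raster.shape
    out = np.where(raster.mask, raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner!r}\n")
        fh.write(f"yllcorner {raster.yllcorner!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def rescale_hazard(raster: HazardRaster, in_min: float, in_max: float) -> HazardRaster:
    """Linearly map unmasked hazard values from [in_min, in_max] onto [0, 1].

    Masked (nodata / non-burnable) cells become 0 but keep their mask flag, so
    downstream zonal means can either count them as unburnable land (value 0)
    or exclude them entirely.
    """
    if in_max <= in_min:
        raise InvalidConfigError(f"in_max ({in_max}) must exceed in_min ({in_min})")
    unmasked = raster.values[~raster.mask]
    if unmasked.size:
        bad = (unmasked < in_min) | (unmasked > in_max)
        if bad.any():
            idx = np.argwhere(~raster.mask)[np.flatnonzero(bad)[0]]
            raise DataError(
                f"hazard value {unmasked[np.flatnonzero(bad)[0]]!r} at cell "
                f"(row {idx[0]}, col {idx[1]}) outside [{in_min}, {in_max}]"
            )
    scaled = (raster.values - in_min) / (in_max - in_min)
    scaled = np.where(raster.mask, 0.0, scaled)
    return HazardRaster(
        scaled, raster.mask.copy(), raster.xllcorner, raster.yllcorner,
        raster.cellsize, raster.crs_label, raster.nodata,
    )


def classify_whp(whp: float, bounds: tuple[float, ...] = DEFAULT_CLASS_BOUNDS) -> str:
    """Map a tract-mean hazard in [0, 1] to a named class.

    0 exactly is non-burnable; boundaries are inclusive upward (a value equal
    to a boundary takes the higher class).
    """
    if np.isnan(whp):
        return "missing"
    if whp == 0.0:
        return HAZARD_CLASSES[0]
    k = int(np.searchsorted(np.asarray(bounds), whp, side="right"))
    return HAZARD_CLASSES[1 + k]


def _assign_cells(
    raster: HazardRaster, tracts: list[tuple[str, BaseGeometry]]
) -> np.ndarray:
    """Assign each cell center to at most one tract (index into ``tracts``).

    Cell-center-in-polygon with a half-open boundary convention: a center lying
    on a shared edge belongs to the tract containing the point nudged toward
    the lower-left, so every center is counted exactly once in a tessellation.
    Returns an int array of tract indices, -1 where unassigned.
    """
    xs, ys = raster.cell_centers()
    nrows, ncols = raster.shape
    assignment = np.full((nrows, ncols), -1, dtype=np.int64)
    eps = 1e-6 * raster.cellsize
    for t_idx, (_tid, geom) in enumerate(tracts):
        xmin, ymin, xmax, ymax = geom.bounds
        # candidate columns/rows whose centers fall in the padded bbox
        c0 = int(np.searchsorted(xs, xmin - eps))
        c1 = int(np.searchsorted(xs, xmax + eps))
        ys_asc = ys[::-1]
        r1 = nrows - int(np.searchsorted(ys_asc, ymin - eps))
        r0 = nrows - int(np.searchsorted(ys_asc, ymax + eps))
        if c0 >= c1 or r0 >= r1:
            continue
        sub_rows, sub_cols = np.meshgrid(
            np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
        )
        free = assignment[r0:r1, c0:c1] < 0
        if not free.any():
            continue
        px = xs[sub_cols[free]]
        py = ys[sub_rows[free]]
        inside = shapely.contains_xy(geom, px, py)
        # boundary centers: covered but not strictly inside -> nudge lower-left
        on_edge = ~inside
        if on_edge.any():
            covered = shapely.intersects_xy(geom, px[on_edge], py[on_edge])
            if covered.any():
                nudged = shapely.contains_xy(
                    geom, px[on_edge][covered] - eps, py[on_edge][covered] - eps
                )
                edge_take = np.zeros(on_edge.sum(), dtype=bool)
                edge_take[np.flatnonzero(covered)[nudged]] = True
                inside = inside.copy()
                inside[np.flatnonzero(on_edge)[edge_take]] = True
        take_rows = sub_rows[free][inside]
        take_cols = sub_cols[free][inside]
        assignment[take_rows, take_cols] = t_idx
    return assignment


def zonal_mean(
    raster: HazardRaster,
    tracts: list[tuple[str, BaseGeometry]],
    include_nonburnable: bool = True,
    class_bounds: tuple[float, ...] = DEFAULT_CLASS_BOUNDS,
) -> pd.DataFrame:
    """Per-tract arithmetic mean of hazard over cells whose centers fall inside.

    Parameters
    ----------
    raster
        Rescaled hazard grid ([0, 1] values; masked cells are non-burnable).
    tracts
        ``(tract_id, polygon)`` pairs sharing the raster's coordinate frame.
    include_nonburnable
        If True (default) non-burnable cells contribute 0 to the mean; if
        False they are excluded from both numerator and denominator.

    Returns
    -------
    DataFrame with columns ``tract_id, whp, n_cells, whp_class``.  Tracts with
    no contributing cell centers get ``whp = NaN`` and a warning.
    """
    if not tracts:
        raise InvalidConfigError("empty tract set")
    ids = [t[0] for t in tracts]
    if len(set(ids)) != len(ids):
        raise InvalidConfigError("tract ids are not unique")
    assignment = _assign_cells(raster, tracts)
    usable = assignment >= 0
    if include_nonburnable:
        contributing = usable
    else:
        contributing = usable & ~raster.mask
    if not usable.any():
        raise DataError("no raster cell center falls inside any tract polygon")

    flat = assignment[contributing]
    sums = np.bincount(flat, weights=raster.values[contributing], minlength=len(tracts))
    counts = np.bincount(flat, minlength=len(tracts)).astype(np.int64)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    empty = [ids[i] for i in range(len(tracts)) if counts[i] == 0]
    for tid in empty:
        warnings.warn(f"tract {tid!r} contains no cell centers; whp set to missing")
    return pd.DataFrame(
        {
            "tract_id": ids,
            "whp": means,
            "n_cells": counts,
            "whp_class": [classify_whp(m, class_bounds) for m in means],
        }
    )


def filter_at_least_moderate(records: pd.DataFrame, threshold: float = 0.4) -> pd.DataFrame:
    """Keep tracts whose mean hazard meets or exceeds the moderate threshold.

    Tracts below the threshold lack the minimal wildfire exposure required for
    the vulnerability analysis (this is what drops heavily urbanized areas on
    real data).  The boundary is inclusive.
    """
    if not 0 < threshold <= 1:
        raise InvalidConfigError(f"threshold must be in (0, 1], got {threshold}")
    kept = records[records["whp"] >= threshold].reset_index(drop=True)
    logger.info(
        "moderate-plus filter (threshold %.3f): kept %d of %d tracts",
        threshold, len(kept), len(records),
    )
    if len(kept) < 2:
        raise DataError(
            f"no usable tracts at or above hazard threshold {threshold} "
            f"(kept {len(kept)}, need >= 2)"
        )
    return kept
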