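"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from first principles (scalar
loops, direct formulas) and never call the vectorized implementation paths
they are used to check.
"""

import numpy as np
import pytest
from shapely.geometry import Point

import fire_equity as fe


def morans_i(field: np.ndarray) -> float:
    """Moran's I with rook (4-neighbor) adjacency, direct formula.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with w symmetric 0/1.
    """
    z = field - field.mean()
    horiz = float(np.sum(z[:, :-1] * z[:, 1:]))
    vert = float(np.sum(z[:-1, :] * z[1:, :]))
    n_pairs = z[:, :-1].size + z[:-1, :].size
    s0 = 2.0 * n_pairs
    return (field.size / s0) * (2.0 * (horiz + vert)) / float(np.sum(z * z))


def brute_force_zonal(raster, tracts, include_nonburnable=True):
    """Per-cell scalar-loop zonal mean with the lower-left half-open rule.

    Each cell center is tested against every polygon with scalar shapely
    predicates: strictly-inside wins; a center on a boundary belongs to the
    polygon that contains the point nudged toward the lower-left.
    """
    xs, ys = raster.cell_centers()
    eps = 1e-6 * raster.cellsize
    sums = {tid: 0.0 for tid, _ in tracts}
    counts = {tid: 0 for tid, _ in tracts}
    nrows, ncols = raster.shape
    for i in range(nrows):
        for j in range(ncols):
            if not include_nonburnable and raster.mask[i, j]:
                continue
            p = Point(xs[j], ys[i])
            owner = None
            for tid, geom in tracts:
                if geom.contains(p):
                    owner = tid
                    break
                if geom.intersects(p) and geom.contains(
                    Point(xs[j] - eps, ys[i] - eps)
                ):
                    owner = tid
                    break
            if owner is not None:
                sums[owner] += raster.values[i, j]
                counts[owner] += 1
    return {
        tid: (sums[tid] / counts[tid] if counts[tid] else float("nan"), counts[tid])
        for tid, _ in tracts
    }


def random_table(rng, n=50, n_groups=3):
    """A random census-like attribute table with 13 indicator columns."""
    import pandas as pd

    table = pd.DataFrame({"tract_id": [f"t{i:04d}" for i in range(n)]})
    shares = rng.dirichlet(np.ones(n_groups), size=n)
    totals = rng.integers(500, 8000, size=n)
    table["pop_total"] = totals
    for g in range(n_groups):
        table[f"pop_g{g}"] = np.round(shares[:, g] * totals).astype(int)
    for spec in fe.DEFAULT_INDICATORS:
        table[spec.column] = rng.normal(size=n)
    return table


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic world used by several integration tests."""
    return fe.SimConfig(
        seed=11, raster_shape=(60, 60), n_tracts_x=12, n_tracts_y=12,
        smoothing_radius=3.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return fe.generate_bundle(small_config)
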