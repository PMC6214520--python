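"""Synthetic hazard landscapes and census-like tract tables with known truth.

Real inputs for this analysis are a national wildfire-hazard raster and
census-tract socioeconomic tables; neither ships with the package.  This
module generates stand-ins with fully known generative structure so that
every downstream stage — zonal aggregation, the adaptive-capacity index, the
vulnerability score, the quantile regressions — can be tested against a
recoverable ground truth:

* a spatially autocorrelated hazard field in [0, 1] (smoothed Gaussian noise,
  min-max normalized) with a configurable non-burnable fraction;
* a rectangular tract tessellation of the raster extent;
* Dirichlet race/ethnicity compositions per tract;
* a scalar latent-disadvantage variable with an exactly-injected sample
  correlation to tract hazard, driving 13 indicator columns through
  per-indicator loadings and noise;
* a heteroscedastic (x, y) scenario whose conditional quantile lines are
  known in closed form, for direct quantile-regression recovery tests;
* optionally, a majority-group composition assignment constructed so that
  majority-group tracts carry a chosen multiple of the mean vulnerability of
  the remaining tracts.

The generator emulates the *structure* of census/hazard data (coupled
indicators, compositional demographics, spatial autocorrelation), not its
margins: tract population sizes, indicator marginal distributions and the
spatial layout of real communities are deliberately simplified.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm
from shapely.geometry import Polygon, box, mapping

from . import capacity, hazard, vulnerability
from .errors import InvalidConfigError

DEFAULT_GROUPS = (
    "white", "black", "hispanic", "native_american", "asian_pacific", "other",
)


@dataclass
class HeteroscedasticParams:
    """y = beta0 + beta1*x + (sigma0 + sigma1*x)*eps, eps ~ N(0,1), x ~ U(0,1).

    The true conditional quantile line at level tau has slope
    beta1 + sigma1*z_tau and intercept beta0 + sigma0*z_tau, with z_tau the
    standard-normal quantile.
    """

    beta0: float = 0.0
    beta1: float = 1.0
    sigma0: float = 0.5
    sigma1: float = 1.0
    n_points: int = 5000

    def scale(self, x):
        return self.sigma0 + self.sigma1 * np.asarray(x, dtype=float)

    def true_line(self, tau: float) -> tuple[float, float]:
        z = float(norm.ppf(tau))
        return self.beta0 + self.sigma0 * z, self.beta1 + self.sigma1 * z


@dataclass
class SimConfig:
    """All knobs of the synthetic world; the seed fixes every random draw."""

    seed: int = 0
    raster_shape: tuple[int, int] = (200, 200)
    smoothing_radius: float = 5.0          # Gaussian sigma, in cells
    nonburnable_frac: float = 0.05
    cellsize: float = 1.0
    n_tracts_x: int = 50
    n_tracts_y: int = 50
    groups: tuple[str, ...] = DEFAULT_GROUPS
    dirichlet_concentrations: tuple[float, ...] = (7.0, 1.2, 1.7, 0.25, 0.55, 0.35)
    disadvantage_hazard_corr: float = 0.6
    group_disadvantage_loadings: tuple[float, ...] = (-0.8, 0.7, 0.6, 1.0, -0.4, 0.3)
    group_noise_sd: float = 1.0
    indicator_loadings: tuple[float, ...] = tuple(
        round(0.6 + 0.05 * j, 2) for j in range(13)
    )
    indicator_noise_sds: tuple[float, ...] = (0.8,) * 13
    heteroscedastic_params: HeteroscedasticParams = field(
        default_factory=HeteroscedasticParams
    )
    pop_mean: float = 4000.0
    pop_sd: float = 1200.0
    pop_min: int = 200
    moderate_threshold: float = 0.4
    #: (group name, target ratio): construct majority-group compositions so
    #: that majority tracts carry this multiple of the others' mean V.
    inject_majority_ratio: tuple[str, float] | None = None

    def __post_init__(self):
        rows, cols = self.raster_shape
        if rows <= 0 or cols <= 0:
            raise InvalidConfigError("raster_shape must be positive")
        if self.smoothing_radius < 0:
            raise InvalidConfigError("smoothing_radius must be >= 0")
        if not 0 <= self.nonburnable_frac < 1:
            raise InvalidConfigError("nonburnable_frac must be in [0, 1)")
        if self.n_tracts_x * self.n_tracts_y < 4:
            raise InvalidConfigError("need at least 4 tracts")
        if self.n_tracts_x > cols or self.n_tracts_y > rows:
            raise InvalidConfigError("tract grid must not be finer than the raster")
        n_g = len(self.groups)
        if len(self.dirichlet_concentrations) != n_g:
            raise InvalidConfigError("one Dirichlet concentration per group")
        if any(c <= 0 for c in self.dirichlet_concentrations):
            raise InvalidConfigError("Dirichlet concentrations must be positive")
        if len(self.group_disadvantage_loadings) != n_g:
            raise InvalidConfigError("one disadvantage loading per group")
        if len(self.indicator_loadings) != 13 or len(self.indicator_noise_sds) != 13:
            raise InvalidConfigError("indicator loadings and noise SDs must have length 13")
        if not -1 <= self.disadvantage_hazard_corr <= 1:
            raise InvalidConfigError("disadvantage_hazard_corr must be in [-1, 1]")
        h = self.heteroscedastic_params
        if min(h.sigma0, h.sigma0 + h.sigma1) <= 0:
            raise InvalidConfigError(
                "heteroscedastic scale sigma0 + sigma1*x must be positive on [0, 1]"
            )
        if self.inject_majority_ratio is not None:
            g, ratio = self.inject_majority_ratio
            if g not in self.groups:
                raise InvalidConfigError(f"unknown injection group {g!r}")
            if ratio <= 0:
                raise InvalidConfigError("injection ratio must be positive")
            if any(l != 0 for l in self.group_disadvantage_loadings):
                raise InvalidConfigError(
                    "majority-ratio injection requires zero group loadings "
                    "(compositions are assigned after the indicators exist)"
                )


@dataclass
class GroundTruth:
    """Generative parameters and latent variables behind one synthetic table."""

    disadvantage: np.ndarray | None = None
    disadvantage_hazard_corr: float | None = None
    indicator_loadings: tuple[float, ...] | None = None
    injected_ratio_target: float | None = None
    injected_ratio_constructed: float | None = None
    majority_group: str | None = None
    majority_tract_ids: list[str] | None = None
    heteroscedastic: HeteroscedasticParams | None = None

    def true_quantile_line(self, tau: float) -> tuple[float, float]:
        if self.heteroscedastic is None:
            raise InvalidConfigError("no heteroscedastic scenario in this truth")
        return self.heteroscedastic.true_line(tau)

    def to_json(self) -> str:
        payload = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if isinstance(val, np.ndarray):
                val = val.tolist()
            elif isinstance(val, HeteroscedasticParams):
                val = dataclasses.asdict(val)
            payload[f.name] = val
        return json.dumps(payload, indent=2)


def _rng(component: int, seed: int) -> np.random.Generator:
    # one independent stream per generator component, all pinned by the seed
    return np.random.default_rng([component, seed])


def generate_hazard_raster(config: SimConfig) -> hazard.HazardRaster:
    """Smoothed-Gaussian hazard field min-max normalized to [0, 1].

    ``smoothing_radius`` is the Gaussian-filter sigma in cell units; 0 gives
    spatially independent noise, larger values give stronger positive spatial
    autocorrelation.  A ``nonburnable_frac`` share of cells is flagged
    non-burnable (value 0, masked).
    """
    rng = _rng(0, config.seed)
    field_ = rng.standard_normal(config.raster_shape)
    if config.smoothing_radius > 0:
        field_ = gaussian_filter(field_, sigma=config.smoothing_radius, mode="reflect")
    lo, hi = field_.min(), field_.max()
    field_ = (field_ - lo) / (hi - lo)
    mask = rng.random(config.raster_shape) < config.nonburnable_frac
    field_ = np.where(mask, 0.0, field_)
    return hazard.HazardRaster(
        field_, mask, cellsize=config.cellsize, crs_label="synthetic"
    )


def generate_tract_grid(config: SimConfig) -> list[tuple[str, Polygon]]:
    """Rectangular tract polygons exactly tiling the raster extent."""
    rows, cols = config.raster_shape
    width = cols * config.cellsize
    height = rows * config.cellsize
    nx, ny = config.n_tracts_x, config.n_tracts_y
    tracts = []
    for iy in range(ny):
        for ix in range(nx):
            x0 = ix * width / nx
            x1 = (ix + 1) * width / nx
            y0 = iy * height / ny
            y1 = (iy + 1) * height / ny
            tracts.append((f"tract_{iy * nx + ix:05d}", box(x0, y0, x1, y1)))
    return tracts


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _exact_corr_mix(target: np.ndarray, noise: np.ndarray, rho: float) -> np.ndarray:
    """Mix noise with a standardized target to hit sample correlation rho exactly.

    The noise is residualized against the standardized target before mixing,
    so corr(result, target) equals rho in the realized sample, not just in
    expectation.
    """
    z = _standardize(target)
    if abs(rho) == 1.0:
        return np.sign(rho) * z
    e = noise - noise.mean()
    e = e - (e @ z) / (z @ z) * z
    if e.std() == 0:
        raise InvalidConfigError("degenerate noise vector in correlation mix")
    return rho * z + np.sqrt(1 - rho**2) * _standardize(e)


def _largest_remainder_counts(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer group counts summing exactly to total (largest-remainder rounding)."""
    raw = shares * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _indicator_columns(
    d: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """13 indicator columns driven by latent disadvantage.

    Each raw column is loading*d + noise, sign-flipped for the
    higher-is-better indicator so that more disadvantage always means worse
    values.  Raw scores are passed through monotone cosmetic maps (logistic
    for percentage-type columns, exponential for the income-type column) —
    purely presentational, since the downstream index uses ranks only.
    """
    cols = {}
    for j, spec in enumerate(capacity.DEFAULT_INDICATORS):
        noise = rng.normal(0.0, config.indicator_noise_sds[j], size=d.size)
        raw = config.indicator_loadings[j] * d + noise
        if spec.direction == "higher_is_better":
            raw = -raw
            cols[spec.column] = 30000.0 * np.exp(0.3 * raw)
        else:
            cols[spec.column] = 100.0 / (1.0 + np.exp(-0.8 * raw))
    return cols


def _force_majority(
    shares: np.ndarray, g: int, majority: bool, rng: np.random.Generator
) -> np.ndarray:
    """Rescale one tract's composition so group g is (not) the strict majority."""
    out = shares.copy()
    if majority:
        target = rng.uniform(0.55, 0.85)
    else:
        if out[g] <= 0.45:
            return out
        target = rng.uniform(0.05, 0.45)
    others = np.delete(out, g)
    others = others / others.sum() * (1.0 - target)
    out[g] = target
    out[np.arange(out.size) != g] = others
    return out


def _select_ratio_subset(
    v: np.ndarray, target: float, frac: float = 0.25
) -> tuple[np.ndarray, float]:
    """Pick a subset S of ~frac*n tracts with mean(v[S])/mean(v[~S]) ~= target.

    S is a contiguous window over the tracts sorted by v: sliding the window
    from the top of the distribution to the bottom sweeps the ratio
    continuously (adjacent order statistics differ by tiny amounts at the
    sample sizes used), so the achievable ratio closest to the target is found
    by evaluating every window position via prefix sums.  Returns (indices
    into v, constructed ratio).
    """
    n = v.size
    m1 = max(2, int(round(frac * n)))
    if m1 >= n - 1:
        raise InvalidConfigError("too few tracts for majority-ratio injection")
    order = np.argsort(-v, kind="stable")
    vs = v[order]
    prefix = np.concatenate([[0.0], np.cumsum(vs)])
    total = prefix[-1]
    starts = np.arange(0, n - m1 + 1)
    win_sum = prefix[starts + m1] - prefix[starts]
    win_mean = win_sum / m1
    rest_mean = (total - win_sum) / (n - m1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = win_mean / rest_mean
    best = int(np.nanargmin(np.abs(ratios - target)))
    return order[best : best + m1], float(ratios[best])


def generate_attributes(
    tract_hazard: pd.DataFrame | np.ndarray,
    config: SimConfig,
    tract_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Census-like attribute table coupled to tract hazard through a latent factor.

    Parameters
    ----------
    tract_hazard
        Either the DataFrame produced by :func:`fire_equity.hazard.zonal_mean`
        (columns ``tract_id``, ``whp``) or a plain per-tract hazard vector.
    config
        Simulation configuration; ``disadvantage_hazard_corr`` is injected as
        an *exact sample* correlation between the latent disadvantage and the
        supplied hazard values.

    Returns
    -------
    (table, truth) where the table has one row per tract with ``tract_id``,
    ``pop_total``, one ``pop_<group>`` count column per group (largest-
    remainder rounded so counts sum to the tract total) and indicator columns
    ``ind_01`` … ``ind_13``.
    """
    if isinstance(tract_hazard, pd.DataFrame):
        ids = tract_hazard["tract_id"].astype(str).tolist()
        hz = tract_hazard["whp"].to_numpy(dtype=float)
    else:
        hz = np.asarray(tract_hazard, dtype=float)
        ids = tract_ids or [f"tract_{i:05d}" for i in range(hz.size)]
    if len(ids) != hz.size:
        raise InvalidConfigError("one hazard value per tract id required")
    if np.isnan(hz).any():
        raise InvalidConfigError("tract hazard contains missing values")
    n = hz.size
    rng = _rng(1, config.seed)

    shares = rng.dirichlet(config.dirichlet_concentrations, size=n)
    loadings = np.asarray(config.group_disadvantage_loadings, dtype=float)
    noise = shares @ loadings + rng.normal(0.0, config.group_noise_sd, size=n)
    d = _exact_corr_mix(hz, noise, config.disadvantage_hazard_corr)
    indicators = _indicator_columns(d, config, rng)

    truth = GroundTruth(
        disadvantage=d,
        disadvantage_hazard_corr=config.disadvantage_hazard_corr,
        indicator_loadings=config.indicator_loadings,
        heteroscedastic=config.heteroscedastic_params,
    )

    if config.inject_majority_ratio is not None:
        g_name, target = config.inject_majority_ratio
        g = config.groups.index(g_name)
        ind_df = pd.DataFrame({"tract_id": ids, **indicators})
        ac = capacity.compute_ac_index(ind_df)
        hz_df = pd.DataFrame({"tract_id": ids, "whp": hz})
        filt = hz_df[hz_df["whp"] >= config.moderate_threshold]
        merged = filt.merge(ac[["tract_id", "ac"]], on="tract_id")
        params = vulnerability.VulnerabilityParams.from_data(
            merged["ac"], merged["whp"],
            moderate_threshold=config.moderate_threshold,
        )
        v = vulnerability.compute_vulnerability(merged["ac"], merged["whp"], params)
        top_idx, constructed = _select_ratio_subset(np.asarray(v), target)
        majority_ids = set(merged["tract_id"].iloc[top_idx])
        filtered_ids = set(merged["tract_id"])
        for i, tid in enumerate(ids):
            if tid in majority_ids:
                shares[i] = _force_majority(shares[i], g, True, rng)
            elif tid in filtered_ids:
                shares[i] = _force_majority(shares[i], g, False, rng)
        truth.injected_ratio_target = target
        truth.injected_ratio_constructed = constructed
        truth.majority_group = g_name
        truth.majority_tract_ids = sorted(majority_ids)

    totals = np.maximum(
        rng.normal(config.pop_mean, config.pop_sd, size=n), config.pop_min
    ).astype(np.int64)
    counts = np.vstack(
        [_largest_remainder_counts(shares[i], totals[i]) for i in range(n)]
    )

    table = pd.DataFrame({"tract_id": ids, "pop_total": totals})
    for k, g_name in enumerate(config.groups):
        table[f"pop_{g_name}"] = counts[:, k]
    for col, vals in indicators.items():
        table[col] = vals
    return table, truth


def generate_heteroscedastic_xy(
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Draw the direct quantile-recovery scenario with known quantile lines."""
    p = config.heteroscedastic_params
    rng = _rng(2, config.seed)
    x = rng.uniform(0.0, 1.0, size=p.n_points)
    eps = rng.standard_normal(p.n_points)
    y = p.beta0 + p.beta1 * x + p.scale(x) * eps
    return x, y, GroundTruth(heteroscedastic=p)


@dataclass
class Bundle:
    """One fully generated synthetic world plus its ground truth."""

    config: SimConfig
    raster: hazard.HazardRaster
    tracts: list
    tract_hazard: pd.DataFrame
    table: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        """Write hazard.asc, tracts.geojson, attributes.csv, ground_truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "raster": str(outdir / "hazard.asc"),
            "tracts": str(outdir / "tracts.geojson"),
            "attributes": str(outdir / "attributes.csv"),
            "ground_truth": str(outdir / "ground_truth.json"),
        }
        hazard.write_ascii_grid(self.raster, paths["raster"])
        features = [
            {
                "type": "Feature",
                "properties": {"tract_id": tid},
                "geometry": mapping(geom),
            }
            for tid, geom in self.tracts
        ]
        with open(paths["tracts"], "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
        self.table.to_csv(paths["attributes"], index=False, lineterminator="\n")
        with open(paths["ground_truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


def generate_bundle(config: SimConfig) -> Bundle:
    """Generate raster, tract grid, zonal hazard and attribute table in one call."""
    raster = generate_hazard_raster(config)
    tracts = generate_tract_grid(config)
    tract_hz = hazard.zonal_mean(raster, tracts)
    table, truth = generate_attributes(tract_hz, config)
    return Bundle(config, raster, tracts, tract_hz, table, truth)
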