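"""Quantile-regression disparity analysis and dispersion diagnostics.

The disparity model regresses tract vulnerability V on a group's population
proportion x at the tail quantiles tau = 0.05 and 0.95, fitting

    Q_tau(V | x) = beta_tau0 + beta_tau1 * x

by exact minimization of the check (pinball) loss

    L_tau(u) = sum_i u_i * (tau - 1[u_i < 0]),

posed as a linear program and solved with the HiGHS simplex/IPM solver.  The
two tail lines bound the envelope of vulnerability attainable at a given group
proportion; an upward-sloping 0.05 line means the *minimum* vulnerability a
tract can have rises with that group's share.  Standard errors come from a
pairs bootstrap.  The coefficient-of-variation diagnostic quantifies how much
vulnerability varies among the tracts with the lowest and highest group
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import pearsonr

from .errors import (
    DataError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidConfigError,
)


@dataclass
class QuantileFit:
    """One fitted conditional-quantile line."""

    tau: float
    beta0: float
    beta1: float
    objective: float
    n: int
    se_beta0: float | None = None
    se_beta1: float | None = None

    def predict(self, x) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)


def check_loss(residuals, tau: float) -> float:
    """Check (pinball) loss: sum of u*(tau - 1[u<0]) over residuals u."""
    if not 0 < tau < 1:
        raise InvalidConfigError(f"tau must be in (0, 1), got {tau}")
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile_line(x, y, tau: float) -> QuantileFit:
    """Globally minimize the check loss over lines beta0 + beta1*x.

    LP formulation: beta0, beta1 are split into positive parts and residuals
    into u+ >= 0, u- >= 0 with beta0 + beta1*x_i + u+_i - u-_i = y_i; the cost
    is tau*sum(u+) + (1-tau)*sum(u-).  Exact and deterministic for fixed
    input; in nondegenerate cases the optimum interpolates two data points.
    """
    if not 0 < tau < 1:
        raise InvalidConfigError(f"tau must be in (0, 1), got {tau}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"quantile fit needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant predictor x: slope unidentifiable")

    ones = np.ones(n)
    eye = sparse.eye(n, format="csc")
    a_eq = sparse.hstack(
        [
            sparse.csc_matrix(ones[:, None]),
            -sparse.csc_matrix(ones[:, None]),
            sparse.csc_matrix(x[:, None]),
            -sparse.csc_matrix(x[:, None]),
            eye,
            -eye,
        ],
        format="csc",
    )
    cost = np.concatenate([np.zeros(4), np.full(n, tau), np.full(n, 1.0 - tau)])
    res = linprog(cost, A_eq=a_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise DataError(f"quantile LP failed: {res.message}")
    beta0 = res.x[0] - res.x[1]
    beta1 = res.x[2] - res.x[3]
    objective = check_loss(y - beta0 - beta1 * x, tau)
    return QuantileFit(tau, float(beta0), float(beta1), objective, n)


def pairwise_oracle(x, y, tau: float) -> tuple[float, float, float]:
    """Brute-force reference: best line through every pair of data points.

    In nondegenerate cases the optimal quantile-regression line interpolates
    at least two observations, so enumerating all pairs (plus horizontal lines
    through each point, covering tied-x pairs) and scoring each with the check
    loss yields the global optimum.  O(n^2) — for validation on small n only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = (np.inf, 0.0, 0.0)
    n = x.size
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            b1 = (y[j] - y[i]) / (x[j] - x[i])
            b0 = y[i] - b1 * x[i]
            obj = check_loss(y - b0 - b1 * x, tau)
            if obj < best[0]:
                best = (obj, b0, b1)
    for i in range(n):  # horizontal candidates
        obj = check_loss(y - y[i], tau)
        if obj < best[0]:
            best = (obj, y[i], 0.0)
    return best


def bootstrap_se(
    x, y, tau: float, n_boot: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Pairs-bootstrap standard errors of (beta0, beta1).

    (x, y) pairs are resampled with replacement and the line refit; the SEs
    are the sample SDs of the refit coefficients.  A resample with constant x
    is redrawn (at most 10 times per replicate).
    """
    if n_boot < 50:
        raise InvalidConfigError(f"n_boot must be >= 50, got {n_boot}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)
    b0s = np.empty(n_boot)
    b1s = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if np.ptp(x[idx]) > 0:
                break
        else:
            raise DegenerateDesignError(
                "bootstrap resample has constant x after 10 redraws"
            )
        fit = fit_quantile_line(x[idx], y[idx], tau)
        b0s[b] = fit.beta0
        b1s[b] = fit.beta1
    return float(np.std(b0s, ddof=1)), float(np.std(b1s, ddof=1))


def extremes_cv(x, v, window: float = 0.25) -> tuple[float, float, int, int]:
    """Coefficient of variation of v at the low and high extremes of x.

    Low subset: x <= min(x) + window; high subset: x >= max(x) - window, with
    the window on the proportion scale (absolute, default 0.25).  CV is the
    sample SD (ddof = 1) of v divided by its mean, per subset.
    """
    if not 0 < window < 1:
        raise InvalidConfigError(f"window must be in (0, 1), got {window}")
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    low = v[x <= x.min() + window]
    high = v[x >= x.max() - window]
    out = []
    for name, sub in (("low", low), ("high", high)):
        if sub.size < 2:
            raise InsufficientDataError(
                f"{name}-proportion subset has {sub.size} tracts, need >= 2"
            )
        mean = sub.mean()
        if mean == 0:
            raise DataError(f"{name}-proportion subset has zero mean vulnerability")
        out.append(float(np.std(sub, ddof=1) / mean))
    return out[0], out[1], int(low.size), int(high.size)


def group_hazard_correlations(x, ac, whp) -> tuple[float, float]:
    """Pearson correlation of a group's proportion with AC and with WHP."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    out = []
    for other in (np.asarray(ac, float), np.asarray(whp, float)):
        if np.ptp(x) == 0 or np.ptp(other) == 0:
            raise DataError("correlation undefined for a constant vector")
        out.append(float(pearsonr(x, other)[0]))
    return out[0], out[1]


def fit_group_disparities(
    records: pd.DataFrame,
    table: pd.DataFrame,
    group_columns: list[str],
    taus: tuple[float, ...] = (0.05, 0.95),
    predictor: str = "proportion",
    cv_window: float = 0.25,
    n_boot: int = 200,
    seed: int = 0,
    total_column: str = "pop_total",
) -> pd.DataFrame:
    """Full disparity table: one row per (group, tau) over the filtered tracts.

    ``predictor`` selects the regressor: the group's tract proportion
    (default) or its raw count.
    """
    if predictor not in ("proportion", "count"):
        raise InvalidConfigError(f"unknown predictor mode {predictor!r}")
    joined = records.merge(table, on="tract_id", how="left")
    v = joined["v"].to_numpy(dtype=float)
    rows = []
    for g_idx, g in enumerate(group_columns):
        counts = joined[g].to_numpy(dtype=float)
        if predictor == "proportion":
            x = counts / joined[total_column].to_numpy(dtype=float)
        else:
            x = counts
        prop = counts / joined[total_column].to_numpy(dtype=float)
        cv_low, cv_high, n_low, n_high = extremes_cv(prop, v, cv_window)
        r_ac, r_whp = group_hazard_correlations(
            prop, joined["ac"].to_numpy(float), joined["whp"].to_numpy(float)
        )
        for t_idx, tau in enumerate(taus):
            fit = fit_quantile_line(x, v, tau)
            se0, se1 = bootstrap_se(
                x, v, tau, n_boot=n_boot,
                seed=seed + 1000 * g_idx + t_idx,
            )
            rows.append(
                {
                    "group": g.removeprefix("pop_"),
                    "tau": tau,
                    "beta0": fit.beta0,
                    "beta1": fit.beta1,
                    "se_beta0": se0,
                    "se_beta1": se1,
                    "objective": fit.objective,
                    "n": fit.n,
                    "cv_low": cv_low,
                    "cv_high": cv_high,
                    "n_low": n_low,
                    "n_high": n_high,
                    "r_ac": r_ac,
                    "r_whp": r_whp,
                }
            )
    return pd.DataFrame(rows)
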