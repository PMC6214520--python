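"""Diagnostic figures: vulnerability plane, representation bars, quantile fans."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .vulnerability import QUADRANTS, VulnerabilityParams

_QUAD_COLORS = {"A": "#e08214", "B": "#b2182b", "C": "#2166ac", "D": "#8073ac"}


def vulnerability_scatter(vuln: pd.DataFrame, params: VulnerabilityParams, path):
    """AC vs hazard plane with quadrant boundaries, colored by quadrant."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for q in QUADRANTS:
        sub = vuln[vuln["quadrant"] == q]
        ax.scatter(sub["ac"], sub["whp"], s=8, alpha=0.6,
                   color=_QUAD_COLORS[q], label=f"{q} (n={len(sub)})")
    ax.axvline(params.ac_split, color="k", lw=0.8, ls="--")
    ax.axhline(params.whp_split, color="k", lw=0.8, ls="--")
    ax.set_xlabel("adaptive-capacity index (0 = greatest capacity)")
    ax.set_ylabel("tract mean wildfire hazard (0-1)")
    ax.set_title("Vulnerability plane")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def representation_bars(rep: pd.DataFrame, path):
    """Per-quadrant bars of group representation ratios vs the expected share."""
    groups = rep["group"].unique()
    fig, axes = plt.subplots(1, len(QUADRANTS), figsize=(3 * len(QUADRANTS), 4),
                             sharey=True)
    for ax, q in zip(np.atleast_1d(axes), QUADRANTS):
        sub = rep[rep["quadrant"] == q].set_index("group").reindex(groups)
        ax.bar(range(len(groups)), sub["ratio"], color="#4393c3")
        expected = sub["expected_share"].iloc[0]
        ax.axhline(expected, color="red", ls=":", lw=1.2,
                   label=f"expected {expected:.3f}")
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups, rotation=60, fontsize=7, ha="right")
        ax.set_title(f"quadrant {q}")
        ax.legend(fontsize=7)
    np.atleast_1d(axes)[0].set_ylabel("share of group living in quadrant")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def quantile_fans(vuln: pd.DataFrame, table: pd.DataFrame, ineq: pd.DataFrame, path,
                  total_column: str = "pop_total"):
    """Per-group scatter of V vs group proportion with the fitted tail lines."""
    joined = vuln.merge(table, on="tract_id", how="left")
    groups = ineq["group"].unique()
    ncols = min(3, len(groups))
    nrows = -(-len(groups) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.2 * nrows),
                             squeeze=False)
    for k, g in enumerate(groups):
        ax = axes[k // ncols][k % ncols]
        x = joined[f"pop_{g}"] / joined[total_column]
        ax.scatter(x, joined["v"], s=5, alpha=0.4, color="grey")
        xs = np.linspace(float(x.min()), float(x.max()), 50)
        for _, row in ineq[ineq["group"] == g].iterrows():
            ax.plot(xs, row["beta0"] + row["beta1"] * xs, lw=1.4,
                    label=f"tau={row['tau']:.2f}")
        sub = ineq[ineq["group"] == g].iloc[0]
        ax.set_title(f"{g}  (CV low {sub['cv_low']:.2f} / high {sub['cv_high']:.2f})",
                     fontsize=9)
        ax.set_xlabel("group proportion", fontsize=8)
        ax.set_ylabel("vulnerability V", fontsize=8)
        ax.legend(fontsize=7)
    for k in range(len(groups), nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
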