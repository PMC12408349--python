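"""Cross-session and cross-region meta-statistics.

Every analysis in this package produces per-session p-values and effect
sizes for each brain region.  This module owns the shared aggregation
steps: Fisher's combined probability test across sessions, step-up FDR
control (Benjamini-Hochberg or Benjamini-Yekutieli) across regions, and
the normalized comparison table that puts all analyses side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: p-values are clipped here before taking logs, so a numerically zero
#: permutation p cannot produce an infinite Fisher statistic.
P_FLOOR = 1e-300


@dataclass
class RegionResult:
    """Aggregated outcome of one analysis for one region."""

    region: str
    analysis: str
    effect_size: float
    p_combined: float
    n_sessions: int
    significant: bool = False
    extra: dict = field(default_factory=dict)


def fisher_combine(pvalues) -> float:
    """Combine independent p-values with Fisher's method.

    X = -2 * sum(log p) is referred to a chi-square distribution with
    2k degrees of freedom.  A single p-value is returned unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return float(p[0])
    p = np.clip(p, P_FLOOR, 1.0)
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


def fdr(pvalues, q: float = 0.01, method: str = "bh"):
    """Step-up false-discovery-rate control across a family of tests.

    Parameters
    ----------
    pvalues : array-like
        One p-value per region (or per directed pair for the Granger
        analysis).
    q : float
        Target FDR level.
    method : {"bh", "by"}
        Benjamini-Hochberg (independence) or Benjamini-Yekutieli
        (arbitrary dependence; divides by the harmonic sum c(m)).

    Returns
    -------
    ndarray of bool
        Rejection flags aligned with the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    key = {"bh": "fdr_bh", "by": "fdr_by"}[method.lower()]
    reject, _, _, _ = multipletests(p, alpha=q, method=key)
    return reject


def apply_region_fdr(results: list[RegionResult], q: float = 0.01,
                     method: str = "bh") -> list[RegionResult]:
    """Set the ``significant`` flag on a family of RegionResults in place."""
    if not results:
        return results
    flags = fdr([r.p_combined for r in results], q=q, method=method)
    for r, f in zip(results, flags):
        r.significant = bool(f)
    return results


def _normalize(values: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if not np.isfinite(hi - lo) or hi == lo:
        # degenerate range: all effects identical -> all zeros by convention
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def build_report(results: list[RegionResult],
                 region_order: list[str] | None = None) -> pd.DataFrame:
    """Comparison table of regions x analyses.

    Effect sizes are min-max normalized to [0, 1] within each analysis so
    that analyses with different units can share one colour scale; the
    ``significant`` flag set by the FDR step is carried alongside.
    Regions are ordered by the supplied canonical ordering (stable,
    diff-friendly), not by effect size.
    """
    if not results:
        return pd.DataFrame()
    rows = pd.DataFrame(
        {
            "region": [r.region for r in results],
            "analysis": [r.analysis for r in results],
            "effect_size": [r.effect_size for r in results],
            "p_combined": [r.p_combined for r in results],
            "n_sessions": [r.n_sessions for r in results],
            "significant": [r.significant for r in results],
        }
    )
    for analysis, grp in rows.groupby("analysis"):
        rows.loc[grp.index, "effect_normalized"] = _normalize(
            grp["effect_size"].to_numpy(float)
        )
    if region_order is None:
        region_order = sorted(rows["region"].unique())
    rows["region"] = pd.Categorical(rows["region"], categories=region_order,
                                    ordered=True)
    return rows.sort_values(["region", "analysis"]).reset_index(drop=True)


def plot_report(table: pd.DataFrame, path=None):
    """Heatmap of the normalized comparison table (visualization only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index="region", columns="analysis",
                              values="effect_normalized", observed=True)
    fig, ax = plt.subplots(figsize=(2 + 0.8 * pivot.shape[1],
                                    1 + 0.25 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label="normalized effect size")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
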