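"""Functional convergence trends: Spearman trend, permutation null, FDR, clustering.

The convergence matrix holds one set-size-corrected significance per
(property, gene set) pair, with columns ordered by ascending effect rank.
The per-property trend is the Spearman correlation between the property's
significances ``s = -log10(convergence p)`` and the sets' effect ranks; a
positive trend means stronger functional signal in higher-effect sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConvergenceMatrix",
    "TrendResult",
    "trend_correlation",
    "spearman_trend_p",
    "filter_properties",
    "permutation_null",
    "bh_fdr",
    "cluster_properties",
    "trend_report",
]

Regime = Literal["strict_0.05", "loose_0.5", "none"]

REGIME_THRESHOLDS: dict[str, float | None] = {
    "strict_0.05": 0.05,
    "loose_0.5": 0.5,
    "none": None,
}


@dataclass
class ConvergenceMatrix:
    """Properties x gene-sets table of convergence p-values.

    ``values`` is a DataFrame with property ids as rows and gene-set ids as
    columns; ``ranks`` gives each column's effect rank.  Columns are stored
    in ascending rank order.
    """

    values: pd.DataFrame
    ranks: pd.Series
    kinds: pd.Series | None = None

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.ranks.index):
            raise ValueError("rank index must match matrix columns")
        order = self.ranks.sort_values(kind="mergesort").index
        self.values = self.values.loc[:, order]
        self.ranks = self.ranks.loc[order].astype(float)
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("convergence matrix contains missing cells")
        if ((vals <= 0) | (vals > 1)).any():
            raise ValueError("convergence p-values must lie in (0, 1]")

    @property
    def property_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def set_ids(self) -> list[str]:
        return list(self.values.columns)

    def significance(self) -> pd.DataFrame:
        """Cell significances s = -log10(convergence p)."""
        return -np.log10(self.values)

    def subset(self, property_ids: Sequence[str]) -> "ConvergenceMatrix":
        kinds = self.kinds.loc[property_ids] if self.kinds is not None else None
        return ConvergenceMatrix(
            self.values.loc[property_ids], self.ranks.copy(), kinds
        )


@dataclass(frozen=True)
class TrendResult:
    """Per-property functional convergence trend."""

    property_id: str
    r_s: float
    trend_p: float
    q: float
    regime: Regime


def spearman_trend_p(r_s: float, n: int) -> float:
    """Two-sided p of a Spearman coefficient under the t-approximation.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` referred to a t distribution with
    ``n - 2`` degrees of freedom; |r| = 1 maps to p = 0.
    """
    if not -1.0 <= r_s <= 1.0:
        raise ValueError("r_s must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r_s) == 1.0:
        return 0.0
    t = r_s * math.sqrt((n - 2) / (1.0 - r_s * r_s))
    return min(2.0 * float(stats.t.sf(abs(t), n - 2)), 1.0)


def trend_correlation(
    significances: Sequence[float],
    ranks: Sequence[float],
) -> tuple[float, float]:
    """Spearman trend of per-set significances against effect ranks.

    Both vectors are mid-ranked (ties averaged) and Pearson-correlated; the
    two-sided p comes from the t-approximation
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom,
    which handles the tied control ranks.  Returns ``(nan, nan)`` when the
    significances (or ranks) have zero variance.
    """
    s = np.asarray(significances, dtype=float)
    g = np.asarray(ranks, dtype=float)
    if s.size != g.size:
        raise ValueError("significances and ranks must have equal length")
    n = s.size
    if n < 4:
        raise ValueError("need at least 4 gene sets for a trend")
    if np.ptp(s) == 0 or np.ptp(g) == 0:
        return float("nan"), float("nan")
    rs = float(np.corrcoef(stats.rankdata(s), stats.rankdata(g))[0, 1])
    rs = max(-1.0, min(1.0, rs))
    return rs, spearman_trend_p(rs, n)


def filter_properties(
    matrix: ConvergenceMatrix,
    threshold: float | None,
) -> list[str]:
    """Ids of properties with at least one set converging below ``threshold``.

    With ``threshold=None`` all properties with a computable trend (nonzero
    significance variance across sets) are kept.
    """
    if threshold is None:
        s = matrix.significance().to_numpy()
        keep = np.ptp(s, axis=1) > 0
    else:
        keep = (matrix.values.to_numpy() < threshold).any(axis=1)
    return [pid for pid, k in zip(matrix.property_ids, keep) if k]


def permutation_null(
    matrix: ConvergenceMatrix,
    n_perm: int,
    rng: np.random.Generator,
) -> dict:
    """Label-permutation null of the trend correlation.

    For each permutation the effect ranks are shuffled across gene-set
    labels and every property's Spearman trend is recomputed.  In the
    ranked setting this is the null distribution of a Spearman correlation,
    so the analytic standard deviation ``1 / sqrt(n - 1)`` (distinct ranks)
    is returned alongside for cross-checking.

    Returns a dict with ``per_property`` (properties x permutations array of
    null r_s), ``pooled`` (flattened), and ``analytic_sd``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    s = matrix.significance().to_numpy()
    g = matrix.ranks.to_numpy()
    n = g.size
    s_ranked = np.apply_along_axis(stats.rankdata, 1, s)
    g_ranked = stats.rankdata(g)

    def _corr(cols: np.ndarray) -> np.ndarray:
        a = s_ranked - s_ranked.mean(axis=1, keepdims=True)
        b = cols - cols.mean()
        denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (a @ b) / denom

    null = np.empty((s.shape[0], n_perm))
    for j in range(n_perm):
        null[:, j] = _corr(g_ranked[rng.permutation(n)])
    return {
        "per_property": null,
        "pooled": null.ravel(),
        "analytic_sd": 1.0 / math.sqrt(n - 1),
    }


def bh_fdr(trend_ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone enforced)."""
    p = np.asarray(trend_ps, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_properties(
    matrix: ConvergenceMatrix,
    cut_height: float | None = None,
    *,
    n_clusters: int = 6,
) -> pd.Series:
    """Cluster properties by Euclidean distance of column-ranked significances.

    Significances are ranked within each gene-set column (so properties are
    compared by their relative standing per set), rows are clustered by
    complete-linkage agglomeration on Euclidean distance, and the dendrogram
    is cut at ``cut_height`` — or, if not given, at the height yielding
    ``n_clusters`` flat clusters.
    """
    if len(matrix.property_ids) < 2:
        raise ValueError("need at least 2 properties to cluster")
    s = matrix.significance().to_numpy()
    col_ranked = np.apply_along_axis(stats.rankdata, 0, s)
    z = linkage(pdist(col_ranked, metric="euclidean"), method="complete")
    if cut_height is not None:
        labels = fcluster(z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(z, t=min(n_clusters, len(matrix.property_ids)),
                          criterion="maxclust")
    return pd.Series(labels, index=matrix.property_ids, name="cluster")


def trend_report(
    matrix: ConvergenceMatrix,
    regime: Regime = "strict_0.05",
) -> pd.DataFrame:
    """Filter, trend-correlate and BH-adjust every property under one regime.

    Returns a DataFrame indexed by property id with columns ``r_s``,
    ``trend_p``, ``q`` and ``regime``; properties failing the regime filter
    or with undefined trends are absent.
    """
    if regime not in REGIME_THRESHOLDS:
        raise ValueError(f"unknown regime {regime!r}")
    keep = filter_properties(matrix, REGIME_THRESHOLDS[regime])
    sig = matrix.significance()
    g = matrix.ranks.to_numpy()
    rows = []
    for pid in keep:
        rs, p = trend_correlation(sig.loc[pid].to_numpy(), g)
        if math.isnan(rs):
            continue
        rows.append((pid, rs, p))
    if not rows:
        return pd.DataFrame(columns=["r_s", "trend_p", "q", "regime"])
    df = pd.DataFrame(rows, columns=["property", "r_s", "trend_p"]).set_index(
        "property"
    )
    df["q"] = bh_fdr(df["trend_p"].to_numpy())
    df["regime"] = regime
    return df
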