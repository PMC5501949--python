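"""Functional tests and set-size-corrected "functional convergence" values.

Three families of per-gene-set tests are supported:

* annotation-set enrichment (one-sided hypergeometric),
* gene-score comparison (Mann-Whitney-Wilcoxon rank-sum),
* network connectivity (within-set vs global degree residuals compared
  against random same-size null sets, rank-sum).

Because every test's p-value depends on the size of the gene set, the
"functional convergence" of a set for a property is the geometric mean of
the test p-value recomputed over many uniform subsamples of a common size
``k``: sets of very different sizes then yield comparable significances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneUniverse
from .networks import WeightedGeneNetwork

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

__all__ = [
    "FunctionalProperty",
    "ConvergenceResult",
    "enrichment_test",
    "score_test",
    "connectivity_test",
    "downsample_convergence",
    "filter_annotation_sets_by_size",
]

Kind = Literal["annotation_set", "gene_score", "network"]


@dataclass
class FunctionalProperty:
    """One testable functional property of a gene set.

    ``payload`` is a gene set (``annotation_set``), a per-gene score Series
    (``gene_score``) or a :class:`WeightedGeneNetwork` (``network``).
    ``direction`` applies to gene scores: ``greater`` tests whether candidate
    genes score higher than background (e.g. haploinsufficiency), ``less``
    whether they score lower (e.g. RVIS, where low means intolerant).
    """

    id: str
    kind: Kind
    payload: object
    direction: Literal["greater", "less"] = "greater"

    def __post_init__(self) -> None:
        if self.kind == "annotation_set":
            self.payload = frozenset(self.payload)
            if not self.payload:
                raise ValueError(f"annotation set {self.id!r} is empty")
        elif self.kind == "gene_score":
            if not isinstance(self.payload, pd.Series):
                self.payload = pd.Series(dict(self.payload), dtype=float)
            if self.payload.empty:
                raise ValueError(f"score table {self.id!r} is empty")
        elif self.kind == "network":
            if not isinstance(self.payload, WeightedGeneNetwork):
                raise TypeError(f"property {self.id!r}: payload must be a network")
        else:
            raise ValueError(f"unknown property kind {self.kind!r}")

    def check_coverage(self, universe: GeneUniverse) -> None:
        if self.kind == "gene_score":
            frac = len(set(self.payload.index) & universe.genes) / len(universe)
            if frac < 0.5:
                logger.warning(
                    "score table %s covers only %.0f%% of the universe",
                    self.id, 100 * frac,
                )


@dataclass(frozen=True)
class ConvergenceResult:
    """Downsampled convergence of one gene set for one property."""

    property_id: str
    set_id: str
    raw_p: float
    convergence_p: float
    subsample_size: int
    iterations: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("raw_p", "convergence_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def enrichment_test(
    candidate: Iterable[str],
    property_set: Iterable[str],
    universe: GeneUniverse,
) -> float:
    """One-sided (upper-tail) hypergeometric enrichment p of the overlap."""
    cand = frozenset(candidate)
    prop = frozenset(property_set)
    if not cand:
        raise ValueError("candidate set is empty")
    if not cand <= universe.genes or not prop <= universe.genes:
        raise ValueError("candidate and property set must lie in the universe")
    overlap = len(cand & prop)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(prop), len(cand)))
    return min(max(p, P_FLOOR), 1.0)


def score_test(
    candidate: Iterable[str],
    scores: pd.Series,
    *,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
) -> float:
    """Rank-sum p comparing candidate gene scores against all other scored genes.

    Exact enumeration is used when both groups have at most 50 untied
    observations; otherwise the normal approximation with tie correction.
    Returns 1.0 when every score is identical (degenerate input).
    """
    cand = frozenset(candidate)
    x = scores[scores.index.isin(cand)].to_numpy(dtype=float)
    y = scores[~scores.index.isin(cand)].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both candidate and background need scored genes")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 50 and y.size <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(min(max(res.pvalue, P_FLOOR), 1.0))


def _sample_index_sets(
    rng: np.random.Generator, n_sets: int, size: int, n_items: int
) -> np.ndarray:
    """Uniform without-replacement index sets, one per row.

    When ``size`` is small relative to the pool, draws with replacement and
    redraws the few rows containing duplicates (exact and fast); otherwise
    takes the ``size`` smallest of per-row random keys.
    """
    if size > n_items:
        raise ValueError("cannot sample more items than the pool holds")
    if 4 * size * size <= n_items:
        draws = rng.integers(0, n_items, size=(n_sets, size))
        while True:
            s = np.sort(draws, axis=1)
            bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
            if not bad.any():
                return draws
            draws[bad] = rng.integers(0, n_items, size=(int(bad.sum()), size))
    keys = rng.random((n_sets, n_items))
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def _ranksum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (x stochastically greater) MWW p, normal approx, tie-corrected."""
    nx_, ny_ = x.size, y.size
    n = nx_ + ny_
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    sv = pooled[order]
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    tie_term = 0.0
    if n > 1 and (sv[1:] == sv[:-1]).any():
        _, counts = np.unique(sv, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
        # mid-rank the ties
        ranks = stats.rankdata(pooled)
    u = ranks[:nx_].sum() - nx_ * (nx_ + 1) / 2.0
    mu = nx_ * ny_ / 2.0
    var = nx_ * ny_ / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u - mu - 0.5) / math.sqrt(var)
    return float(min(max(stats.norm.sf(z), P_FLOOR), 1.0))


def connectivity_test(
    candidate: Iterable[str],
    network: WeightedGeneNetwork,
    n_null_sets: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    null_line: Literal["fit", "identity"] = "fit",
    _candidate_idx: np.ndarray | None = None,
) -> float:
    """Network-modularity p: is the candidate better inter-connected than chance?

    For each candidate gene the global degree (sum of all incident weights)
    and the internal degree (sum of weights to other candidate genes) are
    computed; the same is done for ``n_null_sets`` random in-network gene
    sets of the same size.  A zero-intercept line ``internal = beta * global``
    is fitted across the pooled genes (or fixed to the identity with
    ``null_line="identity"``), residuals are standardized by the pooled
    residual spread, and a one-sided rank-sum test asks whether candidate
    residuals exceed the null residuals.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_null_sets < 100:
        raise ValueError("n_null_sets must be >= 100")
    if _candidate_idx is not None:
        idx = _candidate_idx
    else:
        idx = network.indices(candidate)
    k = idx.size
    if k < 3:
        raise ValueError("candidate must have at least 3 genes in the network")

    w = network.weights
    gdeg = w.sum(axis=1)
    cand_internal = w[np.ix_(idx, idx)].sum(axis=1)
    cand_global = gdeg[idx]

    null_idx = _sample_index_sets(rng, n_null_sets, k, len(network))
    # chunk the (n_null, k, k) gather to bound memory
    chunk = max(1, int(2e7 // (k * k)))
    null_internal = np.empty((n_null_sets, k))
    for start in range(0, n_null_sets, chunk):
        block = null_idx[start:start + chunk]
        null_internal[start:start + block.shape[0]] = w[
            block[:, :, None], block[:, None, :]
        ].sum(axis=2)
    null_global = gdeg[null_idx]

    pooled_g = np.concatenate([cand_global, null_global.ravel()])
    pooled_i = np.concatenate([cand_internal, null_internal.ravel()])
    if null_line == "fit":
        denom = (pooled_g ** 2).sum()
        beta = (pooled_g * pooled_i).sum() / denom if denom > 0 else 0.0
    else:
        beta = 1.0
    resid = pooled_i - beta * pooled_g
    sd = resid.std()
    if sd > 0:
        resid = resid / sd
    return _ranksum_greater(resid[:k], resid[k:])


def downsample_convergence(
    test: Callable[[frozenset], float],
    candidate: Iterable[str],
    k: int,
    iters: int,
    rng: np.random.Generator,
    *,
    property_id: str = "",
    set_id: str = "",
    rng_seed: int | None = None,
) -> ConvergenceResult:
    """Set-size-corrected convergence p for one (property, gene set) pair.

    Draws ``iters`` uniform subsamples of ``k`` genes without replacement,
    recomputes the test p-value on each, and aggregates by geometric mean
    (p floored at 1e-300 before taking logs).  With ``k`` equal to the set
    size the convergence equals the raw p exactly.
    """
    genes = sorted(set(candidate))
    if not 3 <= k <= len(genes):
        raise ValueError(
            f"subsample size {k} must lie in [3, {len(genes)}] for this set"
        )
    if iters < 1:
        raise ValueError("iters must be >= 1")
    raw_p = test(frozenset(genes))
    if k == len(genes):
        logs = np.full(iters, math.log(max(raw_p, P_FLOOR)))
    else:
        arr = np.array(genes, dtype=object)
        logs = np.empty(iters)
        for i in range(iters):
            sub = frozenset(arr[rng.choice(len(arr), size=k, replace=False)])
            logs[i] = math.log(max(test(sub), P_FLOOR))
    conv = float(np.exp(logs.mean()))
    return ConvergenceResult(
        property_id=property_id,
        set_id=set_id,
        raw_p=min(max(raw_p, P_FLOOR), 1.0),
        convergence_p=min(max(conv, P_FLOOR), 1.0),
        subsample_size=k,
        iterations=iters,
        rng_seed=rng_seed,
    )


def filter_annotation_sets_by_size(
    properties: Iterable[FunctionalProperty],
    min_size: int = 20,
    max_size: int = 1000,
) -> list[FunctionalProperty]:
    """Keep annotation-set properties within a size window; pass others through.

    Mirrors the usual practice of dropping tiny (unstable) and huge
    (uninformative) annotation categories before enrichment testing.
    """
    kept = []
    for prop in properties:
        if prop.kind == "annotation_set" and not (
            min_size <= len(prop.payload) <= max_size
        ):
            continue
        kept.append(prop)
    return kept
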