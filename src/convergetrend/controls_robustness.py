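"""Matched controls, leave-class-out robustness and the trait-swap harness.

Promiscuous enrichment signals are often driven by gene length and by
multifunctionality (how many annotation categories a gene belongs to), not
by disease biology.  This module generates control gene sets matched to a
target set on such attributes, and provides two specificity harnesses:
re-running the whole trend analysis with an entire variant class removed,
and swapping alternative trait gene lists into the GWAS slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection, GeneSetRecord, GeneUniverse, rank_gene_sets

logger = logging.getLogger(__name__)

__all__ = [
    "MatchingSpec",
    "multifunctionality_score",
    "matched_control_set",
    "leave_class_out",
    "gwas_swap",
]

MATCH_ATTRIBUTES = ("cds_length", "go_multifunctionality", "disease_multifunctionality")


@dataclass(frozen=True)
class MatchingSpec:
    """How to match control sets to a target set on a per-gene attribute.

    ``tolerance`` is the maximum allowed Kolmogorov-Smirnov statistic
    between the attribute-rank distributions of target and matched set.
    """

    attribute: Literal[
        "cds_length", "go_multifunctionality", "disease_multifunctionality"
    ]
    tolerance: float = 0.1
    n_sets: int = 1
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.attribute not in MATCH_ATTRIBUTES:
            raise ValueError(f"unknown matching attribute {self.attribute!r}")
        if not 0.0 < self.tolerance <= 1.0:
            raise ValueError("tolerance must lie in (0, 1]")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


def multifunctionality_score(
    universe: GeneUniverse,
    annotation_sets: Iterable[Iterable[str]],
) -> pd.DataFrame:
    """Per-gene multifunctionality: number of annotation sets containing it.

    Duplicate annotation sets are collapsed before counting (the count is a
    property of distinct functions, not of how often a file repeats one).
    Returns a DataFrame indexed by gene with columns ``count`` and
    ``standardized_rank`` (mid-ranked count ranks scaled to (0, 1]).
    """
    distinct = {frozenset(s) for s in annotation_sets}
    if not distinct:
        raise ValueError("need at least one annotation set")
    genes = universe.sorted_genes()
    counts = np.zeros(len(genes), dtype=int)
    index = {g: i for i, g in enumerate(genes)}
    for s in distinct:
        for g in s:
            if g in index:
                counts[index[g]] += 1
    ranks = stats.rankdata(counts, method="average") / len(genes)
    return pd.DataFrame(
        {"count": counts, "standardized_rank": ranks}, index=pd.Index(genes, name="gene")
    )


class MatchingError(RuntimeError):
    """Raised when no matched set reaches the requested tolerance."""


def _attribute_values(universe: GeneUniverse, spec: MatchingSpec,
                      extra: Mapping[str, float] | None) -> pd.Series:
    if spec.attribute == "cds_length":
        attr = universe.attribute("cds_length")
    elif spec.attribute == "go_multifunctionality":
        attr = universe.attribute("multifunctionality")
    else:
        if extra is None:
            raise ValueError(
                "disease_multifunctionality matching needs a per-gene mapping"
            )
        attr = extra
    return pd.Series(dict(attr), dtype=float)


def matched_control_set(
    target: GeneSetRecord,
    universe: GeneUniverse,
    spec: MatchingSpec,
    rng: np.random.Generator,
    *,
    disease_multifunctionality: Mapping[str, float] | None = None,
) -> frozenset[str]:
    """Sample a control set matching the target's attribute-rank distribution.

    Sampling is stratified: universe genes are binned by attribute-rank
    decile, each draw takes (from genes outside the target) the same number
    of genes per decile as the target has there, and the draw is accepted
    once the KS statistic between target and control attribute ranks is
    within ``spec.tolerance``.  Raises :class:`MatchingError` (naming the
    best achieved distance) if no draw succeeds within ``max_retries``.
    """
    values = _attribute_values(universe, spec, disease_multifunctionality)
    values = values.loc[sorted(values.index)]
    ranks = pd.Series(
        stats.rankdata(values.to_numpy(), method="average") / len(values),
        index=values.index,
    )
    target_genes = [g for g in sorted(target.genes) if g in ranks.index]
    if not target_genes:
        raise ValueError("target set has no genes with the matching attribute")
    pool = ranks.drop(index=target_genes)
    if len(pool) < len(target_genes):
        raise ValueError("universe too small to draw a disjoint matched set")

    target_ranks = ranks.loc[target_genes].to_numpy()
    deciles = np.clip((target_ranks * 10).astype(int), 0, 9)
    need = np.bincount(deciles, minlength=10)
    pool_deciles = np.clip((pool.to_numpy() * 10).astype(int), 0, 9)
    by_decile = [pool.index.to_numpy()[pool_deciles == d] for d in range(10)]

    best = np.inf
    for _ in range(spec.max_retries):
        chosen: list[str] = []
        feasible = True
        for d in range(10):
            n_d = int(need[d])
            if n_d == 0:
                continue
            bucket = by_decile[d]
            if len(bucket) < n_d:
                feasible = False
                break
            chosen.extend(rng.choice(bucket, size=n_d, replace=False))
        if not feasible:
            # fall back to an unstratified draw when a decile is exhausted
            chosen = list(
                rng.choice(pool.index.to_numpy(), size=len(target_genes), replace=False)
            )
        ks = stats.ks_2samp(target_ranks, ranks.loc[chosen].to_numpy()).statistic
        if ks <= spec.tolerance:
            return frozenset(chosen)
        best = min(best, ks)
    raise MatchingError(
        f"no matched set within tolerance {spec.tolerance} for {target.id!r} "
        f"after {spec.max_retries} tries (best KS distance {best:.3f})"
    )


def leave_class_out(
    collection: GeneSetCollection,
    drop_class: Literal["null_control", "weak", "strong"],
    analysis: Callable[[GeneSetCollection], pd.DataFrame],
) -> pd.DataFrame:
    """Re-run the trend analysis with one whole variant class removed.

    Surviving sets are re-ranked (controls re-tied at the bottom) and the
    supplied analysis closure — typically convergence + trend + FDR — is
    re-run on them.  The report gains a ``dropped_class`` column.
    """
    survivors = [r for r in collection.records if r.variant_class != drop_class]
    if len(survivors) < 4:
        raise ValueError(
            f"dropping class {drop_class!r} leaves {len(survivors)} sets; need >= 4"
        )
    sub = rank_gene_sets(
        GeneSetCollection(
            [replace(r, rank=None) for r in survivors], collection.universe
        )
    )
    report = analysis(sub).copy()
    report["dropped_class"] = drop_class
    return report


def gwas_swap(
    collection: GeneSetCollection,
    alternative_sets: Mapping[str, Iterable[str]],
    min_genes: int,
    analysis: Callable[[GeneSetCollection], pd.DataFrame],
    *,
    fdr_level: float = 0.01,
) -> pd.DataFrame:
    """Trait-specificity harness: swap alternative trait lists into GWAS slots.

    Every set flagged ``swappable`` has its genes replaced by the trait's
    gene list (harmonized to the universe); the full analysis closure is
    re-run per trait and traits are ranked descending by the number of
    significant trend correlations at ``fdr_level``.  Traits with fewer
    than ``min_genes`` genes are excluded.
    """
    slots = [r.id for r in collection.records if r.swappable]
    if not slots:
        raise ValueError("collection has no swappable gene sets")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    eligible = {
        trait: frozenset(genes) & collection.universe.genes
        for trait, genes in alternative_sets.items()
        if len(frozenset(genes) & collection.universe.genes) >= min_genes
    }
    if not eligible:
        raise ValueError(f"no trait has >= {min_genes} genes in the universe")

    rows = []
    for trait in sorted(eligible):
        genes = eligible[trait]
        swapped = GeneSetCollection(
            [
                replace(r, genes=genes, rank=None) if r.id in slots
                else replace(r, rank=None)
                for r in collection.records
            ],
            collection.universe,
        )
        swapped = rank_gene_sets(swapped)
        report = analysis(swapped)
        n_sig = int((report["q"] < fdr_level).sum())
        rows.append((trait, len(genes), n_sig))
        logger.info("swap %s: %d genes, %d significant trends", trait, len(genes), n_sig)
    df = pd.DataFrame(rows, columns=["trait", "n_genes", "n_significant"])
    return df.sort_values(
        ["n_significant", "trait"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
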