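"""Orchestration: convergence matrix assembly and the full trend analysis.

``compute_convergence_matrix`` runs the downsampled functional tests for
every (property, gene set) pair with vectorized fast paths (one shared pool
of subsamples per gene set), and ``run_full_analysis`` wires ranking,
convergence, per-regime trend reports, the permutation null, clustering and
a machine-readable summary into one seeded, reproducible run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .functional_tests import (
    P_FLOOR,
    FunctionalProperty,
    _ranksum_greater,
    _sample_index_sets,
)
from .genesets import GeneSetCollection, rank_gene_sets
from .trend import (
    REGIME_THRESHOLDS,
    ConvergenceMatrix,
    cluster_properties,
    permutation_null,
    trend_report,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "compute_convergence_matrix", "run_full_analysis",
           "leave_class_out_trends"]


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of one analysis run.

    ``k`` is the common subsample size (None: min over sets of 25 and the
    smallest set size); ``iters`` the number of downsampling iterations;
    ``n_perm`` label permutations for the empirical null; ``n_null_sets``
    random null sets per connectivity test.  All randomness derives from
    ``seed``.
    """

    k: int | None = None
    iters: int = 1000
    n_perm: int = 1000
    n_null_sets: int = 1000
    regimes: tuple[str, ...] = ("strict_0.05", "loose_0.5", "none")
    fdr_levels: tuple[float, ...] = (0.01, 0.05)
    null_line: str = "fit"
    seed: int = 0

    def __post_init__(self) -> None:
        for level in self.fdr_levels:
            if not 0.0 < level < 1.0:
                raise ValueError("FDR levels must lie in (0, 1)")
        for regime in self.regimes:
            if regime not in REGIME_THRESHOLDS:
                raise ValueError(f"unknown regime {regime!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def resolve_subsample_size(collection: GeneSetCollection, k: int | None) -> int:
    """Shared subsample size: explicit ``k``, or min(25, smallest set size)."""
    smallest = min(len(r) for r in collection.records)
    if k is None:
        k = min(smallest, 25)
    if not 3 <= k <= smallest:
        raise ValueError(
            f"subsample size {k} must lie in [3, {smallest}] "
            "(the smallest gene set bounds it)"
        )
    return k


def _subsample_pool(
    rng: np.random.Generator, set_idx: np.ndarray, k: int, iters: int
) -> np.ndarray:
    """iters x k universe indices, each row a uniform subsample of the set."""
    if set_idx.size == k:
        return np.tile(set_idx, (iters, 1))
    picks = _sample_index_sets(rng, iters, k, set_idx.size)
    return set_idx[picks]


def _annotation_convergence(
    masks: np.ndarray,
    prop_sizes: np.ndarray,
    subs: np.ndarray,
    n_universe: int,
    k: int,
) -> np.ndarray:
    """Geometric-mean hypergeometric p per property for one set's subsamples."""
    ov = masks[:, subs].sum(axis=2)  # n_props x iters
    tables = stats.hypergeom.sf(
        np.arange(k + 1)[None, :] - 1, n_universe, prop_sizes[:, None], k
    )
    p = np.take_along_axis(tables, ov, axis=1)
    return np.exp(np.log(np.clip(p, P_FLOOR, 1.0)).mean(axis=1))


def _score_convergence(
    ranks_row: np.ndarray,
    tie_term: float,
    n_scored: int,
    subs: np.ndarray,
    direction: str,
) -> float:
    """Geometric-mean one-sided rank-sum p for one score property and one set.

    ``ranks_row`` holds each universe gene's mid-rank within the scored
    genes (NaN when unscored); the tie correction depends only on the
    pooled score vector, so it is precomputed per property.
    """
    sub_ranks = ranks_row[subs]  # iters x k
    n1 = np.isfinite(sub_ranks).sum(axis=1).astype(float)
    r1 = np.nansum(sub_ranks, axis=1)
    n2 = n_scored - n1
    u = r1 - n1 * (n1 + 1) / 2.0
    if direction == "less":
        u = n1 * n2 - u
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n_scored + 1) - tie_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mu - 0.5) / np.sqrt(var)
    p = stats.norm.sf(z)
    p[~np.isfinite(z)] = 1.0
    return float(np.exp(np.log(np.clip(p, P_FLOOR, 1.0)).mean()))


def _network_convergence(
    weights: np.ndarray,
    gdeg: np.ndarray,
    subs: np.ndarray,
    n_null_sets: int,
    rng: np.random.Generator,
    null_line: str,
) -> float:
    """Geometric-mean connectivity p over one set's subsamples."""
    iters, k = subs.shape
    n = weights.shape[0]
    logs = np.empty(iters)
    for i in range(iters):
        cand = subs[i]
        cand_internal = weights[np.ix_(cand, cand)].sum(axis=1)
        null_idx = _sample_index_sets(rng, n_null_sets, k, n)
        null_internal = weights[
            null_idx[:, :, None], null_idx[:, None, :]
        ].sum(axis=2)
        pooled_g = np.concatenate([gdeg[cand], gdeg[null_idx].ravel()])
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
        logs[i] = np.log(max(_ranksum_greater(resid[:k], resid[k:]), P_FLOOR))
    return float(np.exp(logs.mean()))


def compute_convergence_matrix(
    collection: GeneSetCollection,
    properties: Sequence[FunctionalProperty],
    config: RunConfig,
    rng: np.random.Generator,
) -> ConvergenceMatrix:
    """Downsampled convergence p for every property x gene set.

    One pool of ``iters`` subsamples of the shared size ``k`` is drawn per
    gene set and reused across properties, so all properties are assessed
    on identical subsamples; the connectivity test redraws its random null
    sets per subsample.
    """
    if not properties:
        raise ValueError("no properties to test")
    collection = collection.harmonize()
    if any(r.rank is None for r in collection.records):
        collection = rank_gene_sets(collection)
    k = resolve_subsample_size(collection, config.k)

    genes = np.array(collection.universe.sorted_genes())
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_universe = genes.size

    anno = [p for p in properties if p.kind == "annotation_set"]
    score = [p for p in properties if p.kind == "gene_score"]
    nets = [p for p in properties if p.kind == "network"]

    masks = np.zeros((len(anno), n_universe), dtype=bool)
    for j, prop in enumerate(anno):
        idx = [gene_pos[g] for g in prop.payload if g in gene_pos]
        masks[j, idx] = True
    anno_sizes = masks.sum(axis=1)

    score_ranks = np.full((len(score), n_universe), np.nan)
    score_tie, score_n = np.empty(len(score)), np.empty(len(score), dtype=int)
    for j, prop in enumerate(score):
        vals = prop.payload[prop.payload.index.isin(gene_pos)]
        prop.check_coverage(collection.universe)
        pos = np.array([gene_pos[g] for g in vals.index])
        v = vals.to_numpy(dtype=float)
        score_ranks[j, pos] = stats.rankdata(v)
        m = v.size
        _, counts = np.unique(v, return_counts=True)
        score_tie[j] = (counts ** 3 - counts).sum() / (m * (m - 1)) if m > 1 else 0.0
        score_n[j] = m

    net_data = []
    for prop in nets:
        net = prop.payload
        net_gene_pos = {g: i for i, g in enumerate(net.nodes)}
        # universe position -> network position (-1 when absent)
        net_lookup = np.full(n_universe, -1, dtype=int)
        for g, i in net_gene_pos.items():
            if g in gene_pos:
                net_lookup[gene_pos[g]] = i
        net_data.append(
            (prop, net.weights, net.weights.sum(axis=1), net_gene_pos, net_lookup)
        )

    by_rank = collection.by_rank()
    values = {}
    for rec in by_rank:
        t0 = time.perf_counter()
        set_idx = np.array(sorted(gene_pos[g] for g in rec.genes))
        subs = _subsample_pool(rng, set_idx, k, config.iters)
        col = {}
        if anno:
            conv = _annotation_convergence(masks, anno_sizes, subs, n_universe, k)
            for prop, v in zip(anno, conv):
                col[prop.id] = v
        for j, prop in enumerate(score):
            col[prop.id] = _score_convergence(
                score_ranks[j], score_tie[j], score_n[j], subs, prop.direction
            )
        for prop, w, gdeg, net_gene_pos, net_lookup in net_data:
            in_net = np.array(
                sorted(net_gene_pos[g] for g in rec.genes if g in net_gene_pos)
            )
            if in_net.size < 3:
                raise ValueError(
                    f"set {rec.id!r} has fewer than 3 genes in network {prop.id!r}"
                )
            if in_net.size == set_idx.size:
                net_subs = net_lookup[subs]  # whole set in network: reuse pool
            else:
                net_subs = _subsample_pool(
                    rng, in_net, min(k, in_net.size), config.iters
                )
            col[prop.id] = _network_convergence(
                w, gdeg, net_subs, config.n_null_sets, rng, config.null_line
            )
        values[rec.id] = col
        logger.info("set %s: %d properties in %.1fs", rec.id, len(col),
                    time.perf_counter() - t0)

    df = pd.DataFrame(values)  # rows: property ids, cols: set ids
    df = df.loc[[p.id for p in properties]]
    ranks = pd.Series({r.id: r.rank for r in by_rank})
    kinds = pd.Series({p.id: p.kind for p in properties})
    return ConvergenceMatrix(np.clip(df, P_FLOOR, 1.0), ranks, kinds)


def leave_class_out_trends(
    matrix: ConvergenceMatrix,
    collection: GeneSetCollection,
    drop_class: str,
    regime: str = "strict_0.05",
) -> pd.DataFrame:
    """Trend report with one variant class removed, reusing cached convergence.

    Convergence values are per (property, set) and do not depend on the
    ranking, so dropping a class only requires subsetting columns and
    re-ranking the survivors (controls re-tied at the bottom).
    """
    survivors = [r for r in collection.records if r.variant_class != drop_class]
    if len(survivors) < 4:
        raise ValueError(f"dropping {drop_class!r} leaves fewer than 4 sets")
    from dataclasses import replace as _replace

    sub = rank_gene_sets(
        GeneSetCollection([_replace(r, rank=None) for r in survivors],
                          collection.universe)
    )
    ids = sub.ids()
    sub_matrix = ConvergenceMatrix(
        matrix.values[ids].copy(),
        pd.Series(sub.ranks()),
        matrix.kinds,
    )
    report = trend_report(sub_matrix, regime=regime)
    report["dropped_class"] = drop_class
    return report


def run_full_analysis(
    collection: GeneSetCollection,
    properties: Sequence[FunctionalProperty],
    config: RunConfig,
    out_dir=None,
) -> dict:
    """Rank, converge, trend, permute, cluster — one seeded end-to-end run.

    Returns a dict with the ranked collection, the convergence matrix, one
    trend report per regime, permutation-null statistics, cluster labels
    and a JSON-serializable ``summary``.  When ``out_dir`` is given, writes
    ``ranks.tsv``, ``convergence.tsv``, ``trends_<regime>.tsv``,
    ``clusters.tsv`` and ``summary.json``, each with a header comment
    carrying version, seed and config hash.
    """
    rng = np.random.default_rng(config.seed)
    t0 = time.perf_counter()
    collection = rank_gene_sets(
        GeneSetCollection(
            [r for r in collection.records], collection.universe
        )
    ) if any(r.rank is None for r in collection.records) else collection
    logger.info("ranked %d sets", len(collection))

    matrix = compute_convergence_matrix(collection, properties, config, rng)
    logger.info("convergence matrix %s in %.1fs", matrix.values.shape,
                time.perf_counter() - t0)

    reports = {}
    counts = {}
    for regime in config.regimes:
        rep = trend_report(matrix, regime=regime)
        reports[regime] = rep
        counts[regime] = {
            str(level): int((rep["q"] < level).sum()) for level in config.fdr_levels
        }

    null = permutation_null(matrix, config.n_perm, rng)
    clusters = (
        cluster_properties(matrix) if len(matrix.property_ids) >= 2 else None
    )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "k": resolve_subsample_size(collection, config.k),
        "iters": config.iters,
        "n_perm": config.n_perm,
        "n_sets": len(collection),
        "n_properties": len(properties),
        "significant_trends": counts,
        "permutation_null": {
            "mean_r": float(null["pooled"].mean()),
            "sd_r": float(null["pooled"].std()),
            "analytic_sd": null["analytic_sd"],
        },
        "runtime_s": round(time.perf_counter() - t0, 2),
    }

    result = {
        "collection": collection,
        "matrix": matrix,
        "reports": reports,
        "null": null,
        "clusters": clusters,
        "summary": summary,
    }
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _header(config: RunConfig) -> str:
    return (
        f"# convergetrend v{__version__} seed={config.seed} "
        f"config={config.config_hash()}\n"
    )


def _write_outputs(result: dict, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    head = _header(config)

    ranks = pd.DataFrame(
        [
            (r.id, r.variant_class, r.effect_size, r.rank, len(r))
            for r in result["collection"].by_rank()
        ],
        columns=["set", "class", "odds_ratio", "rank", "n_genes"],
    )
    with open(out_dir / "ranks.tsv", "wt") as fh:
        fh.write(head)
        ranks.to_csv(fh, sep="\t", index=False)

    with open(out_dir / "convergence.tsv", "wt") as fh:
        fh.write(head)
        result["matrix"].values.to_csv(fh, sep="\t", index_label="property")

    for regime, rep in result["reports"].items():
        with open(out_dir / f"trends_{regime}.tsv", "wt") as fh:
            fh.write(head)
            rep.to_csv(fh, sep="\t", index_label="property")

    if result["clusters"] is not None:
        with open(out_dir / "clusters.tsv", "wt") as fh:
            fh.write(head)
            result["clusters"].to_csv(fh, sep="\t", index_label="property")

    with open(out_dir / "summary.json", "wt") as fh:
        json.dump(result["summary"], fh, indent=1, sort_keys=True)
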