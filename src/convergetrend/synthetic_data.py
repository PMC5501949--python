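"""Synthetic disease-gene-set scenarios with planted functional convergence.

A scenario emulates the statistical structure the trend analysis assumes: a
gene universe with per-gene length and multifunctionality attributes; a
collection of disease and control gene sets whose membership in a latent
"disease core" pool rises linearly with assigned effect rank; functional
properties (annotation sets, gene scores, one weighted network) of which a
known subset is planted on the core; and ground-truth labels for every
planted property.  With ``signal_slope = 0`` the scenario is fully null.

The default set specification mirrors an 11-set rare/common/control study:
seven candidate sets with odds ratios between 1.06 and 4.1 (two tied at
1.08, broken by a false-positive tie-break key) and four control sets tied
at the bottom rank 2.5.  Set-core membership is planted deterministically
(``round(q * size)`` core genes at rank-dependent probability ``q``) so the
planted gradient is realized exactly; which genes are drawn stays random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controls_robustness import multifunctionality_score
from .functional_tests import FunctionalProperty
from .genesets import (
    GeneSetCollection,
    GeneSetRecord,
    GeneUniverse,
    rank_gene_sets,
    read_gmt,
    write_gmt,
)
from .networks import WeightedGeneNetwork, read_edge_list

__all__ = [
    "SetSpec",
    "NetworkSpec",
    "ScoreSpec",
    "ScenarioConfig",
    "Scenario",
    "generate_scenario",
    "write_scenario",
    "read_scenario",
    "default_set_specs",
    "equal_size_set_specs",
]


@dataclass(frozen=True)
class SetSpec:
    """Size, class and effect size of one gene set to simulate."""

    id: str
    size: int
    variant_class: str
    effect_size: float | None = None
    tiebreak_key: float = 0.0
    swappable: bool = False


def default_set_specs() -> tuple[SetSpec, ...]:
    """The default 11-set study: 7 candidate sets, 4 controls.

    Sizes, odds ratios and classes follow the rare/common/control design of
    a de novo exome + GWAS meta-analysis: recurrent loss-of-function and CNV
    sets carry the strongest effects, missense and common-variant sets the
    weakest, and sibling/silent sets act as null controls.
    """
    return (
        SetSpec("denovo_lof_recurrent", 27, "strong", 4.1),
        SetSpec("denovo_cnv", 72, "strong", 3.95),
        SetSpec("denovo_missense_recurrent", 153, "weak", 1.6),
        SetSpec("denovo_lof", 341, "strong", 1.5),
        SetSpec("denovo_missense", 1339, "weak", 1.06),
        SetSpec("gwas_reported", 49, "weak", 1.08, tiebreak_key=1.0, swappable=True),
        SetSpec("gwas_adjacent", 116, "weak", 1.08, tiebreak_key=0.0, swappable=True),
        SetSpec("silent_proband", 590, "null_control"),
        SetSpec("lof_sibling", 174, "null_control"),
        SetSpec("missense_sibling", 1066, "null_control"),
        SetSpec("silent_sibling", 468, "null_control"),
    )


def equal_size_set_specs(size: int = 200) -> tuple[SetSpec, ...]:
    """Eleven equal-size sets (7 candidates, 4 controls) for calibration runs.

    Equal sizes make the sets exchangeable under the null, which is the
    appropriate design when checking type-I calibration of the trend
    statistic; the default heterogeneous sizes carry a structural
    small-set/large-set variance asymmetry (see the methods note).
    """
    specs = []
    for s in default_set_specs():
        specs.append(replace(s, size=size))
    return tuple(specs)


@dataclass(frozen=True)
class NetworkSpec:
    """Planted-module network structure.

    ``n_modules`` modules of ``module_size`` core genes get uniform
    within-module weight ``within_weight`` on top of a U(0, background_weight)
    background; an additional "artifact module" of ``artifact_size``
    non-core genes at ``artifact_weight`` hosts the study-design confound
    (sets tilted toward it show spurious connectivity).
    """

    n_modules: int = 3
    module_size: int = 100
    within_weight: float = 0.5
    background_weight: float = 0.04
    artifact_size: int = 300
    artifact_weight: float = 0.3


@dataclass(frozen=True)
class ScoreSpec:
    """Planted gene-score structure: core genes shifted by ``shift`` over
    N(0, noise_sd) background noise."""

    shift: float = 1.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one synthetic scenario.

    A candidate set at effect rank ``r`` draws a fraction
    ``q = signal_base + signal_slope * (r - r_min)`` of its genes from the
    disease core (``r_min`` = lowest candidate rank), so the weakest
    candidate set sits just above the controls' chance overlap and the
    signal concentrates in the strong sets; ``signal_slope = 0`` gives a
    fully null scenario (``signal_base`` is then ignored).  The core count
    is realized exactly (``round(q * size)``) rather than binomially
    thinned, so the planted gradient cannot be scrambled by shared
    sampling noise; which genes are drawn stays random.
    ``control_artifact`` switches on the study-design confound: every set
    (controls included) draws ``artifact_rate`` of its genes from the
    network's artifact module, mimicking ascertainment tilted toward hub
    genes.
    """

    n_genes: int = 8000
    set_specs: tuple[SetSpec, ...] = field(default_factory=default_set_specs)
    n_properties: int = 100
    n_planted: int = 14
    n_score_properties: int = 8
    n_planted_score: int = 2
    signal_slope: float = 0.08
    signal_base: float = 0.08
    core_size: int = 550
    property_size_range: tuple[int, int] = (150, 300)
    planted_core_fraction: float = 0.95
    network_spec: NetworkSpec | None = field(default_factory=NetworkSpec)
    score_spec: ScoreSpec = field(default_factory=ScoreSpec)
    control_artifact: bool = False
    artifact_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_slope < 0:
            raise ValueError("signal_slope must be >= 0")
        n_anno_planted = self.n_planted
        if n_anno_planted + self.n_score_properties > self.n_properties:
            raise ValueError("planted + score properties exceed n_properties")
        if self.n_planted_score > self.n_score_properties:
            raise ValueError("n_planted_score exceeds n_score_properties")
        if self.core_size >= self.n_genes:
            raise ValueError("core must be smaller than the universe")
        if self.set_specs and max(s.size for s in self.set_specs) > self.n_genes:
            raise ValueError("a gene set is larger than the universe")
        if self.property_size_range[1] >= self.n_genes:
            raise ValueError("property sizes must be below the universe size")


@dataclass
class Scenario:
    """A generated scenario: data plus ground truth."""

    config: ScenarioConfig
    universe: GeneUniverse
    collection: GeneSetCollection
    properties: list[FunctionalProperty]
    network: WeightedGeneNetwork | None
    ground_truth: dict


def _draw_disjoint(rng, pool: np.ndarray, n: int, taken: set) -> np.ndarray:
    avail = pool[~np.isin(pool, list(taken))] if taken else pool
    if n > avail.size:
        raise ValueError("infeasible sizes: pool exhausted while drawing a set")
    return rng.choice(avail, size=n, replace=False)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full synthetic scenario, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    lengths = np.maximum(
        50, np.round(rng.lognormal(mean=np.log(1500), sigma=0.9, size=n))
    ).astype(int)

    core = rng.choice(n, size=config.core_size, replace=False)
    core_set = set(core.tolist())
    noncore = np.setdiff1d(np.arange(n), core)

    # --- network -----------------------------------------------------------
    network = None
    module_members: list[np.ndarray] = []
    artifact = np.array([], dtype=int)
    if config.network_spec is not None:
        ns = config.network_spec
        w = rng.random((n, n), dtype=np.float32)
        w *= ns.background_weight
        w += w.T.copy()
        w *= 0.5
        n_module_genes = ns.n_modules * ns.module_size
        if n_module_genes > config.core_size:
            raise ValueError("planted modules exceed the core pool")
        module_pool = rng.choice(core, size=n_module_genes, replace=False)
        for m in range(ns.n_modules):
            idx = module_pool[m * ns.module_size:(m + 1) * ns.module_size]
            w[np.ix_(idx, idx)] = ns.within_weight
            module_members.append(idx)
        if ns.artifact_size:
            artifact = rng.choice(noncore, size=ns.artifact_size, replace=False)
            w[np.ix_(artifact, artifact)] = ns.artifact_weight
        np.fill_diagonal(w, 0.0)
        network = WeightedGeneNetwork(tuple(gene_ids), w, validate=False)

    # --- gene sets ---------------------------------------------------------
    records = [
        GeneSetRecord(
            id=s.id,
            genes=frozenset({"__tmp__"}),
            variant_class=s.variant_class,
            effect_size=s.effect_size,
            tiebreak_key=s.tiebreak_key,
            swappable=s.swappable,
        )
        for s in config.set_specs
    ]
    # ranks depend only on effect sizes/classes; assign them before drawing genes
    tmp_universe = GeneUniverse(frozenset(gene_ids))
    ranked = rank_gene_sets(GeneSetCollection(records, tmp_universe))

    candidate_ranks = [r.rank for r in ranked.records if not r.is_control]
    r_min = min(candidate_ranks) if candidate_ranks else 0.0
    filled = []
    for rec, spec in zip(ranked.records, config.set_specs):
        taken: set = set()
        chosen: list[int] = []
        size = spec.size
        if config.control_artifact and artifact.size:
            n_art = min(int(round(size * config.artifact_rate)), artifact.size)
            picked = rng.choice(artifact, size=n_art, replace=False)
            chosen.extend(picked.tolist())
            taken.update(picked.tolist())
        rest = size - len(chosen)
        if rec.is_control or config.signal_slope == 0:
            picked = _draw_disjoint(rng, np.arange(n), rest, taken)
            chosen.extend(picked.tolist())
        else:
            q = min(
                max(config.signal_base
                    + config.signal_slope * (rec.rank - r_min), 0.0),
                0.95,
            )
            n_core = min(int(round(rest * q)), config.core_size, rest)
            picked = rng.choice(core, size=n_core, replace=False)
            chosen.extend(picked.tolist())
            taken.update(picked.tolist())
            picked = _draw_disjoint(rng, noncore, rest - n_core, taken)
            chosen.extend(picked.tolist())
        filled.append(replace(rec, genes=frozenset(gene_ids[chosen])))

    # --- annotation properties ---------------------------------------------
    lo, hi = config.property_size_range
    n_anno = config.n_properties - config.n_score_properties
    n_anno_planted = config.n_planted
    properties: list[FunctionalProperty] = []
    planted_ids: list[str] = []
    anno_sets: list[frozenset] = []
    for j in range(n_anno):
        pid = f"F{j:04d}"
        m = int(rng.integers(lo, hi + 1))
        if j < n_anno_planted and config.signal_slope > 0:
            mc = min(int(round(config.planted_core_fraction * m)), config.core_size)
            genes = np.concatenate([
                rng.choice(core, size=mc, replace=False),
                rng.choice(noncore, size=m - mc, replace=False),
            ])
            planted_ids.append(pid)
        else:
            genes = rng.choice(n, size=m, replace=False)
        anno = frozenset(gene_ids[genes])
        anno_sets.append(anno)
        properties.append(FunctionalProperty(pid, "annotation_set", anno))

    # --- score properties ---------------------------------------------------
    core_indicator = np.zeros(n)
    core_indicator[core] = 1.0
    for j in range(config.n_score_properties):
        pid = f"F{n_anno + j:04d}"
        noise = rng.normal(0.0, config.score_spec.noise_sd, size=n)
        if j < config.n_planted_score and config.signal_slope > 0:
            values = noise + config.score_spec.shift * core_indicator
            planted_ids.append(pid)
        else:
            values = noise
        properties.append(
            FunctionalProperty(
                pid, "gene_score",
                pd.Series(values, index=gene_ids), direction="greater",
            )
        )

    if network is not None:
        pid = "network"
        properties.append(FunctionalProperty(pid, "network", network))
        if config.signal_slope > 0 and module_members:
            planted_ids.append(pid)

    # --- universe with attributes -------------------------------------------
    universe = GeneUniverse(
        genes=frozenset(gene_ids),
        cds_length=dict(zip(gene_ids, lengths.tolist())),
    )
    mf = multifunctionality_score(universe, anno_sets)
    universe = GeneUniverse(
        genes=frozenset(gene_ids),
        cds_length=dict(zip(gene_ids, lengths.tolist())),
        multifunctionality=mf["count"].astype(float).to_dict(),
    )
    collection = GeneSetCollection(filled, universe)

    ground_truth = {
        "planted_properties": sorted(planted_ids),
        "null_properties": sorted(
            p.id for p in properties if p.id not in planted_ids
        ),
        "core_genes": sorted(gene_ids[core].tolist()),
        "artifact_genes": sorted(gene_ids[artifact].tolist()),
        "module_genes": [sorted(gene_ids[m].tolist()) for m in module_members],
        "signal_slope": config.signal_slope,
        "seed": config.seed,
    }
    return Scenario(config, universe, collection, properties, network, ground_truth)


def write_scenario(scenario: Scenario, directory, *, max_network_nodes: int = 2000):
    """Write a scenario to disk as GMT/TSV/JSON files.

    The network is written as a TSV edge list, which is only practical for
    small networks; pass a scenario without a network (or raise the cap)
    otherwise.  Files written: ``universe.tsv``, ``sets.gmt``,
    ``properties.gmt``, ``scores.tsv``, ``network_edges.tsv``,
    ``manifest.yaml``, ``ground_truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    uni = scenario.universe
    genes = uni.sorted_genes()
    pd.DataFrame(
        {
            "gene": genes,
            "cds_length": [uni.cds_length[g] for g in genes],
            "multifunctionality": [uni.multifunctionality[g] for g in genes],
        }
    ).to_csv(directory / "universe.tsv", sep="\t", index=False)

    write_gmt(
        directory / "sets.gmt",
        [(r.id, r.variant_class, r.genes) for r in scenario.collection.records],
    )
    anno = [p for p in scenario.properties if p.kind == "annotation_set"]
    write_gmt(directory / "properties.gmt", [(p.id, "annotation", p.payload) for p in anno])

    score_props = [p for p in scenario.properties if p.kind == "gene_score"]
    if score_props:
        wide = pd.DataFrame(
            {p.id: p.payload.reindex(genes) for p in score_props},
            index=pd.Index(genes, name="gene"),
        )
        wide.to_csv(directory / "scores.tsv", sep="\t")

    if scenario.network is not None:
        if len(scenario.network) > max_network_nodes:
            raise ValueError(
                f"network has {len(scenario.network)} nodes; refusing to write "
                f"more than {max_network_nodes} as a text edge list"
            )
        scenario.network.to_edge_list(directory / "network_edges.tsv")

    manifest = {
        "seed": scenario.config.seed,
        "signal_slope": scenario.config.signal_slope,
        "sets": [
            {
                "id": r.id,
                "class": r.variant_class,
                "odds_ratio": r.effect_size,
                "tiebreak_key": r.tiebreak_key,
                "swappable": r.swappable,
            }
            for r in scenario.collection.records
        ],
        "properties": {
            "annotation_gmt": "properties.gmt",
            "scores_tsv": "scores.tsv" if score_props else None,
            "network_edges_tsv": (
                "network_edges.tsv" if scenario.network is not None else None
            ),
        },
    }
    with open(directory / "manifest.yaml", "wt") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(directory / "ground_truth.json", "wt") as fh:
        json.dump(scenario.ground_truth, fh, indent=1, sort_keys=True)


def read_scenario(directory) -> Scenario:
    """Read back a scenario written by :func:`write_scenario`."""
    directory = Path(directory)
    uni_df = pd.read_csv(directory / "universe.tsv", sep="\t", dtype={"gene": str})
    universe = GeneUniverse(
        genes=frozenset(uni_df["gene"]),
        cds_length=dict(zip(uni_df["gene"], uni_df["cds_length"].astype(int))),
        multifunctionality=dict(
            zip(uni_df["gene"], uni_df["multifunctionality"].astype(float))
        ),
    )
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    set_meta = {s["id"]: s for s in manifest["sets"]}
    records = []
    for set_id, desc, genes in read_gmt(directory / "sets.gmt"):
        meta = set_meta[set_id]
        records.append(
            GeneSetRecord(
                id=set_id,
                genes=genes,
                variant_class=meta["class"],
                effect_size=meta["odds_ratio"],
                tiebreak_key=meta["tiebreak_key"],
                swappable=meta["swappable"],
            )
        )
    collection = rank_gene_sets(GeneSetCollection(records, universe))

    properties: list[FunctionalProperty] = []
    for pid, _, genes in read_gmt(directory / "properties.gmt"):
        properties.append(FunctionalProperty(pid, "annotation_set", genes))
    scores_path = directory / "scores.tsv"
    if scores_path.exists():
        wide = pd.read_csv(scores_path, sep="\t", index_col=0)
        wide.index = wide.index.astype(str)
        for col in wide.columns:
            properties.append(FunctionalProperty(col, "gene_score", wide[col]))
    network = None
    net_path = directory / "network_edges.tsv"
    if net_path.exists():
        network = read_edge_list(net_path)
        properties.append(FunctionalProperty("network", "network", network))

    with open(directory / "ground_truth.json") as fh:
        ground_truth = json.load(fh)
    # stub config: carries run metadata only, not the generating parameters
    config = ScenarioConfig(
        n_genes=len(universe),
        set_specs=(),
        n_properties=0,
        n_planted=0,
        n_score_properties=0,
        n_planted_score=0,
        core_size=1,
        property_size_range=(1, 2),
        network_spec=None,
        seed=manifest["seed"],
        signal_slope=manifest["signal_slope"],
    )
    return Scenario(config, universe, collection, properties, network, ground_truth)
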