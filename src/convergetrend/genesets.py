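"""Gene universes, disease/control gene sets, effect sizes and ranking.

A study is a collection of candidate gene sets, each tagged with a variant
class (``null_control``, ``weak`` or ``strong``) and, for non-control sets,
an average effect size expressed as an odds ratio.  Sets are ranked
ascending by effect size; all control sets share the averaged bottom ranks,
so a study with four controls assigns each of them rank 2.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_CLASSES = ("null_control", "weak", "strong")

__all__ = [
    "GeneUniverse",
    "GeneSetRecord",
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "compute_odds_ratio",
    "rank_gene_sets",
    "pairwise_overlap_test",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT lines; carries the 1-based line number."""


@dataclass(frozen=True)
class GeneUniverse:
    """The background set of genes with optional per-gene attributes.

    Parameters
    ----------
    genes
        Unique gene identifiers (case-sensitive strings).
    cds_length
        Optional mapping gene -> coding-sequence length in base pairs (> 0).
    multifunctionality
        Optional mapping gene -> multifunctionality score (>= 0), i.e. the
        number of annotation sets the gene belongs to (possibly standardized).
    """

    genes: frozenset[str]
    cds_length: Mapping[str, int] | None = None
    multifunctionality: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("universe must contain at least one gene")
        for name, attr in (("cds_length", self.cds_length),
                           ("multifunctionality", self.multifunctionality)):
            if attr is None:
                continue
            missing = set(attr) - self.genes
            if missing:
                raise ValueError(
                    f"{name} has keys outside the universe: {sorted(missing)[:5]}"
                )
        if self.cds_length is not None:
            if any(v <= 0 for v in self.cds_length.values()):
                raise ValueError("cds_length values must be positive")
        if self.multifunctionality is not None:
            if any(v < 0 for v in self.multifunctionality.values()):
                raise ValueError("multifunctionality values must be non-negative")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)

    def attribute(self, name: str) -> Mapping[str, float]:
        attr = getattr(self, name, None)
        if attr is None:
            raise ValueError(f"universe has no '{name}' attribute")
        return attr


@dataclass
class GeneSetRecord:
    """One candidate or control gene set.

    ``effect_size`` is an odds ratio (dimensionless, >= 0) and must be
    undefined exactly for ``null_control`` sets.  ``tiebreak_key`` breaks
    equal odds ratios: a higher key means fewer expected false positives
    and hence a higher rank.  ``rank`` is assigned by :func:`rank_gene_sets`.
    """

    id: str
    genes: frozenset[str]
    variant_class: str
    effect_size: float | None = None
    tiebreak_key: float = 0.0
    rank: float | None = None
    swappable: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"unknown variant class {self.variant_class!r}; "
                f"expected one of {VARIANT_CLASSES}"
            )
        if self.is_control and self.effect_size is not None:
            raise ValueError(f"control set {self.id!r} must not carry an effect size")
        if not self.is_control:
            if self.effect_size is None:
                raise ValueError(f"non-control set {self.id!r} requires an effect size")
            if self.effect_size < 0:
                raise ValueError("effect size (odds ratio) must be >= 0")

    @property
    def is_control(self) -> bool:
        return self.variant_class == "null_control"

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered list of gene sets over a shared universe."""

    records: list[GeneSetRecord]
    universe: GeneUniverse

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("gene set ids must be unique")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, set_id: str) -> GeneSetRecord:
        for r in self.records:
            if r.id == set_id:
                return r
        raise KeyError(set_id)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def harmonize(self) -> "GeneSetCollection":
        """Drop genes absent from the universe, warning per affected set."""
        out = []
        for r in self.records:
            kept = r.genes & self.universe.genes
            dropped = len(r.genes) - len(kept)
            if dropped:
                logger.warning(
                    "set %s: dropped %d gene(s) absent from the universe",
                    r.id, dropped,
                )
            if not kept:
                raise ValueError(f"set {r.id!r} has no genes in the universe")
            out.append(replace(r, genes=kept))
        return GeneSetCollection(out, self.universe)

    def by_rank(self) -> list[GeneSetRecord]:
        """Records sorted ascending by rank (requires ranks assigned)."""
        if any(r.rank is None for r in self.records):
            raise ValueError("ranks not assigned; call rank_gene_sets first")
        return sorted(self.records, key=lambda r: (r.rank, r.id))

    def ranks(self) -> dict[str, float]:
        return {r.id: r.rank for r in self.by_rank()}


def read_gmt(path) -> list[tuple[str, str, frozenset[str]]]:
    """Parse a GMT file: one gene set per tab-separated line.

    Each line must have at least three fields: set id, description, and one
    or more gene identifiers.  Duplicate genes within a line are collapsed.
    """
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: empty gene set")
            records.append((set_id, desc, genes))
    return records


def write_gmt(path, records: Iterable[tuple[str, str, Iterable[str]]]) -> None:
    """Write gene sets in GMT format, genes in sorted order."""
    with open(path, "wt", encoding="utf-8") as fh:
        for set_id, desc, genes in records:
            fh.write("\t".join([set_id, desc, *sorted(set(genes))]) + "\n")


def compute_odds_ratio(
    proband_mut: int,
    proband_silent: int,
    sibling_mut: int,
    sibling_silent: int,
    *,
    pseudocount: bool = False,
) -> float:
    """Odds ratio of mutation burden in probands relative to sibling controls.

    Within each group the odds are the ratio of observed (damaging) mutation
    counts to silent mutation counts; the effect size is the ratio of the
    proband odds to the sibling odds.  A value above 1 indicates a proband
    excess.  With ``pseudocount=True`` the Haldane-Anscombe correction
    (+0.5 to all four counts) guards against zero cells.
    """
    counts = [proband_mut, proband_silent, sibling_mut, sibling_silent]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if pseudocount:
        counts = [c + 0.5 for c in counts]
    pm, ps, sm, ss = counts
    if ps == 0 or ss == 0 or sm == 0:
        raise ValueError(
            "zero denominator; enable pseudocount for zero cells"
        )
    return (pm / ps) / (sm / ss)


def rank_gene_sets(collection: GeneSetCollection) -> GeneSetCollection:
    """Assign effect-size ranks: controls tied at the bottom, the rest ascending.

    Non-control sets are ranked ascending by odds ratio, ties broken by
    ``tiebreak_key`` (higher key ranks higher); sets equal on both are
    average-tied.  All control sets receive the average of the lowest ranks
    ``1..k`` for ``k`` controls (2.5 for four controls).
    """
    controls = [r for r in collection.records if r.is_control]
    candidates = [r for r in collection.records if not r.is_control]
    if not candidates:
        raise ValueError("cannot rank a collection of only control sets")
    k = len(controls)
    control_rank = (k + 1) / 2.0 if k else None

    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].effect_size, candidates[i].tiebreak_key),
    )
    ranks = np.empty(len(candidates))
    pos = 0
    while pos < len(order):
        j = pos
        key = (candidates[order[pos]].effect_size, candidates[order[pos]].tiebreak_key)
        while j < len(order) and (
            candidates[order[j]].effect_size,
            candidates[order[j]].tiebreak_key,
        ) == key:
            j += 1
        tied_ranks = [k + 1 + q for q in range(pos, j)]
        for q in range(pos, j):
            ranks[order[q]] = float(np.mean(tied_ranks))
        pos = j

    new_records = []
    cand_iter = iter(range(len(candidates)))
    for r in collection.records:
        if r.is_control:
            new_records.append(replace(r, rank=control_rank))
        else:
            idx = candidates.index(r)
            new_records.append(replace(r, rank=float(ranks[idx])))
    return GeneSetCollection(new_records, collection.universe)


def pairwise_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: GeneUniverse,
) -> tuple[int, float]:
    """Overlap count and one-sided (enrichment) hypergeometric p of two sets.

    p is the upper-tail probability of observing at least the seen overlap
    when ``|set_a|`` genes are drawn from the universe without replacement,
    with ``|set_b]`` marked as successes.
    """
    a = frozenset(set_a)
    b = frozenset(set_b)
    n = len(universe)
    if n == 0:
        raise ValueError("universe is empty")
    if not a <= universe.genes or not b <= universe.genes:
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, n, len(b), len(a)))
    return overlap, min(p, 1.0)
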