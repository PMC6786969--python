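"""Gene-tree sorting and counting for paleopolyploidy detection.

A whole-genome duplication leaves a burst of gene duplications shared by all
descendant taxa.  Given a ladderized species tree and a collection of rooted
gene trees, each gene-(sub)tree node is assigned to a species-tree node by LCA
mapping; a node whose child maps to the same species node records a shared
duplication there.  The per-node percentage of duplicated subtrees is then
compared against the empirical distribution of the same statistic under
birth-death gene-family simulation without WGD: a node whose observed
percentage exceeds the upper quantile of the null under every simulated rate
condition is flagged as a WGD candidate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .trees import GeneTree, Node, SpeciesTree, TreeError, lca_map

__all__ = [
    "SubtreeRecord",
    "NodeTally",
    "WgdCall",
    "collect_subtrees",
    "per_tree_counts",
    "tally_duplications",
    "bootstrap_tallies",
    "call_wgd",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtreeRecord:
    """One gene-tree node mapped to one species-tree node.

    ``duplication`` is the reconciliation flag (at least one child maps to
    the same species node); ``shared_duplication`` additionally requires BOTH
    children to map there, i.e. both copies survive across both daughter
    lineages — the signature of a duplication shared by the descendant taxa.
    ``apex`` marks the top of a maximal same-node-mapped subtree (the gene
    node's parent maps elsewhere), so apex records partition each gene tree
    into at most one countable subtree per species node visit.
    """

    species_index: int
    gene_node: Node
    concordant: bool
    duplication: bool
    shared_duplication: bool
    apex: bool


@dataclass(frozen=True)
class NodeTally:
    species_index: int
    clade: frozenset
    n_subtrees: int
    n_duplicated: int

    @property
    def percentage(self) -> float:
        if self.n_subtrees == 0:
            return math.nan
        return 100.0 * self.n_duplicated / self.n_subtrees


@dataclass(frozen=True)
class WgdCall:
    species_index: int
    observed_percentage: float
    null_bands: Mapping[str, tuple[float, float]]  # condition -> (lower, upper)
    level: float
    flagged: bool


def _concordant(gene_node: Node, gene_tree: GeneTree, species_tree: SpeciesTree,
                mapping: Mapping[Node, Node]) -> bool:
    """Is the gene subtree consistent with the species relationships?

    Duplicate copies of one taxon are exchangeable: a node both of whose
    children map to the same species node as itself is a duplication vertex
    and is concordant when each child subtree is.  A speciation vertex is
    concordant when its children's taxon sets are disjoint and separate into
    the two daughter clades of the corresponding species node.
    """
    if gene_node.is_leaf:
        return True
    taxa = frozenset(gene_tree.taxon(n) for n in gene_node.leaves())
    spec = mapping[gene_node]
    c1, c2 = gene_node.children
    t1 = frozenset(gene_tree.taxon(n) for n in c1.leaves())
    t2 = frozenset(gene_tree.taxon(n) for n in c2.leaves())
    if mapping[c1] is spec or mapping[c2] is spec or (t1 & t2):
        # duplication vertex at `spec`: both halves evolve on the same clade
        return (_concordant(c1, gene_tree, species_tree, mapping)
                and _concordant(c2, gene_tree, species_tree, mapping))
    if spec.is_leaf:
        return True  # within-taxon structure only
    if len(taxa) < 2:
        return True
    left, right = (frozenset(child.leaf_labels()) for child in spec.children)
    ok = (t1 <= left and t2 <= right) or (t1 <= right and t2 <= left)
    if not ok:
        return False
    return (_concordant(c1, gene_tree, species_tree, mapping)
            and _concordant(c2, gene_tree, species_tree, mapping))


def collect_subtrees(gene_tree: GeneTree, species_tree: SpeciesTree) -> list[SubtreeRecord]:
    """Map every internal gene-tree node onto the species tree.

    ``species_tree`` must be ladderized (internal nodes indexed).  Each
    internal gene-tree node g mapping to internal species node N yields one
    record; its duplication flag is set when the LCA map of at least one child
    of g also equals N.
    """
    if len(gene_tree.leaves()) < 2:
        raise TreeError("gene tree must have at least 2 leaves")
    if any(n.index is None for n in species_tree.internal_nodes()):
        raise TreeError("species tree must be ladderized (indexed) first")
    mapping = lca_map(gene_tree, species_tree)
    records = []
    for g in gene_tree.preorder():
        if g.is_leaf:
            continue
        spec = mapping[g]
        if spec.is_leaf:
            continue  # within-taxon duplications are not shared by descendants
        child_hits = [mapping[c] is spec for c in g.children]
        conc = _concordant(g, gene_tree, species_tree, mapping)
        apex = g.parent is None or mapping[g.parent] is not spec
        records.append(SubtreeRecord(
            species_index=spec.index, gene_node=g, concordant=conc,
            duplication=any(child_hits), shared_duplication=all(child_hits),
            apex=apex))
    return records


def _is_dup(rec: SubtreeRecord, criterion: str) -> bool:
    return rec.shared_duplication if criterion == "shared" else rec.duplication


def per_tree_counts(
    gene_trees: Iterable[GeneTree],
    species_tree: SpeciesTree,
    denominator: str = "all",
    criterion: str = "shared",
    unit: str = "apex",
) -> tuple[list[dict[int, tuple[int, int]]], int]:
    """Per gene tree: species node -> (n_subtrees, n_duplicated).

    ``unit`` chooses the counting unit: ``"apex"`` (default) counts each
    maximal same-node-mapped subtree once, duplicated when any vertex inside
    it meets the criterion; ``"subtree"`` counts every mapped vertex.
    ``denominator`` selects which records count (``"all"`` mapped records or
    only ``"concordant"`` ones); ``criterion`` selects the duplication flag
    (``"shared"`` — both children survive across the node, the burst
    statistic — or ``"reconciliation"`` — any child maps to the node).
    Returns the per-tree count dicts and the number of skipped trees.
    """
    if denominator not in ("all", "concordant"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if criterion not in ("shared", "reconciliation"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if unit not in ("apex", "subtree"):
        raise ValueError(f"unknown unit {unit!r}")
    out = []
    n_skipped = 0
    for tree in gene_trees:
        try:
            records = collect_subtrees(tree, species_tree)
        except TreeError as exc:
            n_skipped += 1
            log.warning("skipping gene tree: %s", exc)
            continue
        records = [r for r in records
                   if denominator == "all" or r.concordant]
        counts: dict[int, tuple[int, int]] = {}
        if unit == "subtree":
            for rec in records:
                ns, nd = counts.get(rec.species_index, (0, 0))
                counts[rec.species_index] = (ns + 1, nd + int(_is_dup(rec, criterion)))
        else:
            # attribute each vertex to the apex of its maximal mapped subtree
            by_node = {r.gene_node: r for r in records}
            apex_of: dict = {}
            for rec in records:  # records come in preorder
                g = rec.gene_node
                parent_rec = by_node.get(g.parent)
                if (rec.apex or parent_rec is None
                        or parent_rec.species_index != rec.species_index
                        or g.parent not in apex_of):
                    apex_of[g] = g
                else:
                    apex_of[g] = apex_of[g.parent]
            dup_components = {(rec.species_index, apex_of[rec.gene_node])
                              for rec in records if _is_dup(rec, criterion)}
            for rec in records:
                if apex_of[rec.gene_node] is not rec.gene_node:
                    continue
                ns, nd = counts.get(rec.species_index, (0, 0))
                is_dup = (rec.species_index, rec.gene_node) in dup_components
                counts[rec.species_index] = (ns + 1, nd + int(is_dup))
        out.append(counts)
    return out, n_skipped


def _aggregate(counts: Iterable[dict[int, tuple[int, int]]],
               species_tree: SpeciesTree) -> list[NodeTally]:
    n_sub: dict[int, int] = {}
    n_dup: dict[int, int] = {}
    for tree_counts in counts:
        for idx, (ns, nd) in tree_counts.items():
            n_sub[idx] = n_sub.get(idx, 0) + ns
            n_dup[idx] = n_dup.get(idx, 0) + nd
    clades = {n.index: n.leaf_labels() for n in species_tree.internal_nodes()}
    return [
        NodeTally(species_index=i, clade=clades[i],
                  n_subtrees=n_sub[i], n_duplicated=n_dup.get(i, 0))
        for i in sorted(n_sub)
    ]


def tally_duplications(
    gene_trees: Iterable[GeneTree],
    species_tree: SpeciesTree,
    denominator: str = "all",
    criterion: str = "shared",
    unit: str = "apex",
) -> list[NodeTally]:
    """Aggregate shared-duplication percentages per species-tree node.

    Nodes never visited by any subtree are omitted (missing, not zero);
    trees that fail mapping are logged and skipped.  See
    :func:`per_tree_counts` for the ``denominator``/``criterion``/``unit``
    switches.
    """
    counts, n_skipped = per_tree_counts(gene_trees, species_tree,
                                        denominator, criterion, unit)
    if not counts and n_skipped == 0:
        raise ValueError("empty gene-tree collection")
    tallies = _aggregate(counts, species_tree)
    if n_skipped:
        log.info("skipped %d gene trees", n_skipped)
    return tallies


def bootstrap_tallies(
    gene_trees: Sequence[GeneTree],
    species_tree: SpeciesTree,
    n_replicates: int = 200,
    seed: Optional[int] = None,
    denominator: str = "all",
    criterion: str = "shared",
    unit: str = "apex",
) -> list[list[NodeTally]]:
    """Replicate tally lists by bootstrap resampling over gene trees.

    The sampling unit is the gene tree, so the replicate-to-replicate spread
    of the per-node percentages reflects the tree-level sampling noise of the
    simulated null; feed the result to :func:`call_wgd`.
    """
    counts, _ = per_tree_counts(gene_trees, species_tree, denominator,
                                criterion, unit)
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        idx = rng.integers(0, len(counts), size=len(counts))
        replicates.append(_aggregate((counts[i] for i in idx), species_tree))
    return replicates


def call_wgd(
    observed: Sequence[NodeTally],
    nulls: Mapping[str, Sequence[Sequence[NodeTally]]],
    level: float = 0.95,
) -> list[WgdCall]:
    """Flag species-tree nodes whose duplication percentage escapes the null.

    ``nulls`` maps a rate-condition name (e.g. multiplier "0.5") to a list of
    replicate tally lists.  Per node and condition the empirical two-sided
    band [(1-level)/2, 1-(1-level)/2] of null percentages is computed; a node
    is flagged only when its observed percentage exceeds the upper quantile in
    EVERY condition.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    calls = []
    for tally in observed:
        bands: dict[str, tuple[float, float]] = {}
        exceeds_all = True
        for cond, replicates in nulls.items():
            vals = []
            for rep in replicates:
                for t in rep:
                    if t.species_index == tally.species_index:
                        vals.append(t.percentage)
            if not vals:
                raise ValueError(
                    f"no null tallies for species node {tally.species_index} "
                    f"in condition {cond!r}")
            arr = np.asarray(vals, dtype=float)
            lower, upper = np.quantile(arr, [lo_q, hi_q])
            bands[cond] = (float(lower), float(upper))
            if not (tally.percentage > upper):
                exceeds_all = False
        calls.append(WgdCall(
            species_index=tally.species_index,
            observed_percentage=tally.percentage,
            null_bands=bands,
            level=level,
            flagged=exceeds_all,
        ))
    return calls
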