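"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the stochastic structure each analysis assumes —
gene trees evolving by duplication and loss inside a species tree (with an
optional whole-genome duplication episode), gene-family counts under the
same linear birth-death law, codon pairs at a controlled synonymous
divergence, Ks values from Gaussian mixtures, and genome gene orders
descended through speciation + WGD + fractionation + inversion + tandem
duplication — and label everything, so that estimator failures localise to
the estimator, not the data.

All generators are reproducible bit-for-bit given (scenario, seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bd import BDParams, RootPrior, GeneCountMatrix, simulate_gene_tree, _alpha_beta
from .ks import _site_counts, _AA, _STOPS, _BASES, CodonAlignmentPair
from .synteny import GeneLocus, HomologyPair, SyntenyBlock
from .trees import GeneTree, Node, SpeciesTree, parse_newick

__all__ = [
    "fern_species_tree",
    "sim_gene_trees_wgd",
    "sim_gene_counts",
    "sim_ks_mixture",
    "sim_codon_pairs",
    "LineageEvents",
    "EvolutionScenario",
    "sim_genome_evolution",
    "two_genome_scenario",
    "evaluate_blocks",
]


# ---------------------------------------------------------------------------
# The packaged fern-like demo fixture


_FERN_RELATIVE_DEPTHS = {
    "Dipteris": 1.0, "Lygodium": 280 / 300, "Blechnum": 220 / 300,
    "Pilularia": 200 / 300, "Salvinia": 180 / 300, "Azolla": 80 / 300,
}


def fern_species_tree(depth: float = 100.0) -> SpeciesTree:
    """A 7-taxon ultrametric fern-like species tree (synthetic fixture).

    The topology follows the sampled lineages — two Azolla species, Salvinia
    and Pilularia (the heterosporous Salviniales), a polypod (Blechnum) inside
    the core leptosporangiates, with Lygodium and Dipteris outside — while the
    branch lengths are plausible relative divergence depths scaled to a root
    depth of ``depth`` time units; they are not measured values.  The default
    depth of 100 keeps the all-taxa-conditioned gene-tree simulator's
    acceptance probability workable even at five-fold rates while leaving the
    birth-death rates well identified.
    """
    s = depth / 300.0
    nwk = (
        f"(Dipteris:{300 * s!r},(Lygodium:{280 * s!r},(Blechnum:{220 * s!r},"
        f"(Pilularia:{200 * s!r},(Salvinia:{180 * s!r},"
        f"(Azolla_filiculoides:{80 * s!r},Azolla_caroliniana:{80 * s!r})"
        f":{100 * s!r}):{20 * s!r}):{20 * s!r}):{60 * s!r}):{20 * s!r});"
    )
    return parse_newick(nwk, kind="species")


def find_clade(tree: SpeciesTree, taxa: Iterable[str]) -> Node:
    """The smallest node whose leaves are exactly ``taxa``."""
    wanted = frozenset(taxa)
    for node in tree.preorder():
        if node.leaf_labels() == wanted:
            return node
    raise ValueError(f"no clade with leaves {sorted(wanted)}")


# ---------------------------------------------------------------------------
# Gene trees with an injected WGD


def sim_gene_trees_wgd(
    tree: SpeciesTree,
    params: BDParams,
    wgd_node: Optional[Node],
    retention: float,
    n: int,
    seed: Optional[int] = None,
    require_all_taxa: bool = True,
) -> tuple[list[GeneTree], dict]:
    """Simulate ``n`` gene trees with a WGD episode at ``wgd_node``.

    Background duplication/loss follows the birth-death simulator; at the WGD
    node every surviving lineage doubles and the extra copy is retained with
    probability ``retention`` (retention 0 reproduces the no-WGD null on the
    same seed path).  Returns the trees and a truth record.
    """
    if not 0.0 <= retention <= 1.0:
        raise ValueError("retention must be in [0, 1]")
    rng = np.random.default_rng(seed)
    trees = [
        simulate_gene_tree(tree, params, require_all_taxa=require_all_taxa,
                           rng=rng, wgd_node=wgd_node, retention=retention)
        for _ in range(n)
    ]
    truth = {
        "wgd_clade": sorted(wgd_node.leaf_labels()) if wgd_node is not None else None,
        "retention": retention,
        "params": (params.lam, params.mu, params.multiplier),
        "n": n,
    }
    return trees, truth


# ---------------------------------------------------------------------------
# Gene-count matrices


def sim_gene_counts(
    tree: SpeciesTree,
    params: BDParams,
    prior: RootPrior,
    n_families: int,
    seed: Optional[int] = None,
) -> tuple[GeneCountMatrix, pd.DataFrame]:
    """Gene-family counts evolved by the exact birth-death transition law.

    The root count is a shifted-geometric draw; along each branch every gene
    independently leaves 0 descendants with probability alpha or a geometric
    number with parameter beta — the same closed-form law the likelihood
    uses.  Returns the matrix and a truth frame (root count, root-spanning
    flag per family).
    """
    rng = np.random.default_rng(seed)
    lam, mu = params.effective
    taxa = sorted(tree.taxa)
    root_counts = rng.geometric(prior.p, size=n_families)

    counts_at: dict[Node, np.ndarray] = {tree.root: root_counts.astype(np.int64)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        alpha, beta = _alpha_beta(lam, mu, node.length or 0.0)
        start = counts_at[node.parent]
        survivors = rng.binomial(start, 1.0 - alpha)
        # sum of k geometric(1-beta) variables = k + NegBinomial(k, 1-beta)
        extra = np.zeros_like(survivors)
        pos = survivors > 0
        if beta > 0:
            extra[pos] = rng.negative_binomial(survivors[pos], 1.0 - beta)
        counts_at[node] = survivors + extra

    leaf_counts = {leaf.label: counts_at[leaf] for leaf in tree.leaves()}
    df = pd.DataFrame(leaf_counts, columns=taxa,
                      index=[f"fam{i}" for i in range(n_families)])
    matrix = GeneCountMatrix(df, m_max=100)
    spanning = matrix.root_spanning(tree)
    truth = pd.DataFrame({
        "root_count": root_counts,
        "root_spanning": spanning.to_numpy(),
    }, index=df.index)
    return matrix, truth


# ---------------------------------------------------------------------------
# Ks mixtures


@dataclass(frozen=True)
class KsSample:
    values: np.ndarray
    labels: np.ndarray  # component index per retained value
    n_truncated: int
    means: tuple
    sds: tuple


def sim_ks_mixture(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    n_per_component: Optional[int] = None,
    n_total: Optional[int] = None,
    seed: Optional[int] = None,
    lo: float = 0.05,
    hi: float = 5.0,
) -> KsSample:
    """Labeled Gaussian-mixture Ks draws, truncated to the usable range.

    Give either ``n_per_component`` (equal draws per component) or
    ``n_total`` with ``weights`` (multinomial allocation).  Values outside
    [lo, hi] are dropped and counted.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if np.any(sds <= 0):
        raise ValueError("sds must be positive")
    k = len(means)
    rng = np.random.default_rng(seed)
    if n_per_component is not None:
        alloc = np.full(k, n_per_component)
    else:
        if n_total is None or weights is None:
            raise ValueError("give n_per_component, or n_total with weights")
        w = np.asarray(weights, float)
        if w.min() < 0 or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")
        alloc = rng.multinomial(n_total, w)
    values, labels = [], []
    n_trunc = 0
    for j in range(k):
        draws = rng.normal(means[j], sds[j], size=alloc[j])
        keep = (draws >= lo) & (draws <= hi)
        n_trunc += int((~keep).sum())
        values.append(draws[keep])
        labels.append(np.full(keep.sum(), j))
    return KsSample(
        values=np.concatenate(values), labels=np.concatenate(labels),
        n_truncated=n_trunc, means=tuple(means), sds=tuple(sds),
    )


# ---------------------------------------------------------------------------
# Codon pairs at controlled synonymous divergence


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            return codon


def _synonymous_moves(seq: list[str]) -> list[tuple[int, str]]:
    """(codon index, replacement codon) for every synonymous 1-nt change."""
    moves = []
    for idx, codon in enumerate(seq):
        aa = _AA[codon]
        for i in range(3):
            for base in _BASES:
                if base == codon[i]:
                    continue
                alt = codon[:i] + base + codon[i + 1:]
                if alt not in _STOPS and _AA[alt] == aa:
                    moves.append((idx, alt))
    return moves


def _nonsynonymous_moves(seq: list[str], banned: set[int]) -> list[tuple[int, str]]:
    moves = []
    for idx, codon in enumerate(seq):
        if idx in banned:
            continue
        aa = _AA[codon]
        for i in range(3):
            for base in _BASES:
                if base == codon[i]:
                    continue
                alt = codon[:i] + base + codon[i + 1:]
                if alt not in _STOPS and _AA[alt] != aa:
                    moves.append((idx, alt))
    return moves


@dataclass(frozen=True)
class CodonPairRecord:
    pair: CodonAlignmentPair
    true_ks: float  # realised synonymous events per ancestral synonymous site
    true_ka: float
    saturated: bool


def sim_codon_pairs(
    n: int,
    target_ks: float,
    length: int = 300,
    seed: Optional[int] = None,
    target_ka: float = 0.0,
) -> list[CodonPairRecord]:
    """Codon pairs diverged by counted synonymous substitution events.

    Each pair descends from a random ancestral sequence of ``length`` codons;
    Poisson(target_ks x synonymous sites) synonymous single-nucleotide events
    are applied, split between the two branches, multi-hits allowed.  The
    truth is the realised events-per-ancestral-synonymous-site divergence.
    Optional nonsynonymous events hit at most one per codon, keeping the two
    channels separable.  Pairs beyond the correction range (3/4 of sites
    different) are flagged saturated.
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("divergence targets must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        anc = [_random_codon(rng) for _ in range(length)]
        s_sites = sum(_site_counts(c)[0] for c in anc)
        n_sites = 3 * length - s_sites
        n_syn = int(rng.poisson(target_ks * s_sites)) if target_ks > 0 else 0
        n_non = int(rng.poisson(target_ka * n_sites)) if target_ka > 0 else 0
        seqs = [list(anc), list(anc)]
        for _ in range(n_syn):
            branch = int(rng.integers(2))
            moves = _synonymous_moves(seqs[branch])
            idx, alt = moves[int(rng.integers(len(moves)))]
            seqs[branch][idx] = alt
        hit_codons: set[int] = set()
        applied_non = 0
        for _ in range(n_non):
            branch = int(rng.integers(2))
            moves = _nonsynonymous_moves(seqs[branch], hit_codons)
            if not moves:
                break
            idx, alt = moves[int(rng.integers(len(moves)))]
            seqs[branch][idx] = alt
            hit_codons.add(idx)
            applied_non += 1
        pair = CodonAlignmentPair("".join(seqs[0]), "".join(seqs[1]))
        true_ks = n_syn / s_sites if s_sites else 0.0
        saturated = true_ks > 0.75 * 3.0  # beyond any correctable divergence
        out.append(CodonPairRecord(
            pair=pair, true_ks=true_ks,
            true_ka=applied_non / n_sites if n_sites else 0.0,
            saturated=saturated,
        ))
    return out


# ---------------------------------------------------------------------------
# Genome gene-order evolution


@dataclass(frozen=True)
class LineageEvents:
    """Events on one species-tree branch, applied in the order
    WGD -> inversions -> tandem duplications."""

    wgd_retention: Optional[float] = None  # None = no WGD on this branch
    inversions: int = 0
    # inversion spans stay > 2 x the chainer's default max_gap, so a block
    # can never bridge an inverted interval through its centre anchor
    inversion_span: tuple[int, int] = (60, 100)  # genes, inclusive bounds
    tandem_rate: float = 0.0  # per gene

    def __post_init__(self):
        if self.wgd_retention is not None and not 0.0 <= self.wgd_retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")
        if not 0.0 <= self.tandem_rate <= 1.0:
            raise ValueError("tandem rate must be in [0, 1]")


@dataclass(frozen=True)
class EvolutionScenario:
    species_tree: SpeciesTree
    ancestral_genes: int = 300
    ancestral_chromosomes: int = 2
    events: Mapping[str, LineageEvents] = field(default_factory=dict)
    # events are keyed by the branch's child clade: "root" for the stem, a
    # taxon name for a terminal branch, or comma-joined sorted taxa
    score_mean: float = 100.0
    score_sd: float = 5.0
    spurious_rate: float = 0.02  # spurious homology pairs per emitted gene
    seed: Optional[int] = None


def two_genome_scenario(
    shared_wgd: Optional[float] = None,
    lineage_wgd: Optional[str] = None,
    lineage_retention: float = 0.8,
    inversions: int = 2,
    tandem_rate: float = 0.02,
    ancestral_genes: int = 300,
    seed: Optional[int] = None,
) -> EvolutionScenario:
    """Convenience scenario on a 2-taxon tree (genomes A and B).

    ``shared_wgd`` is a retention probability for a WGD on the stem (before
    the A/B split); ``lineage_wgd`` names the genome with a private WGD.
    """
    tree = parse_newick("(A:1,B:1);", kind="species")
    events: dict[str, LineageEvents] = {}
    if shared_wgd is not None:
        events["root"] = LineageEvents(wgd_retention=shared_wgd)
    for taxon in ("A", "B"):
        retention = lineage_retention if lineage_wgd == taxon else None
        events[taxon] = LineageEvents(
            wgd_retention=retention, inversions=inversions, tandem_rate=tandem_rate)
    return EvolutionScenario(
        species_tree=tree, ancestral_genes=ancestral_genes, events=events, seed=seed)


class _SimGene:
    __slots__ = ("family", "copy", "seg", "tandem")

    def __init__(self, family: int, copy: str, seg: int, tandem: bool = False):
        self.family = family
        self.copy = copy
        self.seg = seg
        self.tandem = tandem

    def clone(self) -> "_SimGene":
        return _SimGene(self.family, self.copy, self.seg, self.tandem)


@dataclass(frozen=True)
class GenomeSimResult:
    loci: dict[str, GeneLocus]  # gene id -> locus, per emitted genome
    pairs: list[HomologyPair]
    truth: pd.DataFrame  # gene_a, gene_b, relationship, seg_a, seg_b
    planted_blocks: list[frozenset]  # per genome pair: sets of (gene_a, gene_b)


def sim_genome_evolution(scenario: EvolutionScenario) -> GenomeSimResult:
    """Evolve gene orders down the species tree and emit labeled homology.

    The ancestral genome descends through speciation; on each branch a WGD
    (duplicate every chromosome, then fractionation deletes one member of
    each duplicate pair with probability 1-retention, from a random side),
    inversions (reversing random intervals; the interval and its right flank
    get fresh collinearity-segment ids) and tandem duplications (adjacent
    copies) are applied.  Homology pairs connect genes of the same family
    within and between genomes, with noisy scores plus spurious pairs.

    The truth table labels every pair (orthologue / paralogue / tandem /
    spurious); planted blocks are groups of >= 5 true pairs sharing a
    (segment_a, segment_b) combination — precisely the collinear runs a
    chainer should recover.
    """
    rng = np.random.default_rng(scenario.seed)
    seg_counter = itertools.count()
    wgd_counter = itertools.count()
    fam_ids = itertools.count()
    inverted_families: set[int] = set()

    per_chrom = scenario.ancestral_genes // scenario.ancestral_chromosomes
    genome0 = []
    for _ in range(scenario.ancestral_chromosomes):
        seg = next(seg_counter)
        genome0.append([_SimGene(next(fam_ids), "", seg)
                        for _ in range(per_chrom)])

    def events_for(node: Node, tree: SpeciesTree) -> LineageEvents:
        if node is tree.root:
            key = "root"
        else:
            labels = sorted(node.leaf_labels())
            key = labels[0] if len(labels) == 1 else ",".join(labels)
        return scenario.events.get(key, LineageEvents())

    def apply_events(genome: list[list[_SimGene]], ev: LineageEvents) -> list[list[_SimGene]]:
        if ev.wgd_retention is not None:
            wgd_id = next(wgd_counter)
            new_genome = []
            for chrom in genome:
                orig, dup = [], []
                seg_map: dict[int, int] = {}
                for g in chrom:
                    g0, g1 = g.clone(), g.clone()
                    g0.copy = f"{g.copy}W{wgd_id:02d}.0;"
                    g1.copy = f"{g.copy}W{wgd_id:02d}.1;"
                    if g.seg not in seg_map:
                        seg_map[g.seg] = next(seg_counter)
                    g1.seg = seg_map[g.seg]
                    if rng.random() < ev.wgd_retention:
                        orig.append(g0)
                        dup.append(g1)
                    elif rng.random() < 0.5:
                        orig.append(g0)
                    else:
                        dup.append(g1)
                new_genome.append(orig)
                if dup:
                    new_genome.append(dup)
            genome = new_genome
        for _ in range(ev.inversions):
            # keep inversion territories disjoint across the whole history
            # (in ancestral-family space), so that independent inversions in
            # sister lineages can never partially cancel and the planted
            # segment labels stay faithful to realised collinearity
            for _attempt in range(30):
                sizes = np.array([len(c) for c in genome], dtype=float)
                ci = int(rng.choice(len(genome), p=sizes / sizes.sum()))
                chrom = genome[ci]
                span = int(rng.integers(ev.inversion_span[0], ev.inversion_span[1] + 1))
                span = min(span, len(chrom) - 1)
                if span < 2:
                    continue
                start = int(rng.integers(0, len(chrom) - span + 1))
                families = {g.family for g in chrom[start:start + span]}
                if families & inverted_families:
                    continue
                inverted_families.update(families)
                seg_inv = next(seg_counter)
                seg_right = next(seg_counter)
                for g in chrom[start:start + span]:
                    g.seg = seg_inv
                for g in chrom[start + span:]:
                    g.seg = seg_right
                genome[ci] = (chrom[:start] + chrom[start:start + span][::-1]
                              + chrom[start + span:])
                break
        if ev.tandem_rate > 0:
            for ci, chrom in enumerate(genome):
                new_chrom = []
                for g in chrom:
                    new_chrom.append(g)
                    if rng.random() < ev.tandem_rate:
                        t = g.clone()
                        t.copy = g.copy + "T"
                        t.tandem = True
                        new_chrom.append(t)
                genome[ci] = new_chrom
        return genome

    tree = scenario.species_tree
    genomes_at: dict[Node, list[list[_SimGene]]] = {}
    root_genome = apply_events([c[:] for c in genome0], events_for(tree.root, tree))
    genomes_at[tree.root] = root_genome
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_genome = genomes_at[node.parent]
        inherited = [[g.clone() for g in chrom] for chrom in parent_genome]
        genomes_at[node] = apply_events(inherited, events_for(node, tree))

    # emit leaf genomes
    loci: dict[str, GeneLocus] = {}
    genes_by_id: dict[str, _SimGene] = {}
    by_family: dict[int, list[str]] = {}
    for leaf in tree.leaves():
        serial = itertools.count(1)
        for ci, chrom in enumerate(genomes_at[leaf]):
            chrom_name = f"{leaf.label}_chr{ci}"
            for rank, g in enumerate(chrom):
                gid = f"{leaf.label}_g{next(serial):05d}"
                loci[gid] = GeneLocus(leaf.label, chrom_name, gid, rank)
                genes_by_id[gid] = g
                by_family.setdefault(g.family, []).append(gid)

    # homology pairs: all same-family pairs (within and between genomes)
    pairs = []
    rows = []
    for fam, gids in sorted(by_family.items()):
        for ga, gb in itertools.combinations(sorted(gids), 2):
            a, b = genes_by_id[ga], genes_by_id[gb]
            la, lb = loci[ga], loci[gb]
            score = max(10.0, float(rng.normal(scenario.score_mean, scenario.score_sd)))
            pairs.append(HomologyPair(la, lb, score))
            rows.append({
                "gene_a": ga, "gene_b": gb,
                "relationship": _true_relationship(a, b, la, lb),
                "chrom_a": la.chrom, "chrom_b": lb.chrom,
                "seg_a": a.seg, "seg_b": b.seg,
            })
    # spurious cross-family pairs
    all_ids = sorted(loci)
    n_spurious = int(round(scenario.spurious_rate * len(all_ids)))
    made = 0
    while made < n_spurious:
        ga, gb = rng.choice(all_ids, size=2, replace=False)
        if genes_by_id[ga].family == genes_by_id[gb].family:
            continue
        score = max(10.0, float(rng.normal(scenario.score_mean * 0.6, scenario.score_sd)))
        pairs.append(HomologyPair(loci[ga], loci[gb], score))
        rows.append({"gene_a": ga, "gene_b": gb, "relationship": "spurious",
                     "chrom_a": loci[ga].chrom, "chrom_b": loci[gb].chrom,
                     "seg_a": genes_by_id[ga].seg, "seg_b": genes_by_id[gb].seg})
        made += 1
    truth = pd.DataFrame(rows)

    # planted blocks: true (non-tandem, non-spurious) pairs grouped by the
    # chromosome pair and collinearity-segment combination
    planted: dict[tuple, set] = {}
    for row in rows:
        if row["relationship"] in ("spurious", "tandem"):
            continue
        key = (row["chrom_a"], row["chrom_b"], row["seg_a"], row["seg_b"])
        planted.setdefault(key, set()).add((row["gene_a"], row["gene_b"]))
    planted_blocks = [frozenset(v) for v in planted.values() if len(v) >= 5]

    return GenomeSimResult(loci=loci, pairs=pairs, truth=truth,
                           planted_blocks=planted_blocks)


def _true_relationship(a: _SimGene, b: _SimGene, la: GeneLocus, lb: GeneLocus) -> str:
    # the copy path records the side taken at every WGD along the gene's
    # ancestry; tandem marks ("T") are orthogonal and stripped for comparison
    ca = a.copy.replace("T", "")
    cb = b.copy.replace("T", "")
    if la.genome == lb.genome:
        if ca == cb:
            return "tandem" if (a.tandem or b.tandem) else "paralogue"
        return "paralogue"
    # between genomes: differing choices at a WGD shared by both paths make
    # the pair paralogous; a lineage-specific WGD only extends one path
    shorter, longer = sorted((ca, cb), key=len)
    return "orthologue" if longer.startswith(shorter) else "paralogue"


def evaluate_blocks(
    recovered: Sequence[SyntenyBlock],
    planted: Sequence[frozenset],
    min_overlap: float = 0.5,
) -> tuple[float, float]:
    """(precision, recall) of recovered blocks against planted blocks.

    A recovered block is a true positive when at least ``min_overlap`` of its
    anchors fall inside one single planted block; a planted block is
    recovered when one single recovered block contains at least
    ``min_overlap`` of its pairs.
    """
    rec_sets = [frozenset((min(p.a.gene_id, p.b.gene_id), max(p.a.gene_id, p.b.gene_id))
                          for p in b.anchors) for b in recovered]
    planted_norm = [frozenset((min(a, b), max(a, b)) for a, b in blk) for blk in planted]
    if not rec_sets:
        return (1.0 if not planted_norm else 0.0, 0.0 if planted_norm else 1.0)
    tp_rec = sum(
        1 for r in rec_sets
        if any(len(r & p) >= min_overlap * len(r) for p in planted_norm)
    )
    precision = tp_rec / len(rec_sets)
    if not planted_norm:
        return precision, 1.0
    tp_pla = sum(
        1 for p in planted_norm
        if any(len(r & p) >= min_overlap * len(p) for r in rec_sets)
    )
    recall = tp_pla / len(planted_norm)
    return precision, recall
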