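"""Collinear synteny-block detection and syntenic-depth classification.

After a whole-genome duplication, every chromosomal region initially exists
twice, so a genome that duplicated after its split from a sister lineage
shows a 2:1 syntenic relationship against that sister (two of its regions
align to one sister region), while a duplication predating the split leaves
2:2 patterns.  Working in gene-rank coordinates (the ordinal position of
each gene along its chromosome), this module

* separates tandem duplicates (same chromosome, within a small gene-rank
  distance) from candidate collinearity anchors,
* chains anchors into syntenic blocks by dynamic programming on the
  (rank_a, rank_b) dot plot, in both collinear and inverted orientation,
* merges compatible same-chromosome-pair blocks, classifies region depth
  ratios (1:1 / 2:1 / 2:2 / other), and
* emits syntelog pairs (syntenic paralogues within a genome, syntenic
  orthologues between genomes) for downstream Ks analysis.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "GeneLocus",
    "HomologyPair",
    "SyntenyBlock",
    "DepthSummary",
    "ChainParams",
    "classify_tandem",
    "chain_blocks",
    "merge_blocks",
    "depth_classify",
    "syntelog_pairs",
    "SyntelogPair",
    "read_gene_orders",
    "read_homology_pairs",
    "write_blocks",
]


@dataclass(frozen=True, order=True)
class GeneLocus:
    genome: str
    chrom: str
    gene_id: str
    index: int  # 0-based ordinal along the chromosome
    strand: str = "+"


@dataclass(frozen=True)
class HomologyPair:
    """An unordered homologous gene pair; canonical order is enforced."""

    a: GeneLocus
    b: GeneLocus
    score: float = 1.0

    def __post_init__(self):
        if self.a.gene_id == self.b.gene_id and self.a.genome == self.b.genome:
            raise ValueError("self-pair")
        if self.score <= 0:
            raise ValueError("score must be positive")
        if (self.b.genome, self.b.chrom, self.b.index) < (self.a.genome, self.a.chrom, self.a.index):
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)


@dataclass(frozen=True)
class SyntenyBlock:
    """A chain of anchors, strictly monotone on both chromosomes."""

    anchors: tuple[HomologyPair, ...]
    orientation: str  # "collinear" | "inverted"
    score: float

    def __post_init__(self):
        ia = [p.a.index for p in self.anchors]
        ib = [p.b.index for p in self.anchors]
        if any(y <= x for x, y in zip(ia, ia[1:])):
            raise ValueError("anchors not strictly increasing on chromosome a")
        step_ok = (lambda x, y: y > x) if self.orientation == "collinear" else (lambda x, y: y < x)
        if any(not step_ok(x, y) for x, y in zip(ib, ib[1:])):
            raise ValueError("anchors not strictly monotone on chromosome b")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def chrom_a(self) -> tuple[str, str]:
        return self.anchors[0].a.genome, self.anchors[0].a.chrom

    @property
    def chrom_b(self) -> tuple[str, str]:
        return self.anchors[0].b.genome, self.anchors[0].b.chrom

    @property
    def span_a(self) -> tuple[int, int]:
        ia = [p.a.index for p in self.anchors]
        return min(ia), max(ia)

    @property
    def span_b(self) -> tuple[int, int]:
        ib = [p.b.index for p in self.anchors]
        return min(ib), max(ib)


class SyntelogPair(NamedTuple):
    gene_a: str
    gene_b: str
    relationship: str  # syntenic_paralogue | syntenic_orthologue


@dataclass(frozen=True)
class ChainParams:
    min_pairs: int = 5
    max_gap: int = 25  # gene ranks, on either chromosome
    gap_penalty: float = 5.0  # per gene rank skipped


@dataclass(frozen=True)
class DepthSummary:
    """Region-level depth ratios for one genome pair."""

    classes: dict  # class string -> count of correspondence groups
    groups: tuple  # per group: (n_regions_a, n_regions_b, block indices)

    @property
    def modal_class(self) -> Optional[str]:
        if not self.classes:
            return None
        return max(sorted(self.classes), key=lambda c: self.classes[c])


# ---------------------------------------------------------------------------
# Tandem classification


def classify_tandem(
    pairs: Iterable[HomologyPair], max_distance: int = 10
) -> dict[str, list[HomologyPair]]:
    """Split pairs into tandem duplicates and candidate anchors.

    A pair is tandem iff both loci lie in the same genome AND chromosome and
    their gene-rank distance is at most ``max_distance`` (boundary included:
    "within ten genes apart").  Tandem pairs never enter block chaining.
    """
    out = {"tandem": [], "candidate_anchor": []}
    for p in pairs:
        same_region = p.a.genome == p.b.genome and p.a.chrom == p.b.chrom
        if same_region and abs(p.a.index - p.b.index) <= max_distance:
            out["tandem"].append(p)
        else:
            out["candidate_anchor"].append(p)
    return out


# ---------------------------------------------------------------------------
# Chaining


def _best_chain(
    anchors: list[HomologyPair], used: list[bool], inverted: bool,
    params: ChainParams,
) -> Optional[tuple[float, list[int]]]:
    """Highest-scoring single chain over unused anchors for one orientation.

    Dynamic programming over anchors sorted by (rank_a, rank_b); the score of
    a chain is the sum of anchor scores minus ``gap_penalty`` per gene rank
    skipped on either chromosome, with gaps capped at ``max_gap``.  Ties
    prefer the chain ending (and predecessors) with lower rank_a, then lower
    rank_b.
    """
    sign = -1 if inverted else 1
    pts = sorted(
        (i for i in range(len(anchors)) if not used[i]),
        key=lambda i: (anchors[i].a.index, sign * anchors[i].b.index))
    if not pts:
        return None
    ia = [anchors[i].a.index for i in pts]
    ib = [sign * anchors[i].b.index for i in pts]
    sc = [anchors[i].score for i in pts]
    n = len(pts)
    best_score = [0.0] * n
    back: list[Optional[int]] = [None] * n
    for i in range(n):
        best_score[i] = sc[i]
        for j in range(i):
            da = ia[i] - ia[j]
            db = ib[i] - ib[j]
            if da <= 0 or db <= 0:
                continue
            if da - 1 > params.max_gap or db - 1 > params.max_gap:
                continue
            cand = best_score[j] + sc[i] - params.gap_penalty * ((da - 1) + (db - 1))
            if cand > best_score[i] + 1e-12:
                best_score[i] = cand
                back[i] = j
    end = max(range(n), key=lambda i: (best_score[i], -ia[i], -ib[i]))
    chain = []
    i: Optional[int] = end
    while i is not None:
        chain.append(pts[i])
        i = back[i]
    chain.reverse()
    return best_score[end], chain


def chain_blocks(
    pairs: Sequence[HomologyPair],
    params: ChainParams = ChainParams(),
) -> list[SyntenyBlock]:
    """Extract syntenic blocks from candidate anchors.

    Anchors are grouped by chromosome pair.  Chains are extracted greedily in
    descending score: each round the best remaining chain in either
    orientation (collinear or inverted) claims its anchors, and chains
    shorter than ``min_pairs`` are discarded.  Deterministic for a fixed
    input set.
    """
    groups: dict[tuple, list[HomologyPair]] = defaultdict(list)
    for p in pairs:
        groups[(p.a.genome, p.a.chrom, p.b.genome, p.b.chrom)].append(p)
    blocks = []
    for key in sorted(groups):
        anchors = sorted(groups[key], key=lambda p: (p.a.index, p.b.index))
        used = [False] * len(anchors)
        while True:
            best = None
            for inverted in (False, True):
                cand = _best_chain(anchors, used, inverted, params)
                if cand is not None and (best is None or cand[0] > best[0][0] + 1e-12):
                    best = (cand, inverted)
            if best is None:
                break
            (score, idxs), inverted = best
            for i in idxs:
                used[i] = True
            if len(idxs) < params.min_pairs:
                continue  # discarded, but its anchors are consumed
            chain = [anchors[i] for i in idxs]
            if inverted:
                chain.sort(key=lambda p: (p.a.index, -p.b.index))
            blocks.append(SyntenyBlock(
                anchors=tuple(chain),
                orientation="inverted" if inverted else "collinear",
                score=score,
            ))
    return blocks


def merge_blocks(blocks: Sequence[SyntenyBlock], max_gap: int = 25) -> list[SyntenyBlock]:
    """Merge same-chromosome-pair, same-orientation blocks whose gap is at
    most ``max_gap`` on both chromosomes and whose union stays monotone.

    A simplified quota-style merge: blocks are scanned in rank_a order and
    absorbed into the running block when compatible.
    """
    by_pair: dict[tuple, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        by_pair[(b.chrom_a, b.chrom_b, b.orientation)].append(b)
    out = []
    for key in sorted(by_pair):
        group = sorted(by_pair[key], key=lambda b: b.span_a)
        current = group[0]
        for nxt in group[1:]:
            merged_anchors = tuple(sorted(
                current.anchors + nxt.anchors,
                key=lambda p: (p.a.index,
                               p.b.index if current.orientation == "collinear" else -p.b.index),
            ))
            gap_a = nxt.span_a[0] - current.span_a[1] - 1
            try:
                candidate = SyntenyBlock(
                    anchors=merged_anchors,
                    orientation=current.orientation,
                    score=current.score + nxt.score,
                )
            except ValueError:
                candidate = None
            if candidate is not None and 0 <= gap_a <= max_gap:
                current = candidate
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


# ---------------------------------------------------------------------------
# Depth classification


def _overlaps(lo1, hi1, lo2, hi2) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def depth_classify(blocks: Sequence[SyntenyBlock], merge_gap: int = 25) -> DepthSummary:
    """Classify correspondence groups of blocks by their region depth ratio.

    Blocks are connected when their regions overlap — within ``merge_gap``
    gene ranks — on either genome (same chromosome); within a connected
    component, block regions on each side closer than ``merge_gap`` are
    merged into regions (rearrangements fragment blocks without changing
    copy depth), and the component is classified by the (regions on side a :
    regions on side b) pattern.
    """
    n = len(blocks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = blocks[i], blocks[j]
            if bi.chrom_a == bj.chrom_a and _overlaps(
                    bi.span_a[0], bi.span_a[1] + merge_gap, bj.span_a[0], bj.span_a[1] + merge_gap):
                union(i, j)
            if bi.chrom_b == bj.chrom_b and _overlaps(
                    bi.span_b[0], bi.span_b[1] + merge_gap, bj.span_b[0], bj.span_b[1] + merge_gap):
                union(i, j)

    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(i)

    def count_regions(idxs, side) -> int:
        intervals: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
        for i in idxs:
            b = blocks[i]
            chrom = b.chrom_a if side == "a" else b.chrom_b
            span = b.span_a if side == "a" else b.span_b
            intervals[chrom].append(span)
        total = 0
        for chrom, spans in intervals.items():
            spans.sort()
            merged_hi = None
            for lo, hi in spans:
                if merged_hi is None or lo > merged_hi + merge_gap:
                    total += 1
                    merged_hi = hi
                else:
                    merged_hi = max(merged_hi, hi)
        return total

    classes: dict[str, int] = defaultdict(int)
    groups = []
    for idxs in comps.values():
        da = count_regions(idxs, "a")
        db = count_regions(idxs, "b")
        hi, lo = max(da, db), min(da, db)
        if (hi, lo) in ((1, 1), (2, 1), (2, 2)):
            label = f"{da}:{db}" if (da, db) in ((1, 1), (2, 1), (2, 2)) else f"{hi}:{lo}"
        else:
            label = "other"
        classes[label] += 1
        groups.append((da, db, tuple(sorted(idxs))))
    return DepthSummary(classes=dict(classes), groups=tuple(groups))


# ---------------------------------------------------------------------------
# Syntelogs


def syntelog_pairs(blocks: Sequence[SyntenyBlock]) -> list[SyntelogPair]:
    """Anchor gene pairs labeled by block type, ready for Ks analysis."""
    out = []
    for b in blocks:
        within = b.chrom_a[0] == b.chrom_b[0]
        label = "syntenic_paralogue" if within else "syntenic_orthologue"
        for p in b.anchors:
            out.append(SyntelogPair(p.a.gene_id, p.b.gene_id, label))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_gene_orders(path, fmt: str = "tsv") -> dict[str, GeneLocus]:
    """Gene loci keyed by gene id.

    TSV columns: genome, chrom, gene_id, start[, strand]; base-pair starts
    are converted to 0-based consecutive gene ranks per chromosome.  GFF3
    input takes gene features, with the genome name taken from the filename
    stem.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        need = {"genome", "chrom", "gene_id", "start"}
        if not need <= set(df.columns):
            raise ValueError(f"gene-order TSV must have columns {sorted(need)}")
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique")
        from pathlib import Path

        genome = Path(path).stem
        rows = [
            {"genome": genome, "chrom": f.seqid, "gene_id": f.id,
             "start": f.start, "strand": f.strand or "+"}
            for f in db.features_of_type("gene")
        ]
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    out: dict[str, GeneLocus] = {}
    for (genome, chrom), sub in df.groupby(["genome", "chrom"], sort=True):
        sub = sub.sort_values("start", kind="mergesort").reset_index(drop=True)
        for rank, row in sub.iterrows():
            gid = str(row["gene_id"])
            if gid in out:
                raise ValueError(f"duplicate gene id {gid}")
            out[gid] = GeneLocus(str(genome), str(chrom), gid, int(rank), str(row["strand"]))
    return out


def read_homology_pairs(path, loci: dict[str, GeneLocus]) -> list[HomologyPair]:
    """3-column TSV (gene_a, gene_b, score) resolved against gene loci."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        ga, gb = str(row["gene_a"]), str(row["gene_b"])
        if ga not in loci or gb not in loci:
            raise ValueError(f"unknown gene in homology pair: {ga}, {gb}")
        out.append(HomologyPair(loci[ga], loci[gb], float(row["score"])))
    return out


def write_blocks(blocks: Sequence[SyntenyBlock], path) -> None:
    rows = []
    for i, b in enumerate(blocks):
        rows.append({
            "block_id": i,
            "genome_a": b.chrom_a[0], "chrom_a": b.chrom_a[1],
            "genome_b": b.chrom_b[0], "chrom_b": b.chrom_b[1],
            "orientation": b.orientation,
            "n_anchors": b.n_anchors,
            "score": b.score,
            "anchors": ";".join(f"{p.a.gene_id}|{p.b.gene_id}" for p in b.anchors),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
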