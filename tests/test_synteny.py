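"""Tandem classification, block chaining, depth ratios, syntelog emission."""

import itertools

import numpy as np
import pytest

from fernwgd.synteny import (
    ChainParams, GeneLocus, HomologyPair, SyntenyBlock, chain_blocks,
    classify_tandem, depth_classify, merge_blocks, read_gene_orders,
    read_homology_pairs, syntelog_pairs, write_blocks,
)


def L(genome, chrom, gid, idx):
    return GeneLocus(genome, chrom, gid, idx)


def diagonal_pairs(n, chrom_a=("A", "a1"), chrom_b=("B", "b1"), offset=0,
                   score=100.0, invert=False, b_start=None):
    out = []
    for i in range(n):
        ib = (b_start - i) if invert else (i + offset if b_start is None else b_start + i)
        out.append(HomologyPair(
            L(chrom_a[0], chrom_a[1], f"{chrom_a[1]}_g{i}", i),
            L(chrom_b[0], chrom_b[1], f"{chrom_b[1]}_g{ib}", ib),
            score))
    return out


class TestClassifyTandem:
    def test_distance_ten_on_same_chromosome_is_tandem(self):
        p = HomologyPair(L("A", "c1", "g5", 5), L("A", "c1", "g15", 15))
        parts = classify_tandem([p])
        assert parts["tandem"] == [p]  # boundary inclusive

    def test_distance_eleven_is_an_anchor(self):
        p = HomologyPair(L("A", "c1", "g5", 5), L("A", "c1", "g16", 16))
        parts = classify_tandem([p])
        assert parts["candidate_anchor"] == [p]

    def test_different_chromosomes_never_tandem(self):
        p = HomologyPair(L("A", "c1", "g1", 1), L("A", "c2", "g2", 1))
        parts = classify_tandem([p])
        assert parts["candidate_anchor"] == [p]

    def test_hand_placed_fixture_partitions_exactly(self):
        """20 hand-placed pairs vs manual enumeration of the tandem rule."""
        pairs, expected = [], []
        for i, (chrom_b, d) in enumerate(itertools.product(
                ["c1", "c2"], [0, 1, 5, 9, 10, 11, 15, 20, 30, 50])):
            a = L("A", "c1", f"p{i}a", 100 + i * 200)
            b = L("A", chrom_b, f"p{i}b", 100 + i * 200 + d + (1 if d == 0 else 0))
            pairs.append(HomologyPair(a, b))
            dist = abs(a.index - b.index)
            expected.append("tandem" if chrom_b == "c1" and dist <= 10
                            else "candidate_anchor")
        parts = classify_tandem(pairs)
        for p, side in zip(pairs, expected):
            assert p in parts[side]
        assert len(parts["tandem"]) + len(parts["candidate_anchor"]) == 20

    def test_commutes_with_gene_relabeling(self):
        pairs = [HomologyPair(L("A", "c1", "x1", 3), L("A", "c1", "x2", 8)),
                 HomologyPair(L("A", "c1", "x3", 3), L("B", "c9", "x4", 8))]
        renamed = [HomologyPair(L("A", "c1", "y1", 3), L("A", "c1", "y2", 8)),
                   HomologyPair(L("A", "c1", "y3", 3), L("B", "c9", "y4", 8))]
        a = classify_tandem(pairs)
        b = classify_tandem(renamed)
        assert [len(a["tandem"]), len(a["candidate_anchor"])] == \
               [len(b["tandem"]), len(b["candidate_anchor"])]


def _brute_force_best_chain(anchors, used, inverted, params):
    """Exhaustive search over all valid chains (monotone, gap-capped)."""
    sign = -1 if inverted else 1
    avail = [i for i in range(len(anchors)) if not used[i]]
    best = (0.0, None)

    def extend(chain, score):
        nonlocal best
        if chain and score > best[0] + 1e-12:
            best = (score, list(chain))
        last = chain[-1] if chain else None
        for i in avail:
            if i in chain:
                continue
            if last is not None:
                da = anchors[i].a.index - anchors[last].a.index
                db = sign * anchors[i].b.index - sign * anchors[last].b.index
                if da <= 0 or db <= 0:
                    continue
                if da - 1 > params.max_gap or db - 1 > params.max_gap:
                    continue
                gain = anchors[i].score - params.gap_penalty * ((da - 1) + (db - 1))
            else:
                gain = anchors[i].score
            chain.append(i)
            extend(chain, score + gain)
            chain.pop()

    extend([], 0.0)
    return best


def _brute_force_blocks(anchors, params):
    """Greedy extraction with the brute-force single-chain search."""
    used = [False] * len(anchors)
    blocks = []
    while True:
        best = (0.0, None, None)
        for inverted in (False, True):
            score, chain = _brute_force_best_chain(anchors, used, inverted, params)
            if chain is not None and score > best[0] + 1e-12:
                best = (score, chain, inverted)
        if best[1] is None:
            break
        for i in best[1]:
            used[i] = True
        if len(best[1]) >= params.min_pairs:
            blocks.append(best[0])
    return sorted(blocks)


class TestChainBlocks:
    def test_perfect_diagonal_yields_one_block(self):
        blocks = chain_blocks(diagonal_pairs(10))
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 10
        assert blocks[0].orientation == "collinear"

    def test_no_anchors_no_blocks(self):
        assert chain_blocks([]) == []

    def test_antidiagonal_found_as_inverted(self):
        blocks = chain_blocks(diagonal_pairs(8, invert=True, b_start=20))
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_blocks_satisfy_monotonicity_invariant(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            pairs = [HomologyPair(
                L("A", "a1", f"a{i}", i),
                L("B", "b1", f"b{i}", int(rng.integers(0, 40))),
                float(rng.uniform(50, 150)))
                for i in rng.choice(100, size=n, replace=False)]
            for b in chain_blocks(pairs):
                ia = [p.a.index for p in b.anchors]
                ib = [p.b.index for p in b.anchors]
                assert ia == sorted(ia) and len(set(ia)) == len(ia)
                assert ib == sorted(ib, reverse=b.orientation == "inverted")

    def test_matches_exhaustive_chaining_on_tiny_instances(self, rng):
        """Block-set scores equal a brute-force search over all valid
        chains, on instances of up to 12 anchors."""
        params = ChainParams(min_pairs=2, max_gap=5, gap_penalty=2.0)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            seen = set()
            pairs = []
            while len(pairs) < n:
                ia, ib = int(rng.integers(0, 12)), int(rng.integers(0, 12))
                if (ia, ib) in seen:
                    continue
                seen.add((ia, ib))
                # continuous scores: chain-score ties have measure zero, so
                # greedy extraction order is uniquely determined
                pairs.append(HomologyPair(
                    L("A", "a1", f"a{trial}_{ia}_{ib}", ia),
                    L("B", "b1", f"b{trial}_{ia}_{ib}", ib),
                    float(rng.uniform(5, 20))))
            got = sorted(b.score for b in chain_blocks(pairs, params))
            want = _brute_force_blocks(pairs, params)
            assert np.allclose(got, want)

    def test_commutes_with_gene_relabeling(self):
        pairs = diagonal_pairs(7)
        relabeled = [HomologyPair(
            L(p.a.genome, p.a.chrom, "z" + p.a.gene_id, p.a.index),
            L(p.b.genome, p.b.chrom, "z" + p.b.gene_id, p.b.index),
            p.score) for p in pairs]
        a = chain_blocks(pairs)
        b = chain_blocks(relabeled)
        assert [(x.span_a, x.span_b, x.score) for x in a] == \
               [(x.span_a, x.span_b, x.score) for x in b]


class TestMergeBlocks:
    def test_compatible_neighbours_merge(self):
        left = chain_blocks(diagonal_pairs(6))[0]
        right = chain_blocks(diagonal_pairs(
            6, offset=0, b_start=None) )[0]
        # build a shifted copy manually: indices 16..21
        shifted = SyntenyBlock(
            anchors=tuple(HomologyPair(
                L("A", "a1", f"r{i}", 16 + i), L("B", "b1", f"s{i}", 16 + i))
                for i in range(6)),
            orientation="collinear", score=60.0)
        merged = merge_blocks([left, shifted], max_gap=25)
        assert len(merged) == 1
        assert merged[0].n_anchors == 12

    def test_distant_blocks_stay_apart(self):
        left = chain_blocks(diagonal_pairs(6))[0]
        far = SyntenyBlock(
            anchors=tuple(HomologyPair(
                L("A", "a1", f"r{i}", 60 + i), L("B", "b1", f"s{i}", 60 + i))
                for i in range(6)),
            orientation="collinear", score=60.0)
        assert len(merge_blocks([left, far], max_gap=25)) == 2


class TestDepthClassify:
    def test_single_block_is_one_to_one(self):
        blocks = chain_blocks(diagonal_pairs(10))
        d = depth_classify(blocks)
        assert d.classes == {"1:1": 1}
        assert d.modal_class == "1:1"

    def test_two_a_regions_on_one_b_region_is_two_to_one(self):
        b1 = chain_blocks(diagonal_pairs(10, chrom_a=("A", "a1")))[0]
        b2 = chain_blocks(diagonal_pairs(10, chrom_a=("A", "a2")))[0]
        d = depth_classify([b1, b2])
        assert d.classes == {"2:1": 1}

    def test_lineage_specific_wgd_scenario_is_modal_two_to_one(self):
        from fernwgd.simulate import sim_genome_evolution, two_genome_scenario

        sc = two_genome_scenario(lineage_wgd="A", seed=21)
        sim = sim_genome_evolution(sc)
        parts = classify_tandem(sim.pairs)
        blocks = merge_blocks(chain_blocks(parts["candidate_anchor"]))
        between = [b for b in blocks if b.chrom_a[0] != b.chrom_b[0]]
        assert depth_classify(between).modal_class == "2:1"

    def test_shared_wgd_scenario_is_modal_two_to_two(self):
        from fernwgd.simulate import sim_genome_evolution, two_genome_scenario

        sc = two_genome_scenario(shared_wgd=0.8, seed=22)
        sim = sim_genome_evolution(sc)
        parts = classify_tandem(sim.pairs)
        blocks = merge_blocks(chain_blocks(parts["candidate_anchor"]))
        between = [b for b in blocks if b.chrom_a[0] != b.chrom_b[0]]
        assert depth_classify(between).modal_class == "2:2"


class TestSyntelogs:
    def test_within_genome_block_emits_paralogue_pairs(self):
        blocks = chain_blocks(diagonal_pairs(10, chrom_a=("A", "a1"),
                                             chrom_b=("A", "a2")))
        out = syntelog_pairs(blocks)
        assert len(out) == 10
        assert {p.relationship for p in out} == {"syntenic_paralogue"}

    def test_between_genome_block_emits_orthologue_pairs(self):
        out = syntelog_pairs(chain_blocks(diagonal_pairs(8)))
        assert {p.relationship for p in out} == {"syntenic_orthologue"}

    def test_orthologue_emission_precision_on_synthetic_truth(self):
        from fernwgd.simulate import sim_genome_evolution, two_genome_scenario

        sc = two_genome_scenario(lineage_wgd="A", seed=23)
        sim = sim_genome_evolution(sc)
        truth = {frozenset((r.gene_a, r.gene_b)): r.relationship
                 for r in sim.truth.itertuples()}
        parts = classify_tandem(sim.pairs)
        blocks = merge_blocks(chain_blocks(parts["candidate_anchor"]))
        between = [b for b in blocks if b.chrom_a[0] != b.chrom_b[0]]
        emitted = syntelog_pairs(between)
        correct = sum(truth.get(frozenset((p.gene_a, p.gene_b))) == "orthologue"
                      for p in emitted)
        assert correct / len(emitted) >= 0.95


class TestIO:
    def test_gene_orders_get_consecutive_ranks(self, tmp_path):
        path = tmp_path / "orders.tsv"
        path.write_text(
            "genome\tchrom\tgene_id\tstart\n"
            "A\tc1\tg2\t5000\nA\tc1\tg1\t100\nA\tc2\tg3\t1\n")
        loci = read_gene_orders(path)
        assert loci["g1"].index == 0 and loci["g2"].index == 1
        assert loci["g3"].index == 0

    def test_homology_pairs_resolve_against_loci(self, tmp_path):
        orders = tmp_path / "orders.tsv"
        orders.write_text("genome\tchrom\tgene_id\tstart\n"
                          "A\tc1\tg1\t100\nB\tc1\tg2\t100\n")
        loci = read_gene_orders(orders)
        hom = tmp_path / "hom.tsv"
        hom.write_text("gene_a\tgene_b\tscore\ng1\tg2\t99.5\n")
        pairs = read_homology_pairs(hom, loci)
        assert pairs[0].score == 99.5

    def test_blocks_tsv_written(self, tmp_path):
        blocks = chain_blocks(diagonal_pairs(6))
        out = tmp_path / "blocks.tsv"
        write_blocks(blocks, out)
        import pandas as pd

        df = pd.read_csv(out, sep="\t")
        assert df.loc[0, "n_anchors"] == 6
        assert df.loc[0, "orientation"] == "collinear"
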