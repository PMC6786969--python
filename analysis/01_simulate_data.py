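#!/usr/bin/env python
"""Generate the synthetic study inputs with full ground truth.

Writes, under results/data/: the 7-taxon fern-like species tree; 1,000 gene
trees carrying a retention-0.4 WGD at the Azolla crown plus the four-condition
birth-death null sets; a 2,000-family gene-count matrix at the study rates;
a three-peak Ks sample; and two-genome gene orders/homology for a
lineage-specific and a shared WGD scenario.
"""

import argparse
import json
from pathlib import Path

from fernwgd import bd, simulate
from fernwgd.pipeline import stage_seed
from fernwgd.trees import ladderize

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()
out = args.outdir
out.mkdir(parents=True, exist_ok=True)

tree = ladderize(simulate.fern_species_tree())
(out / "species_tree.nwk").write_text(tree.to_newick() + "\n")
params = bd.BDParams(0.0031, 0.0039)
prior = bd.RootPrior(1.5)

node = simulate.find_clade(tree, ("Azolla_filiculoides", "Azolla_caroliniana"))
trees, truth = simulate.sim_gene_trees_wgd(
    tree, params, node, retention=0.4, n=1000,
    seed=stage_seed(args.seed, "trees"))
with open(out / "gene_trees.nwk", "w") as fh:
    for t in trees:
        fh.write(t.to_newick() + "\n")
(out / "gene_trees.truth.json").write_text(json.dumps(truth, indent=2))
print(f"gene trees: 1000 with WGD at node N{node.index} "
      f"({','.join(sorted(node.leaf_labels()))}), retention 0.4")

nulls = bd.simulate_null(tree, params, n_per_condition=1000,
                         seed=stage_seed(args.seed, "nulls"))
bd.write_null_sets(nulls, out / "nulls", params, stage_seed(args.seed, "nulls"))
print("null sets: 4 conditions x 1000 trees (multipliers 0.5/1/3/5)")

matrix, count_truth = simulate.sim_gene_counts(
    tree, params, prior, 2000, seed=stage_seed(args.seed, "counts"))
matrix.to_tsv(out / "gene_counts.tsv")
count_truth.to_csv(out / "gene_counts.truth.tsv", sep="\t")
print(f"gene counts: 2000 families, {int(count_truth.root_spanning.sum())} "
      "span the root")

sample = simulate.sim_ks_mixture((0.8, 1.0, 1.25), (0.08,) * 3,
                                 n_per_component=1000,
                                 seed=stage_seed(args.seed, "ks"))
with open(out / "ks_values.tsv", "w") as fh:
    fh.write("gene_a\tgene_b\tks\tclass\tcomponent\n")
    for i, (v, lab) in enumerate(zip(sample.values, sample.labels)):
        fh.write(f"sim{i}a\tsim{i}b\t{v:.6f}\tunclassified\t{lab}\n")
print(f"Ks sample: {len(sample.values)} values, "
      f"{sample.n_truncated} outside [0.05, 5]")

for name, kwargs in (("lineage_wgd", dict(lineage_wgd="A")),
                     ("shared_wgd", dict(shared_wgd=0.8))):
    sim = simulate.sim_genome_evolution(simulate.two_genome_scenario(
        seed=stage_seed(args.seed, name), **kwargs))
    gdir = out / f"genomes_{name}"
    gdir.mkdir(exist_ok=True)
    with open(gdir / "gene_orders.tsv", "w") as fh:
        fh.write("genome\tchrom\tgene_id\tstart\tstrand\n")
        for locus in sorted(sim.loci.values()):
            fh.write(f"{locus.genome}\t{locus.chrom}\t{locus.gene_id}\t"
                     f"{locus.index}\t{locus.strand}\n")
    with open(gdir / "homology.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for p in sim.pairs:
            fh.write(f"{p.a.gene_id}\t{p.b.gene_id}\t{p.score:.2f}\n")
    sim.truth.to_csv(gdir / "truth.tsv", sep="\t", index=False)
    print(f"genomes ({name}): {len(sim.loci)} genes, {len(sim.pairs)} "
          f"homology pairs, {len(sim.planted_blocks)} planted blocks")
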