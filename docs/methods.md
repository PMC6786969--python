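# Methods

`fernwgd` reimplements, as one tested pipeline over fully synthetic data,
the four lines of evidence used to establish episodic whole-genome
duplications (WGDs) in heterosporous ferns: shared gene-tree duplications
against a birth–death simulation null, birth–death rate estimation from
gene-family counts, Gaussian-mixture decomposition of synonymous-distance
(Ks) spectra, and syntenic-depth ratios. This note records the models, the
parameter choices, and the places where the design was genuinely open.

## Species-tree fixture

All tree-based analyses run on a 7-taxon ultrametric species tree: two
*Azolla* species, *Salvinia* and *Pilularia* (Salviniales), a polypod
(*Blechnum*) completing the core leptosporangiates, with *Lygodium* and
*Dipteris* outside. The topology is the accepted fern arrangement; the
branch lengths are *relative* divergence depths taken from the fern
timescale and rescaled to a root depth of 100 time units
(`fern_species_tree(depth=...)`). The rescaling is a deliberate package
choice: duplication/loss rates are quoted per branch-length unit, so only
the product rate × depth matters, and a root depth of 100 at the default
rates both keeps the rates sharply identified from 2,000 families and keeps
the acceptance probability of the all-taxa-conditioned gene-tree simulator
above roughly 1/200 even at five-fold rates (at a 300-unit depth the
five-fold condition would reject ~14,000 trees for every accepted one,
which makes the null design impractical without changing its definition).
The fixture's lengths are plausible, not measured; nothing downstream
assumes a unit of Myr.

## Gene-family birth–death model

Each gene duplicates at rate λ and is lost at rate μ, independently, along
every branch (a linear birth–death process). The default rates are
λ = 0.0031 and μ = 0.0039 per gene per branch-length unit — the values the
fern analysis reports — and they are simulation truth throughout, never
fitted constants.

*Transition probabilities.* The single-gene offspring law after time *t*
has the classical closed form: extinction probability α, and a geometric
tail with parameter β, where for λ ≠ μ, α = μ(e^{(λ−μ)t}−1)/(λe^{(λ−μ)t}−μ)
and β = (λ/μ)α, with α = β = λt/(1+λt) at λ = μ and the obvious λ=0 / μ=0 /
t=0 degenerations. Multi-copy transitions are built by iterated convolution
of this law truncated at the state bound M: every composition of an end
state m ≤ M has parts ≤ M, so truncation is *exact* for all retained
entries, and the row-sum deficit equals the probability of exceeding M
(checked < 1e−8 for all rates and branch lengths used in tests). The scalar
`transition_prob` is validated against 10⁵ exact event-driven (Gillespie)
simulations.

*Count likelihood.* A family's likelihood is a pruning recursion over
ancestral states 0..M (default M = 100, the bound the fern analysis used),
vectorised across families; leaf messages are one-hot, so their propagation
is a column lookup rather than a matrix product. The root state is summed
against a shifted-geometric prior on n ≥ 1 with mean 1.5 (P(n) =
p(1−p)^{n−1}, p = 1/mean) — the prior the fern analysis specified.

*Root-spanning conditioning.* Estimation uses only families observed in at
least one taxon on **each** root daughter clade (the reading of "spanning
the root" adopted here; conditioning on mere presence somewhere would not
remove the bias this device exists for). The conditioning probability is
computed in closed form: the probability that one root gene leaves no
observed descendant inside a clade follows the branch-wise probability
generating function recursion g = α + (1−α)(1−β)z/(1−βz), and the prior is
summed through its own pgf (a geometric series), so no truncation enters.
The closed form is itself checked against the simulated spanning fraction.

*Estimation.* (λ, μ) are maximised on the log-rate scale with Nelder–Mead
from a fixed four-point start schedule (deterministic), tolerance 1e−8 on
the log-likelihood. For speed the multi-start phase runs at a reduced state
bound (max observed count + 25) and the winner is polished at the full
M = 100; the two bounds agree to ~1e−12 at these rates because the state
distribution decays geometrically far below either bound. Standard errors
come from the central-difference Hessian at the optimum (delta method back
to the rate scale). A dense grid search on a small instance reproduces the
optimiser's result.

*Simulation.* Gene trees start from a single lineage entering at the
species root (the guest-tree convention; the shifted-geometric prior
belongs to the count likelihood, not the tree simulator — the two devices
play different roles and are kept separate). Lineages duplicate and die
along branches, enter both daughters at speciations, and extinct subtrees
are pruned. With `require_all_taxa` the simulator rejection-samples until
every species retains a gene, as the null design demands; rejection counts
are recorded. Gene-count matrices are simulated from the *same* offspring
law the likelihood uses (binomial survivors plus a negative-binomial
geometric sum), so estimator failures localise to the estimator.

## Duplication mapping and the burst test

Each gene-tree node is assigned to a species-tree node by LCA mapping; the
species tree is ladderized (larger clade first, ties by smallest leaf
label) so internal nodes carry stable indices N1..Nk root-to-tip.

Three counting decisions were genuinely open and are exposed as switches:

- **Duplication criterion.** A gene vertex with *any* child mapping to the
  same species node is a duplication in the standard reconciliation sense
  (`criterion="reconciliation"`; this flag is verified exhaustively against
  the brute-force oracle on all ≤4-taxon, ≤2-copies-per-taxon gene trees).
  The burst statistic instead uses `criterion="shared"`: *both* children
  map to the node, i.e. both copies survive across both daughter lineages.
  That is what "a duplication shared by the descendant taxa" means, and it
  is what separates an episodic event from background turnover: under the
  all-taxa survival conditioning, high-rate null trees are enriched for
  compensating single-copy duplications (any-child flag at the *Azolla*
  crown: 34% in the 5× null vs 29% for a retention-0.4 WGD — inseparable),
  while duplications retained in duplicate across both daughters stay rare
  (shared flag: 12% null vs 36% signal).
- **Counting unit.** `unit="apex"` (default) counts each *maximal*
  same-node-mapped subtree once — its apex vertex, whose parent maps
  elsewhere — and marks it duplicated when any vertex inside meets the
  criterion. This makes the gene tree the sampling unit and gives the
  expected arithmetic (50 root-duplicated + 50 single-copy trees → 50% at
  the root; counting every mapped vertex would give 25%, because a
  duplicated tree contributes three root-mapped vertices).
  `unit="subtree"` provides the per-vertex alternative.
- **Denominator.** All mapped records by default; `denominator="concordant"`
  restricts to subtrees whose topology is consistent with the (restricted)
  species tree, with duplicate copies of a taxon treated as exchangeable.

*Null calibration.* Following the published design, nulls are simulated at
rate multipliers {0.5, 1, 3, 5}, 1,000 accepted trees each, every tree
retaining at least one tip per species. Per node and condition the 95%
band is the empirical 2.5/97.5% quantile pair of per-replicate percentages;
replicates are 200 bootstrap resamples over the 1,000 null trees (the
natural tally unit is the tree, and 100+ replicate tallies are needed for a
meaningful empirical quantile — disjoint 10-tree sub-tallies would quantise
the percentage too coarsely). A node is flagged only when the observed
percentage exceeds the upper quantile in **every** condition — the
conservative reading of "exceeded the 95% confidence intervals of the
simulations".

Under the study conditions (retention 0.4 at the *Azolla* crown, 1,000
observed trees), the flagged set is exactly the injected node in 20/20
seeded replicates, with the observed percentage (33–39%) roughly double the
harshest null's upper quantile.

## Ks estimation and mixture decomposition

*Ks estimator.* Pairwise Ks is computed with the Nei–Gojobori (1986)
counting method: per-codon synonymous site fractions (mutations to stop
codons count as nonsynonymous; sites normalised so S+N = 3 per codon),
equal-weight averaging over all minimal mutational pathways for multi-hit
codons (pathways through stop codons are excluded unless all are), sites
averaged between the two sequences, and the Jukes–Cantor correction
d = −¾ln(1 − 4p/3), undefined (saturated) when the argument is
non-positive. This is a deliberate substitution for the codon-ML estimator
used on the real data — counting methods are dependency-free and
desk-verifiable — and the interface accepts externally computed Ks tables
so ML estimates can be dropped in. The implementation is cross-checked
against an independent counting implementation (agreement to < 0.02, the
residual being the stop-pathway convention) and recovers a simulated
synonymous divergence of 0.5 to within 10% over 500 pairs.

*Range filter.* Only pairs with 0.05 ≤ Ks ≤ 5 (both endpoints included)
enter mixture fitting; counts removed below, above and undefined are
reported.

*Mixture model.* Unequal-variance univariate Gaussians on the raw Ks scale
(the analysis being emulated reports per-component variances, so the
variance-model family is fixed to the unequal-variance 1-D case rather
than searched). EM runs from 10 deterministic k-means-style starts (first
start: exact quantile means; later starts: seeded resampling; each
followed by 10 Lloyd iterations); every start is advanced 50 iterations
and the best is polished to convergence (log-likelihood improvement
< 1e−8 or 1,000 iterations) — the short-EM strategy. Starts that collapse
(variance < 1e−8) are re-initialised, and a winner that collapses during
polish falls back to the next candidate; ten consecutive failures raise.
E-step densities are computed directly (no log-sum-exp): with the variance
floor the per-component log-density is bounded above by ≈9, so overflow is
impossible, and total-density underflow only occurs mid-collapse, where it
is treated as collapse. The log-likelihood trace is monotone and asserted
so in tests; a fitted run is cross-checked against an independent EM
implementation.

*Model selection.* K = 1..9 fitted, BIC = −2·loglik + (3K−1)·ln n
minimised, full BIC table retained. Component gene-pair counts are
reported both by hard assignment (maximum responsibility) and as soft
responsibility sums. On the simulated fern layout — components at 0.8
(recent *Azolla*-type WGD), 1.0 (divergence) and 1.25 (older WGD), sd
0.08, 1,000 pairs each — BIC selects K = 3 and all means return within
±0.02; on single-Gaussian samples K = 1 is selected in ≥ 90% of replicates.
Each Ks set is fitted separately, never pooled.

## Synteny

All coordinates are gene ranks (0-based ordinal along the chromosome);
base-pair starts are converted on input. Homology pairs are an input — no
sequence search is reimplemented.

- **Tandem rule.** Same genome, same chromosome, rank distance ≤ 10
  (inclusive, "within ten genes apart"); tandem pairs never enter chaining.
- **Chaining.** Per chromosome pair, dynamic programming on the
  (rank_a, rank_b) dot plot maximises anchor-score sum minus a gap penalty
  of 5 per rank skipped on either axis, gaps capped at 25 ranks, run in
  both orientations. Extraction is greedy: each round the best remaining
  chain in either orientation claims its anchors (so a long collinear
  chain can never be discarded wholesale for sharing one stray anchor with
  an inverted chain); chains shorter than 5 anchors are discarded. Ties
  break toward lower rank_a then rank_b, making the output deterministic.
  On instances small enough to enumerate, the extracted block-set scores
  equal a brute-force search.
- **Merging.** Same-chromosome-pair, same-orientation blocks merge when
  the gap is ≤ 25 ranks and the union stays monotone — a simplified
  quota-style merge.
- **Depth.** Blocks are connected when their regions overlap (within a
  25-rank tolerance) on either genome; per connected component, regions on
  each side are merged with the same tolerance and the component is
  classified by its regions-a : regions-b pattern (1:1, 2:1, 2:2, other).
  Depth never consults Ks. The defaults (min 5 anchors, max gap 25,
  penalty 5) stand in for the "default parameters" of the published
  synteny tools, whose exact values are not recoverable; all are exposed.

The gap penalty of 5 per rank against anchor scores of ~100 is chosen so
that bridging a large structural gap through a single stray anchor is
never score-positive; with a penalty ≪ anchor score the chainer happily
stitches two true blocks through the centre anchor of an intervening
inversion.

## Synthetic genome histories

`sim_genome_evolution` descends an ancestral gene order (default 300 genes
on 2 chromosomes) through the species tree. Per branch: an optional WGD
(every chromosome duplicated, then each duplicate pair fractionated with
probability 1−retention, the lost side chosen at random), inversions
(reversing a random 60–100-gene interval), and tandem duplications
(adjacent copies, default rate 0.02/gene). Homology pairs connect all
same-family genes with Gaussian-noise scores (mean 100, sd 5) plus 2%
spurious cross-family pairs.

Two bookkeeping devices make the ground truth exact rather than
approximate. First, every gene carries a collinearity-segment id; an
inversion assigns fresh ids to the interval and its right flank, so a
planted block is simply ≥5 true pairs sharing a (chromosome pair, segment
pair) key. Second, inversion territories are kept disjoint in
ancestral-family space across the whole history, because independent
inversions in sister lineages hitting homologous intervals partially
cancel and would silently desynchronise the segment labels from realised
collinearity. Inversion spans (60–100) also exceed twice the chainer's
max gap, so a chain can never bridge an inverted interval through its
centre anchor — truth and detectability are aligned by construction, which
is what a recovery experiment needs. Copy-path strings record the side
taken at every WGD, so orthologue/paralogue truth is the prefix relation
between paths (a lineage-specific WGD extends one path; a differing choice
at a shared WGD makes the pair paralogous).

Under the default noise, block recovery is exact to ≥0.95
precision/recall; a lineage-specific WGD yields modal depth 2:1 and a
shared WGD 2:2, with no parameter changes between scenarios.

*Codon pairs.* The NG86 oracle generator applies a Poisson(target × S)
number of synonymous single-nucleotide events (multi-hit allowed, split
between the two branches) rather than simulating a continuous-time codon
model — simpler, and sufficient to calibrate a counting estimator. Truth
is the realised events-per-ancestral-synonymous-site. Optional
nonsynonymous events hit at most one codon each, keeping the two channels
exactly separable (ks = 0 in pure-nonsynonymous mode).

## Flow cytometry

Two standard curves, exact arithmetic: two-point interpolation between the
*A. thaliana* 2n and 4n standard peaks, 2C = (0.66·(F−S2n) +
0.33·(S4n−F))/(S4n−S2n) pg, and single-standard proportionality to *Z.
mays* 'CE-777', 2C = 5.57·F/S2n pg.

## Reproducibility

Every generator and experiment is bit-reproducible given its seed. The
pipeline derives per-stage seeds by hashing the stage name into a
SHA-256-based sequence below 2³¹, so stages re-run in isolation; null
conditions spawn child seed sequences from the master seed. Timestamps
appear only in stage manifests.

## Problem sizes

The packaged experiments run at: 20 replicates × 2,000 families (rate
recovery); 20 replicates × (1,000 observed + 4 × 1,000 null) trees (burst
detection); 1,000 Ks pairs per component; 300-gene two-genome histories.
These are the sizes at which the recovery properties quoted above were
measured.

## What passing does and does not show

The generators share their process definitions with the estimators, which
is exactly what a recovery experiment requires and exactly what limits it:
passing shows the inference machinery is internally correct and well
calibrated, not that real fern data satisfy the models. Real gene trees
carry reconstruction error and arbitrary rooting (rooting is the caller's
responsibility; an outgroup helper is provided); real Ks spectra are not
Gaussian mixtures truncated to [0.05, 5]; real homology scores are not
Gaussian; gene-family rates are not homogeneous across families or
branches (heterogeneous-rate and WGD-aware count likelihoods are out of
scope). The headline counts of the real fern analysis (e.g. 242/988 and
83/254 within-genome blocks/pairs, 3,587 orthologue pairs) depend on the
actual genome assemblies and are not reproducible here; the package
establishes method correctness at desk scale instead.

## Known limitations

- The linear birth–death model has no among-family rate variation and no
  ploidy-aware likelihood; the WGD enters only through simulation.
- The concordance filter treats duplicate copies of one taxon as
  exchangeable and resolves input multifurcations deterministically
  (lexicographic) rather than probabilistically.
- NG86 with Jukes–Cantor saturates above Ks ≈ 3 in practice; saturated
  pairs are reported, not imputed.
- The quota-style merge is a gap-bounded monotone union, not a full
  quota-ratio optimisation.
- `estimate_rates` warns below 50 usable families rather than refusing.
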