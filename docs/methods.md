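# Methods

This note documents the models implemented in `wgdkit`, their assumptions,
the defaults that matter, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## K<sub>S</sub> estimation (ks.py)

Pairwise synonymous and nonsynonymous divergence uses Nei–Gojobori (1986)
counting with a Jukes–Cantor correction. Per codon, each of the nine
single-base changes contributes 1/3 of a site to the synonymous count when
it preserves the amino acid (changes into stop codons count as
nonsynonymous). Differences between two codons are averaged over all
shortest mutational pathways (1, 2 or 6 orderings); pathways passing
through a stop codon are excluded from the average, and in the rare case
that every pathway is blocked the codon pair is excluded from the
comparison. Sites are averaged over the two sequences, restricted to the
codons actually compared (codons containing an ambiguous base are dropped
pairwise). `pS >= 3/4` (or `pN >= 3/4`) sets the `saturated` flag and the
corresponding rate is +inf.

NG86 replaces maximum-likelihood codon models (e.g. Goldman–Yang with F3×4
frequencies) deliberately: it is deterministic and exactly checkable
against brute-force pathway enumeration (the test suite does this over all
61×61 sense-codon pairs to 1e−9). The known cost is a mild underestimate
of divergence at high K<sub>S</sub>; this shifts distribution tails, not the
location of a WGD peak in the 0.5–1.5 range this package targets. Only the
standard genetic code is supported. Real-data use requires pre-aligned,
gap-free codon sequences; the bundled simulator evolves sequences without
indels, so the identity alignment is exact and no MSA stage exists here.

## Node-weighted age distributions (distribution.py)

Families are connected components of the similarity graph thresholded at
the paranome E-value cutoff (default 1e−10). Granular clustering (MCL and
relatives) is a tuning detail the weighting correction does not depend on;
components are the reproducible choice. Families are cut into subfamilies
by complete-linkage clustering so that **all** pairwise K<sub>S</sub> within
a subfamily are ≤ 5 ("does not exceed" read strictly; saturated or
undefined pairs count as beyond the ceiling; `method="single"` exposes the
looser chained reading). Subfamily trees are UPGMA
(average linkage) on the K<sub>S</sub> matrix — the tree is used only to
group pairs per duplication node, and a paranome near its duplication peaks
is approximately ultrametric, so a likelihood tree would change nothing the
weighting sees (`method="nj"` is the fallback for strongly
rate-heterogeneous subfamilies: neighbor joining with midpoint rooting).
Every internal node is treated as a duplication node; the
m cross-clade pairs at a node get weight 1/m. Invariants enforced by test:
per-node mass exactly 1, per-subfamily mass exactly n−1, and invariance of
the distribution to duplicated input rows (weights derive from the tree,
never from row counts).

Peaks: Gaussian KDE with Silverman bandwidth on weighted samples, argmax on
a fixed grid of step 0.01 spanning the data range. Confidence intervals:
B ≥ 100 bootstrap resamples (atoms drawn with probability proportional to
their weights), percentile interval of the resample peaks at coverage 0.90.
A degenerate sample (range below one grid step) returns its point mass with
a zero-width interval. Peak-window selection (default [0.6, 1.4]) uses a
closed interval on both boundaries.

## Co-linearity (collinearity.py)

The genome model is rank-based: base-pair coordinates only order genes
along scaffolds, then each gene is its 0-based rank. Strand is stored and
flipped by inversions but does not enter the chaining score (dot-plot
orientation only). Weak matches are removed by c-score:
`bitscore(a,b) / max(best(a), best(b)) >= 0.5`.

Chaining is an explicit dynamic program, not a profile-search synteny tool:
a chain may step from match p to q iff both rank coordinates advance by
1..`max_rank_gap` (default 25) in a consistent direction (forward or
inverted); `score = n_matches * 10 − (skipped ranks)`. Chains are extracted
best-score first (ties resolve to the lexicographically smallest
(rank_a, rank_b) sequence; only positive-scoring chains are reportable),
each match joins at most one segment, and segments need
`min_anchor_pairs` anchors (default 5; presets 5/10/15 mirror fragmented
vs chromosome-level assemblies). The defaults detect segments of ≥ 5
anchors through moderate fractionation (retention ≈ 0.3 leaves geometric
rank gaps with mean ≈ 3, far below the gap cap). On instances of ≤ 10
matches the extracted best chain is tested identical to exhaustive
enumeration. In self-comparisons the identity diagonal is masked and each
unordered pair appears once.

Overlapping segment intervals (closed; a shared rank is an overlap) union
into broader regions. `depth[r]` counts the segment intervals covering rank
r — recomputable by brute force, and that oracle is a test. `multiplicity`
adds the region itself as one copy (depth + 1 inside covered regions): a
position with three partner segments after two full-retention WGDs has
depth 3 and multiplicity 4, the genomic copy number. Both views are
exposed because "how many segments stack here" and "how many copies exist"
differ by exactly the reference copy. Recursive profile search for highly
degenerated segments is **not** implemented; depth beyond pairwise
segments arises only from overlapping pairwise segments. Cross-genome
multiplicity claims (4:1, 2:2, ...) come from connected components of the
region link graph.

## Orthologs and relative timing (orthology.py)

Reciprocal best hits with the cross-species cutoff 1e−5 applied in both
directions before best-hit selection; best = highest bit-score, then lowest
E-value, then lexicographically smallest partner (full determinism). The
RBH relation is a partial matching by construction. Ortholog distributions
are unweighted; saturated pairs are excluded and counted.

The timing rule is this package's formalization of a visual peak
comparison: 90% bootstrap CIs for the anchor peak and the ortholog peak;
anchor CI entirely below → the WGD postdates the speciation
(`wgd_follows_speciation`); entirely above → predates; overlap →
`indistinguishable`. The rule assumes comparable synonymous rates in the
lineages compared — rate heterogeneity can shift one peak relative to the
other. `relative_rate_caveat` checks this assumption when a shared third
taxon is available (the two focal species' ortholog peaks against it should
coincide; a >20% relative discrepancy returns a warning), but no correction
is applied.

## Placement (placement.py)

Gene trees are neighbor joining on Poisson-corrected amino-acid distances
(−ln(1−p); saturated pairs capped at the largest finite distance + 1), with
branch support from B = 200 codon-column bootstrap replicates (distances
and NJ recomputed per replicate, bipartitions counted). NJ replaces
ML tree inference deliberately: the placement questions are coalescence
orders, for which NJ on these families is accurate and orders of magnitude
cheaper; externally computed trees can be substituted by constructing
`GeneTreeNode` structures directly. NJ is implemented in numpy for speed
inside the bootstrap loop and is cross-checked against dendropy's
implementation in the test suite. A branch whose unrooted bipartition is
trivial (a pendant split) is present in every replicate and carries
support 100 by definition.

Families enter placement after: anchors with K<sub>S</sub> > 5 are dropped;
families sharing a surviving anchor are merged (an anchor spanning two
families marks a family-assignment artifact); retained families have
≤ 300 genes, ≥ 1 anchor pair and ≥ 1 outgroup gene. Rooting uses the
outgroup when its genes form a clade on some rooting of the unrooted tree,
else midpoint (ties to the lexicographically smallest tip pair).

Reconciliation is LCA mapping. A node is a **duplication** iff its child
clades share ≥ 1 species. "Consistent with the species phylogeny" is
formalized as: the node's map is a strict ancestor of both children's maps
(the standard LCA-reconciliation criterion); non-duplication nodes failing
it are **dubious**. An anchor pair must coalesce at a duplication node
(else it is reported unplaced); the trace toward the upper bound continues
past dubious nodes, and the number skipped is logged per placement.
Anchors with no speciation ancestor get a root-open interval and are
reported in an "unbounded" bin, never forced onto a branch. Support for a
placement is the bootstrap value of the branch leading to the coalescent
node; if that node is the root, its two child branches are the same
unrooted edge and either support is used. Multifurcating species trees are
allowed; strictness is evaluated on the multifurcation as given.

## The simulator (simulate.py)

What it emulates: gene families descending an ultrametric species tree;
WGDs duplicating whole scaffolds with independent per-gene retention;
later fractionation (loss restricted to genes with ≥ 2 surviving copies in
their genome — biased duplicate loss, which also keeps every family
represented); inversions reversing uniform rank windows and flipping
strands; tandem duplications; and codon sequences whose pairwise NG86
K<sub>S</sub> tracks event ages.

Units: branch lengths are per-lineage K<sub>S</sub>, so the expected
pairwise K<sub>S</sub> of two tips is their path length (twice the split
height); a WGD's `age_ks` is the expected pairwise K<sub>S</sub> between
the duplicates it leaves, placing the event at per-lineage height
`age_ks/2`. These are the only conventions under which duplicate pairs from
a WGD at `age_ks = 1.0` measure K<sub>S</sub> ≈ 1.0.

Sequence evolution is a proposal process: uniform random site, uniform
random different base; proposals creating an internal stop are rejected;
synonymous proposals are always accepted, nonsynonymous with probability
ω (default 0.2). The process stops when the number of accepted synonymous
substitutions reaches a Poisson target with mean
`target_ks × S_sites(parent)`; the Jukes–Cantor correction then recovers
the target from the observed (multiple-hit-reduced) differences. The
Monte-Carlo tests verify the contract: mean estimated K<sub>S</sub> within
15% of the target for targets ≤ 1.5, calibration slope 1 ± 0.15 over a
divergence ladder. Unreachable targets (short sequences, saturation) are
capped and flagged in the ground truth. Homology scores are similarity
proxies — bitscore = (1 − protein p-distance) × protein length, E-value
= 10^(−bitscore/10) floored at 1e−180 — sufficient because downstream
stages use only score rank order, an E-value cutoff and c-score ratios.

Defaults are chosen as realistic study conditions and are not tuned per
test: 500 families of 300 codons for single-genome age distributions, 100
scaffold genes; retention 0.3 for a detectable but fractionated WGD;
fractionation 0.05 per copy per K<sub>S</sub> unit and 2 inversions per
genome as mild background (scenario scripts that need exact copy counts set
them to 0); tandem rate 0.01; ω = 0.2 (typical purifying selection).
Identical seeds give byte-identical emitted files.

What the simulator does **not** emulate — hence what passing tests do not
show about real data: indels and alignment error, codon-usage and GC bias,
among-site and among-lineage rate variation, transposable elements,
tandem-array expansions, segmental (non-whole-genome) duplications, and
base-pair-scale structure. Results on real genomes additionally depend on
the external alignment quality and on assembly contiguity.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the
statistical claims testable in minutes: 20 seeded replicates for peak
recovery (500 families each) and placement recovery (100 families, 4
species, B = 100 bootstrap), 100 replicates for CI calibration (400 draws,
B = 200), 200 random instances for the chaining oracle, 1,000 random trees
for mass conservation. KDE grid step 0.01; linkage ties broken by
pre-sorted member order; NJ ties by smallest index pair; all RNG through
`numpy.random.default_rng` seeds.

## Known limitations

- Connected-component families can chain distinct families through
  promiscuous domains on real data; the subfamily K<sub>S</sub> ceiling
  bounds the damage but an MCL-style backend would be the upgrade path.
- NG86 saturates above K<sub>S</sub> ≈ 3–4; older WGDs need the anchor
  route (synteny survives where K<sub>S</sub> does not) and even anchors
  lose power with heavy fractionation.
- The disjoint-CI timing rule is conservative: overlapping intervals return
  `indistinguishable` rather than a direction.
- Depth is pairwise-segment coverage; heavily degenerated ancient
  multiplicity that only profile search would recover is underestimated.
- The placement stage dates duplications, not absolute ages; converting
  peak K<sub>S</sub> to time requires external rate or fossil calibration,
  which is out of scope.
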