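# Methods

This note documents the models and procedures `gilnet` implements, the
parameters that matter, what the synthetic fixtures emulate (and what they
do not), and the numerical and design choices made where the design was
genuinely open.

## Pre-processing and quality control

Input matrices are samples × probesets on a log2 intensity scale (a
`--log2` flag applies log2(x+1) for linear-scale inputs; probe-level
summarization such as RMA from raw array files is out of scope). Control
probesets are identified by id prefix (default `AFFX`), and probesets
mapping to more than one gene locus — or missing from the probe map, which
makes them unplaceable on the genome — are removed as ambiguous.

Quantile normalization forces every sample onto the cross-sample mean
quantile profile; after it, each sample's sorted intensity vector is
identical and per-rank values equal the cross-sample mean of that rank.

Outlier arrays are those failing **at least two of three** statistics, each
flagged above the Tukey upper fence (Q3 + 1.5·IQR across samples):

- T1: mean Euclidean distance to all other samples;
- T2: Kolmogorov–Smirnov statistic between the sample's intensity ECDF and
  the pooled ECDF of all samples;
- T3: 1 − median Pearson correlation with all other samples.

These three are this package's concrete choices for a "fail ≥ 2 of 3" QC
contract; they are ordinary, testable statistics, not a reimplementation of
any specific QC package. One known hazard (observed in testing): a
biologically distinct condition group comprising a small fraction of the
compendium (≲ 15 % of samples) can be flagged wholesale by the global
fences, because its members are mutually close but far from everything
else. Per-group QC after partitioning mitigates this; the global pass is
still the right place to catch individually aberrant arrays.

## Sample grouping

Samples are points, probes coordinates. k defaults to the common rule of
thumb ⌊√(n/2)⌋; k-means is Lloyd's algorithm with k-means++ initialization
and 10 seeded restarts (the seed is recorded in the output — any
within-cluster-sum-of-squares minimizer is acceptable; determinism and
provenance are what matter). Groups below `min_arrays` (default 25) are
reported as `too_few_arrays` and skipped; the threshold is configurable
because collections built with related pipelines have occasionally included
networks from slightly smaller groups.

## RMT thresholding

For each group the all-pairs Pearson matrix is scanned with hard thresholds
t (coarse grid 0.01 from `t_start` = 0.50, refined to 0.001 between the
last rejecting and first accepting coarse candidates — thresholds are
conventionally reported at 2 decimals, and refinement removes grid
sensitivity). At each t, genes with at least one off-diagonal |r| ≥ t are
kept, sub-threshold entries are zeroed (unit diagonal), and the eigenvalue
spectrum is tested:

- eigenvalues are deduplicated at tolerance 1e-6 (degenerate eigenvalues
  from disconnected duplicates otherwise spike the spacing distribution at
  zero); at least 100 distinct eigenvalues are required for a testable
  spectrum, otherwise the scan ends with `too_few_genes`;
- the spectrum is **unfolded** with a monotone cubic (PCHIP) spline fitted
  to the empirical cumulative spectral function at every 10th distinct
  eigenvalue (minimum 5 knots), and spacings are normalized to mean exactly
  1 — standard practice to remove the local density trend;
- the nearest-neighbour spacing distribution is compared to the Poisson
  form e⁻ˢ by χ² over 60 bins on [0, 3] (spacings above 3 pooled into the
  last bin), with critical value χ²₀.₉₉₉(59) ≈ 98.3 (p = 0.001).

**Transition semantics.** The spectrum of a dense random symmetric matrix
shows GOE level repulsion; a modular (near block-diagonal) one is Poisson.
The scan therefore looks for the *transition*: the chosen threshold is the
smallest accepting t **preceded by a rejection** at a lower candidate. If
the very first candidate already accepts, there is no transition inside the
grid to locate and the scan reports `no_threshold_found`. This matters in
practice: a pure-noise matrix thresholded at 0.5 is a sparse, fragmented
graph whose NNSD is trivially Poisson (isolated dyads have no level
repulsion), and a literal "smallest accepting t" rule would hand it a
spurious threshold. Under transition semantics pure noise fails — matching
the empirical behaviour of collections in which some sample groups yield no
network — while matrices with genuine modular structure emerging from a
random background are thresholded at the transition point.

The flip side is that the scan must *start inside the random phase*: a
matrix whose transition lies at or below `t_start` is reported as
transition-free. For the synthetic study fixtures (ρ = 0.95 modules over a
noise background, 40 samples per group) the transition sits near |r| ≈ 0.5,
so the pipeline runs on those fixtures start the scan at 0.45; the
operation default stays 0.50. Both settings are exposed in the run config.

Thresholding is on |r| (both correlation signs kept, sign stored per edge);
a signed-only mode is a configuration flag. When several single-locus
probes map to one gene, the probe with the highest mean intensity
represents the gene — a deterministic, logged collapse rule.

## Link-community modules

Modules are communities of *edges*. Adjacent edges (sharing exactly one
endpoint k) are scored by S = |n⁺(i) ∩ n⁺(j)| / |n⁺(i) ∪ n⁺(j)| with i, j
the outer endpoints and n⁺ the closed neighbourhood; similarity is not
defined (and never zero-filled) for non-adjacent pairs. Single linkage over
the sparse adjacent-pair list is computed exactly with a Kruskal-style
union-find — equivalent to hierarchical single linkage on the line graph —
and the dendrogram is cut at the height maximizing partition density

D = (2/M) Σ_c m_c (m_c − (n_c − 1)) / ((n_c − 2)(n_c − 1)),

with m_c edges and n_c induced nodes per community (communities with
n_c = 2 contribute 0). Ties between heights with equal maximal D resolve to
the lowest height (finest partition) — deterministic, and finer modules
suit downstream trait filtering. Edge clusters below `min_edges` = 2 are
discarded as unclustered, mirroring the convention that isolated edges are
not communities. Similarity is computed on the unweighted graph; a
weighted variant is a non-goal. Modules are named
`{collection}_{GIL}_LCM%04d` in descending edge-count order (ties by
lexicographically smallest gene id), so naming is reproducible.

## Enrichment, module similarity, meta-network

Term enrichment is a one-sided (over-representation) Fisher exact test —
the hypergeometric upper tail — for every term with at least one in-module
gene, against a background defaulting to all genes with ≥ 1 annotation
(configurable to all genome genes; the choice is logged). The cutoff is raw
p < 0.01 with no multiple-testing correction, matching the classical
DAVID-style procedure this stage reproduces; a Benjamini–Hochberg column is
emitted for information only. Term identifiers are not propagated up any
ontology graph.

Module pairs with ≥ 30 genes each are scored by gene-set Jaccard J and by
Cohen's κ over enriched-term presence vectors. The κ universe is the union
of terms enriched in at least one module of the collection (collection-wide
universes make κ comparable across pairs; a pair-local mode exists as
configuration). Modules with no enriched terms have undefined κ: they are
excluded from κ-based meta-network edges but keep their J scores. The
meta-network requires **both** κ ≥ 0.5 and J ≥ 0.3 (inclusive); the two
cutoffs correspond empirically (κ ≈ 0.5 tracks J ≈ 0.3 in the J~κ
regression) and both are configurable. The J~κ relation itself is reported
as ordinary least squares R² with slope-test p.

## Genetic features and trait overlap

Coordinates are 1-based inclusive throughout (GFF3 convention; BED input is
converted on read). QTLs shorter than 5 bp — single-marker placements — are
replaced by a 2 Mb interval (the median QTL size in the source database)
centred on the original midpoint and clamped to chromosome ends; centring
is this package's placement choice. GWAS SNPs with p ≤ 1e-4 become windows
of 300 kb **total** span (± 150 kb), reading "a 300-kb window around the
SNP" as the estimated average linkage-disequilibrium extent; a
`snp_window_per_side` flag switches to ± 300 kb. Genes inherit a feature's
trait by ≥ 1 bp overlap.

The module–trait score is a one-sided Fisher test of the 2×2 table (in
module / not) × (trait-overlapping / not) over a gene background defaulting
to the union of all GIL node sets — the frame modules are actually sampled
from; all-genome backgrounds are a configuration. A gene "overlaps" a trait
when it is assigned at least `min_features` distinct features of the
allowed types (counting genes, with the distinct features hit reported
alongside). Edge highlighting uses the union of the two endpoints' feature
sets against the same `min_features` rule. Biomarker SNPs are all known
SNPs within 50 kb of any trait-overlapping module gene (distance 0 inside
the gene), deduplicated and position-sorted.

The test is a guide, not a causal probability: trait assignment by interval
overlap produces many false positives (large QTLs, dense trait families,
tandem gene arrays), and no correction for positional gene clustering is
attempted here.

## Synthetic fixtures

`generate_compendium` plants, per condition group, single-latent-factor
modules: gene value = baseline + loading·z(sample) + noise, with loading
chosen so the expected within-module Pearson correlation is ρ
(loading²/(loading² + σ²) = ρ — the latent-factor construction scales
linearly and makes the expected correlation analytic, unlike an explicit
Cholesky of a target correlation matrix). Outside the home group all genes
are independent noise around their baseline plus a per-(group, gene)
condition offset that separates groups (σ_group = 1.0, an ordinary
between-condition effect size for log2 arrays and orders of magnitude above
the within-group noise σ = 0.1, so the planted grouping is recoverable by
any reasonable clustering). Defaults: 4 groups × 40 samples, 800 genes,
5 modules of 25 genes per group, ρ = 0.95. The first 2 modules of each
group reuse the same gene sets across groups — emulating the recurrence of
co-expression modules across condition layers that drives node redundancy
and cross-layer module similarity; the rest are group-private (and drawn
from disjoint pools across groups when the gene count allows, so planted
modules can serve as disjoint genomic targets).

`generate_genome` places genes in evenly spaced non-overlapping slots
(default 4 chromosomes of 3 Mb, ~15 kb spacing, 2 kb genes). Each targeted
module receives a contiguous slot run covered by a QTL (100 % of its genes)
plus two significant GWAS SNPs inside the run; untargeted ("random") trait
features are placed uniformly. All randomness descends from a single root
seed through named `SeedSequence` spawn keys, so each stage is
independently reproducible and outputs are byte-identical per seed.

What the fixtures do **not** emulate: probe-level artifacts (mismatch
probes, saturation, background), heavy-tailed intensity distributions,
correlated noise between modules, batch effects within groups, linkage
disequilibrium structure beyond a fixed window, or realistic gene length
and density variation. Passing tests therefore demonstrate that the
pipeline recovers the structure it is designed for under clean conditions,
not that it is robust to every artifact of real array compendia.

## Validation experiments (`gilnet.experiments`)

- **Spacing-test calibration**: iid Exponential(1) spacings (the Poisson
  null, n = 2000) must be accepted and GOE eigenvalues (500 × 500) rejected
  in ≥ 95 % of 100 seeded replicates each.
- **Planted-block scan**: 20 blocks of 30 genes at ρ = 0.95 among 200 noise
  genes, 25 samples; the scan must find a threshold strictly inside
  (0.5, 0.95) and the network must retain ≥ 90 % of within-block pairs.
  The noise genes are essential: with every gene in a block the matrix is
  modular from the scan start and there is no transition to detect.
- **Null calibration**: with genes placed without any module–position
  congruence and 5–15 random 150-kb features per replicate, the fraction of
  module–trait tests with p < 0.05 over 200 replicates estimates the
  empirical size of the nominal-0.05 test (observed ≈ 0.03 — conservative,
  as exact tests on discrete tables are). Positional clustering of module
  genes (the targeted-module layout) inflates this rate, which is exactly
  the tandem-array-style bias the trait test's caveat warns about.
- **End-to-end recovery**: the default fixture through the full pipeline
  with k = 4 (the known group count — the run validates recovery, not model
  selection) yields mean best-match Jaccard ≥ 0.8 between planted and
  discovered modules, and each planted-trait module attains the smallest
  module–trait p in its GIL.
- **Dilution**: per-group networks' union recovers strictly more planted
  within-module pairs than the single network built from the un-partitioned
  compendium (10 seeds) — the premise of layered construction. In pooled
  data the within-group correlation ρ is attenuated both by averaging over
  groups in which the pair is uncorrelated and by between-group variance,
  so planted pairs fall below any usable threshold.

Problem sizes in the experiments (matrix sizes, replicate counts) are
chosen so the full validation battery runs in a few minutes on one CPU
while leaving the Monte-Carlo margins comfortably away from their
acceptance bounds.

## Known limitations

- The three outlier statistics are stand-ins for an unspecified QC
  battery; flags agree with the "fail ≥ 2 of 3" contract but not with any
  particular published tool.
- The NNSD χ² uses fixed binning on [0, 3]; very small surviving matrices
  (just above the 100-eigenvalue floor) have low expected counts in the
  tail bins and a noisier statistic.
- Threshold scans cannot see transitions at or below `t_start`; such
  matrices are reported as failures rather than thresholded at the grid
  edge.
- κ on modules with few enriched terms is dominated by co-absence over a
  large universe; the collection-wide universe makes scores comparable but
  compresses them toward small values for sparsely annotated modules.
- Trait p-values are uncorrected for positional gene clustering and for
  multiple modules × traits; they rank hypotheses, nothing more.
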