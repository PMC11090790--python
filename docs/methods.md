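# Methods

This note documents the models, conventions and numerical choices behind
`melreg`, in the order the pipeline runs.

## Coordinates and peak-to-gene assignment

BED files and in-memory peaks are 0-based half-open; gene tables (TSV) are
1-based inclusive and converted on read, as are GTF `gene` features. The TSS
is the first transcribed base: `start` on the + strand, `end − 1` (0-based)
on the − strand.

The promoter window is strand-oriented. With upstream *u* and downstream *d*
(defaults 1000 / 0), a position at signed distance *x* from the TSS —
measured in the direction of transcription, negative = upstream — is in the
promoter iff −*u* < *x* ≤ *d*. The boundary convention (lower-exclusive,
upper-inclusive) makes the TSS base itself a promoter position while keeping
the window exactly *u* + *d* bp wide.

A peak is anchored at its summit when one is recorded, else at its interval
midpoint (configurable). Each peak gets exactly one category: promoter beats
gene body; among several eligible genes the smallest |signed TSS distance|
wins, ties broken by lexicographic gene id, so assignment is deterministic
and invariant to input order. Promoter/gene-body lookup uses interval trees;
the test suite checks the result against an all-pairs quadratic scan.

## Peak-set comparison

A peak of set A is *conserved* when it overlaps at least one peak of set B
by ≥ `min_overlap_bp` (default 1). Venn-style significance uses the
hypergeometric upper tail P(X ≥ k). The default universe is the union of the
compared peak sets merged into non-overlapping loci; note that with exactly
two sets this universe makes k the minimum forced by the margins (every
locus belongs to at least one set), so the default is only informative when
the universe is built from more conditions than the pair being tested, or
supplied externally. Gene-level overlap tests against the annotation
universe do not have this degeneracy and are what the acceptance script
reports.

## DE filtering and integration

Differential-expression tables carry (gene_id, lfc, pvalue[, padj]) with lfc
in log₂. Thresholds are strict — up = {p < p_max and lfc > lfc_min},
down = {p < p_max and lfc < −lfc_min}, defaults p_max = 0.001,
lfc_min = 1 — so boundary rows are excluded. Filtering defaults to the raw
p-value with a flag for the adjusted column. Bound-fraction reports give
|class ∩ bound| / |class| for all-DE/up/down/background, each with a
hypergeometric upper-tail enrichment p against a universe defaulting to all
genes in the table. Binding dynamics per gene: conserved (bound in both
conditions), de novo (induced only), lost (basal only), unbound.

## Regulon construction

Candidate targets are the intersection of the bound-gene sets from ≥ 2
cellular contexts; targets are candidates passing the DE filter. The mode is
sign(lfc) × tf_direction, with tf_direction = +1 when the contrast raises TF
activity (an induction experiment), so up-regulated bound genes become
activated targets. Weights are uniform 1 by default; `weight_mode="pvalue"`
uses 1 − p. An empty result is an explicit error, never a silent empty
regulon. Serialization is a TSV (tf, target, mode, weight) with stable
target ordering; DoRothEA-style tables import through a column mapping with
the mor sign preserved.

## ssGSEA

For one profile, genes are ordered by decreasing expression (ties broken by
gene id for determinism); rank weights are |midrank|^α with α = 0.25 by
default (α = 0 reduces the statistic to a pure function of in-set
positions). The score is the sum over all positions of the weighted in-set
ECDF minus the unweighted out-of-set ECDF. Signature genes absent from the
profile are dropped with a warning; a signature with no overlap, or covering
the whole profile, is an error. Matrix scoring applies the same statistic
column-wise; optional `global_range` normalization divides the whole matrix
by its score range. Cross-sample comparability holds only within one
parameterization.

## Activity scoring (NES)

Rank signatures come from a DE contrast (sign(lfc)·(−log₁₀ p), capped at ±10
to avoid infinities) or per cell (standard-normal quantile of the within-
cell midrank). The enrichment score of a regulon is the weighted mean of its
targets' signature z-scores with repressed targets' contributions flipped —
a two-tailed statistic, antisymmetric under mode flips.

Two numerical choices make the analytic null exact rather than asymptotic:

1. The namespace z-scores Φ⁻¹(midrank/(n+1)) are re-standardized to zero
   mean and unit population variance; for finite n the raw quantiles have
   variance below 1 (≈ 0.94 at n = 150), which would bias the analytic NES
   by several percent relative to a permutation null.
2. The analytic null variance of Σ mode·w·z accounts for drawing the k
   target z-scores *without replacement* from the finite namespace:
   Var = Σw² − ((Σ mode·w)² − Σw²)/(n − 1). As n → ∞ this reduces to the
   familiar Σw² (aREA-style) normalization.

With these, the analytic NES is standard normal under gene-label-random
signatures (verified: |mean| ≤ 0.05, sd within [0.9, 1.1] over 2000 draws)
and agrees with the seeded permutation null within Monte-Carlo error at
n_perm = 10 000. A closed exhaustive null (enumeration of all target-label
assignments) is available for small namespaces and is the ground truth in
the tests. Three-tailed and pleiotropy corrections found in full VIPER are
deliberately not implemented.

## Spatial phenotyping

Cell tables carry per-cell coordinates, a tissue class
(epidermis/stroma/tumor) and `<Marker>_<compartment>` mean intensities; the
classified compartment is nuclear for ZEB1/ZEB2/MITF/SOX9/SOX10 and membrane
for NGFR (antibody localization convention, configurable). Level
vocabularies: four levels (not_expressed/low/intermediate/high) for
ZEB1/ZEB2/MITF/SOX9, three for SOX10, two for NGFR. Calls use
lower-inclusive half-open bins: the highest level whose lower cutoff ≤
intensity. Cutoff values are mandatory configuration — the package never
assumes biological thresholds; the quantile helper (cutoffs at i/k quantiles
of the tumor-cell distribution) is a synthetic working default only, and
cross-slide intensity comparability is the user's responsibility.

Group comparisons partition tumor cells by one marker's level and compare
another marker's intensity across all group pairs with a two-sided
Mann-Whitney test — the exact null distribution for tie-free groups of ≤ 8
cells, the normal approximation otherwise — Bonferroni-corrected over the
pairs actually tested in the call (groups under 2 cells are excluded with a
warning). Medians are reported per group. Co-occurrence tables count cells
over the full Cartesian product of level vocabularies, zeros included, so
marginals reproduce per-marker compositions. Dot-map exports use the
convention high→red, intermediate→yellow, low→blue, not expressed→grey.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a `SimulationConfig`; the single seed
fans out to fixed per-generator substreams, so outputs are byte-reproducible
and adding a generator never perturbs another's draws.

* **Annotation/peaks** — genes on two synthetic chromosomes at 20 kb
  spacing, random strands; per peak the category is a single Bernoulli/
  multinomial draw (promoter 0.62, remainder split between gene body and
  intergenic) and only the *placement* is retried on collision, so planted
  fractions are unbiased. The induced condition holds 2000 peaks, twice the
  basal count; 33% of induced peaks are carried over from basal unchanged
  and de-novo peaks are rejection-sampled off basal intervals, so overlap
  recovery is clean. Defaults (0.62 promoter, 0.33 conserved, 2× peak
  count) are the study conditions of an induced lineage TF.
* **DE tables** — bound genes are DE with odds multiplied by 3.0 (solved
  numerically so the overall DE fraction stays 0.25, ≈ the ratio of a few
  thousand DE genes to a protein-coding transcriptome); DE genes draw
  p strictly below and |lfc| strictly above the thresholds, non-DE genes the
  complement, so planted flags are exactly recoverable — by construction,
  not approximation.
* **Expression** — x₉ⱼ = baseline₉ + mode₉·θⱼ·effect + N(0, 1) on a
  log-like scale, 2000 genes × 400 cells, 25 signed targets, θ ∈ {0, 2}
  in two equal groups. Because baselines are shared across cells, NES
  values within one run are correlated; null-centering claims are therefore
  assessed across generator replicates.
* **Spatial cells** — Gaussian-blob clones along the dedifferentiation
  axis; the ZEB1-high clones carry low MITF/SOX10/ZEB2 and elevated
  NGFR/SOX9, with a 5% ZEB1/NGFR/SOX9 triple-positive clone. Intensities
  are log-normal (σ = 0.25) around a geometric ladder of level means
  (1/5/25/125), so the ground-truth cutoffs (geometric midpoints) separate
  levels with ≈ 0.1% error. Stroma (10%) and epidermis (5%) cells are added
  as background.

Not emulated: read-level noise, peak-calling artifacts, chromatin structure,
batch effects, dropout in single-cell counts, imaging physics or
segmentation error. Passing tests demonstrate that the pipeline's logic is
correct and calibrated on data that satisfies its assumptions; they do not
certify performance on real data where those assumptions degrade.

## Problem sizes and degenerate inputs

The packaged study conditions (2000 genes/peaks, 400 cells, 1000 spatial
cells, 2000 null draws, 10 000 permutations) keep the full suite and the
acceptance script in the seconds-to-a-minute range on one CPU. Degenerate
inputs are explicit errors: zero-extent promoter windows, inconsistent
hypergeometric margins, empty universes, signatures with no overlap or full
coverage, constant profiles (warning, zero scores), zero-spread permutation
nulls, and empty regulons.
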