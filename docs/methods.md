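# Methods

This note records the models, conventions and numerical choices behind
`regvaran`, and what the synthetic fixtures do and do not establish.

## Coordinates and data model

All internal coordinates are 0-based half-open; BED files are emitted
as-is and VCF positions are converted on ingest (POS − 1). A single
convention end to end removes the usual off-by-one failure class at the
cost of one conversion at each boundary.

Regions carry a five-class type vocabulary (bivalent, enhancer,
insulator, promoter, silencer), provenance sets (sources, detection
methods, tissues), closest-gene and closest-TSS links, and an optional
constraint value in [0, 1]. Gene links carry one of four evidence
classes (direct, closest_gene, closest_tss, eqtl); eQTL and phenotype
links are consumed as precomputed tables — inferring them from raw
association data is out of scope.

## Redundancy collapsing

Catalogs of regulatory elements from different sources describe the same
elements with slightly different boundaries. Two same-type regions merge
when their reciprocal overlap, min(overlap/len_A, overlap/len_B), is at
least a threshold (default **0.8**; configurable). The relation is
closed transitively (connected components) and re-applied to the merged
union spans until a fixed point, which makes the operation idempotent —
collapse(collapse(X)) = collapse(X). The 0.8 default is deliberately
conservative: a lower threshold lets chains of partially overlapping
regions coalesce into spans much longer than any input element.
Different region types never merge, even at identical coordinates, so
type strata stay intact. Merged regions union their provenance sets and
keep the lexicographically smallest member id.

## Closest gene and TSS

Closest gene minimizes the gap distance between the region span and the
gene span (0 when overlapping; the stored distance is signed, negative
when the gene precedes the region). Closest TSS minimizes the distance
from the region midpoint to the strand-dependent transcription start
(start for '+', end − 1 for '−' under the half-open convention). Ties
break to the lexicographically smaller gene id, so results are
deterministic under input reordering.

## Variation constraint

The observed variant count per region (one per VCF site; multi-allelic
records count once) is regressed by **ordinary least squares** on five
covariates: region length (bp), GC fraction, and the fractions of the
region overlapped by segmental duplications, low-complexity regions and
exons (overlap fractions are computed on merged feature intervals).
Length enters raw (not log) and counts are untransformed; the fit
requires n ≥ 60 regions and a full-rank design, and a rank-deficient
design fails loudly with the collinear column pair named.

The constraint value is the mid-rank empirical CDF of the residual
(expected − observed): the fraction of regions with a smaller residual
plus half the fraction with an equal one. This maps any residual
distribution onto [0, 1], is strictly monotone in the residual, gives
tied residuals identical values, and is invariant to adding a constant
to all counts (the intercept absorbs it). Ranking raw residuals is the
default; an optional mode ranks internally studentized residuals
(leverage-adjusted), off by default because the raw-residual rank is
what the percentile-based flagging below operates on and the
studentized variant changes only borderline orderings.

Regions are **flagged as constrained** when their constraint is strictly
above the nearest-rank percentile of the constraint distribution
(default 99): q = sorted[⌈p/100 · n⌉ − 1]. With distinct residuals this
flags (100 − p)% of regions up to integer rounding (exactly 100 of
10 000 at the default), flags nothing when n is too small to resolve the
tail (n = 5 at p = 99), and never exceeds ⌈n/100⌉ flags.

## Control sampling and enrichment

Control regions are drawn per chromosome with the source set's exact
size multiset (sizes are not re-drawn from a fitted distribution —
each source size is placed once), uniformly over the usable space,
never overlapping excluded intervals (telomere/centromere masks).
Placement weights each usable slot by its number of valid start
positions, so the sampler is uniform over all valid placements and
byte-deterministic under its seed.

Enrichment uses Fisher's exact test at the **region level**: a region
"hits" a feature if it overlaps at least one feature base, and the 2×2
table is regions vs size-matched controls. With size- and
chromosome-matched controls, region-level counting avoids the length
confounding that base-level counting would need to model. The odds
ratio is (a·d)/(b·c), with the Haldane +0.5 correction applied (and
flagged) only when a zero cell occurs; the p-value is the exact
two-sided hypergeometric probability.

Per-region conservation summaries (fraction of bases with track value
strictly above each threshold — default 1, 1.5, 2 — plus median and
maximum) are computed over covered bases only: score tracks are
genuinely partial, and treating uncovered bases as zeros would conflate
missingness with low conservation. Regions with no covered base are
excluded and counted. Group comparisons use the Mann-Whitney U test
(exact enumeration when both n ≤ 8 and tie-free, otherwise the normal
approximation with tie correction; all-identical input returns p = 1).

## Score benchmarking

AUC is the Mann-Whitney probability (concordant pairs + half ties) /
(n₊·n₋), computed from mid-ranks; it equals trapezoidal integration of
the empirical ROC curve and is invariant under monotone transforms.
Scores are oriented higher-is-more-pathogenic and a variant is called
positive when its score is ≥ the threshold. Three operating points are
calibrated over the observed score values:

- **TPR90**: the *largest* threshold retaining TPR ≥ 0.9 (the most
  specific cutoff that keeps sensitivity), with its FDR;
- **FDR50**: the *smallest* threshold achieving FDR = FP/(FP+TP) ≤ 0.5
  (the most sensitive cutoff controlling false discoveries), with its
  TPR; undefined and flagged when unattainable;
- **max accuracy**, ties broken toward the higher threshold.

Variants missing a score are excluded per score (missingness differs
between scores) and the exclusions counted; genome coverage of each
track is reported alongside. An optional composite (mean of AUC and max
accuracy) is provided purely as a ranking convenience.

## Variant annotation and levels

A variant allele's affected span is POS..POS+len(REF)−1 converted to
half-open. Score lookup for deletions/MNVs takes the maximum over
affected positions; insertions read the two flanking positions — a
documented choice, since per-position tracks define no canonical indel
value. Levels are nested by construction: rare (AF strictly below 1%)
in-region (1), + functional element (2), + score at/above its FDR50
threshold (3), + region constraint ≥ 0.7 inclusive (4). A missing
population AF passes the rarity gate by default with an RV_AFMISS flag
(absence from a population database is itself evidence of rarity); a
strict mode treats missing AF as common. Multi-allelic records are
annotated per ALT with per-allele levels.

Structural variants (SVTYPE, symbolic or breakend ALTs) are annotated
with overlapping regions and controlled genes but no level, since a
large SV typically overlaps many elements; BND records are annotated at
each breakend position, and non-BND SVs without END or SVLEN are
skipped and counted. Existing consequence annotations (snpEff ANN /
bcftools BCSQ style) can be extended with `regulatory_region_variant`
entries for controlled genes not already present; existing entries are
never modified. Annotation is idempotent (RV_* fields are replaced, not
duplicated) and preserves record counts and genotype columns.

## HPO-driven prioritization and trio filters

Gene Z-score tables are converted to mid-rank percentiles over all
table genes; genes absent from the table are reported, never silently
assigned a percentile. Three percentile presets are named — permissive
0.90 (level gating), likely 0.95 (default reporting), strong 0.99 —
because different analysis stages legitimately use different
stringencies. Candidates are ranked by best qualifying gene Z-score,
ties by genomic order.

Segregation: recessive requires proband hom-alt with both parents het;
dominant requires an affected het/hom-alt proband with hom-ref parents.
Missing genotypes fail safe (the variant does not pass). Compound-het
pairing requires proband het for both variants of a gene pair, with
parental origin inferred from parental genotypes only (no read-backed
phasing): one variant carried by the father only and one by the mother
only is trans; same-side pairs are cis and excluded; pairs where either
variant is carried by both parents are kept but flagged phase-ambiguous.
Pairs are classified coding+coding / coding+regulatory /
regulatory+regulatory, with the coding label taken from consequence
annotations or a pluggable predicate.

## Synthetic data

Desk-scale defaults: 2 chromosomes × 1 Mb with 10 kb telomere and 50 kb
centromere masks, 2000 regions with log-uniform sizes in [100, 1000] bp
(the typical regulatory-element size range) and 5% planted
near-duplicates, 200 genes, 5000 trio variants with a 30/70
common/rare AF mixture, score tracks covering 15% of genome positions,
and a labeled set of 72 positives / 725 negatives (a 1:10 class ratio)
whose score separation is set via the expected AUC (default 0.85,
shift = √2·Φ⁻¹(AUC)). Constraint fixtures plant a 2% subset of regions
with the variant rate multiplied by 0.2. Every generator is
byte-deterministic under its seed.

The fixtures emulate the *statistical structure* the methods assume —
not real data. They contain no linkage disequilibrium, no mutation-rate
heterogeneity beyond the planted depletion, no realistic gene density
or tissue ontology, and genotypes are exact Hardy-Weinberg draws.
Passing tests therefore demonstrate correctness of the machinery
(counting, ranking, calibration, filtering, format round-trips) under
known ground truth, not performance on real genomes.

## Problem sizes

The test suite and acceptance checks run the constraint model at up to
10 000 regions (flag-rate check) and 5000 regions × 20 seeds
(planted-depletion recovery), annotation at 5000-variant VCFs, and
oracle-equivalence checks at 20 random fixtures per operation — sizes
chosen so the full stack exercises every code path in well under a
minute on a laptop while keeping Monte-Carlo assertions stable.

## Known limitations

- OLS on counts can yield negative expectations for short regions; the
  constraint rank is unaffected (it only orders residuals), but the
  expected counts themselves should not be interpreted as rates.
- The FDR50 threshold search assumes FDR is meaningful at every
  cut-point; on tiny labeled sets the threshold can sit on a single
  variant.
- Overlapping regions share variant sites, so the fitted per-bp variant
  rate sits slightly above the generating rate in dense catalogs; this
  biases no ranking, only the coefficient's interpretation.
- Trans inference from parental genotypes cannot resolve pairs where
  both parents carry both variants; such pairs are reported as
  phase-ambiguous rather than dropped.
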