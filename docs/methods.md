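# Methods

## The layered-meristem model

The package models an angiosperm shoot system as a chain of branch
initiation events (nodes) through which two genetically isolated cell
layers co-propagate: L1, the epidermis lineage (anticlinal divisions
only), and L2, the interior lineage. The assumptions carried throughout
are the five conditions under which cell variant frequency can be read
off read counts: diploidy, normal mitotic division, stable ploidy, no
gene conversion or extrachromosomal duplication at the site, and
retained heterozygosity. Under them, a mutation subfixed in a fraction
`g` of one layer's cells has

    E[VAF%] = 100 · g · s_layer(organ) / 2,     CVF% = 2 · VAF%

with `s_layer` the layer's read share of the organ. `g` is 1.0 for
founder-event mutations and 0.5 for first-daughter mutations (one
division after an unmarked founder). CVF is clipped at 100 with an
explicit violation flag — a true heterozygous subfixed mutation cannot
exceed 50% VAF, so the flag marks data that break the assumptions
rather than silently saturating.

Layer read shares default to the histological L1 cell proportions:
petal 0.251, stamen 0.146, sepal 0.140, leaf blade 0.122, carpel 0.094.
Endopolyploidy enters as per-layer mean genome-copy weights
(`s_L1 = f·w1 / (f·w1 + (1−f)·w2)`): the `none` and `both_layers`
scenarios coincide because uniform weights cancel, while `L1_only`
inflates L1 read shares — the diagnostic the scenarios exist for. The
elevated weight vector defaults to 70% 2C / 30% 8C cells (mean 4.4
against the diploid 2.0); the scenario structure, not the particular
weights, is what the analysis depends on.

## What the simulator emulates — and what it does not

`simulate_dataset` draws, per initiation event and lineage,
Poisson(`mu_event`) mutations (`mu_event` defaults to 1.0, the rate
scale suggested by nested mutation counts in woody *Prunus*). Flowers
attach at configured nodes with a 5 sepal / 5 petal / 5 stamen /
1 carpel inventory; forced events plant founder mutations, a
first-daughter mutation, and radial sector wedges (a petal with
adjacent sepals and a stamen). The default scenario has two flowers on
sibling sub-branch nodes, two deep anchor mutations per layer (trunk
node and the next node, a main-branch/sub-branch marker pair), eight
clean canopy control leaves, and three split-lysate sepal pairs in the
second flower. The second flower's L1 founder is deliberately unmarked:
its flower-wide L1 mutation is the first-daughter case, so the default
dataset exercises both ratio classes.

Read counts are total ~ Poisson(64.3) and alt ~ Binomial(total, f) per
site and sample, with symmetric-binomial strand splits. On top of the
organ-mean layer shares, each lysate draws its own realised L1 share
from Beta(m·κ, (1−m)·κ) with κ = 25. This is the biological variance of
micro-punched plugs: a 0.5 mm punch captures few cell files, so the
local L1:L2 ratio varies well beyond read noise — it is what makes
low-lineage VAFs range up to the ~21% assignment threshold rather than
sitting at their 7% organ means, it is shared between split subsamples
of one lysate (hence the high split-pair R²), and it is the shared
signal that makes same-layer VAFs correlate. Split subsamples get
independent read noise and an optional per-(mutation, subsample)
dropout rate for false-negative injection. `deterministic=True`
replaces all sampling by expected values (fixed depth, rounded counts,
no jitter): the zero-noise / infinite-depth limit used for exact-count
audits.

Not emulated: spatial cell geometry, mutational sequence context,
indels (SNVs only), amplification bias beyond binomial sampling, L1/L2
replacement or displacement events, and more than two genetically
distinct lineages per sample. Passing tests therefore demonstrate that
the estimators recover truth under the layered binomial model with
punch-scale share variation — not that real whole-genome-amplified
libraries are free of artifact classes the simulator does not generate.

Decoy sites for the filter audit are constructed deterministically per
artifact class (parental-heterozygosity, no supporting sample,
control-missing, strand-biased, triallelic, INDEL-adjacent, hard-filter
failures), each built to pass every cascade step except its own, so
expected per-step removal counts are exact.

## Filter cascade

Step 1 (parental): remove sites with more than `max_cmp_depth = 2` alt
reads in any control or alt reads in more than `max_cmp_total = 3`
controls. Step 2 (local quality): remove sites with no sample holding
at least `min_supp_depth = 5` alt reads, sites uncovered in more than
`max_cmp_miss = 3` controls, triallelic sites, strand-biased sites, and
SNVs within ±5 bp of an INDEL. Step 3: GATK-style hard thresholds
(QD < 2.0, QUAL < 30.0, SOR > 4.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0), strict comparisons, missing
rank-sum annotations passing. Design choices where convention had to be
fixed: strand bias is a two-sided Fisher exact test on pooled carrier
strand counts at α = 0.001 plus a both-strands requirement once alt
reads reach 6; "missing" means zero aligned reads; the carrier-side
presence threshold for de novo calling is ≥ 2 alt reads, mirroring the
control-side depth bound; boundary values pass everywhere. Every step
conserves counts (removed + retained = input) and logs a per-site
reason; the visual-inspection stage of manual pipelines is replaced by
an exported review table, with no automated stand-in claimed.

A de novo floral mutation is a retained site present in ≥ 1 sample of
one flower and in no sample outside it; a zero-coverage sample is
missing, never absent, and contributes no evidence either way.

## Statistics

**Permutation Z.** Observed Pearson r on the samples where both VAF
vectors are measured; the null permutes one vector's sample labels
(default 10,000 times); Z = (r_obs − mean r_null) / sd r_null and the
p-value is the add-one-corrected permutation tail. The construction
(permuting one vector, standardising against the null) is one of
several defensible ones; its null p-values are verified uniform by KS
test. Nesting restricts the correlation to the samples where the
candidate is observed — its flower or leaf — because including samples
where a floral mutation is structurally absent would turn the test into
presence-overlap with the anchors. A candidate joins a lineage group
when positively correlated (p < 0.05 per test, no multiplicity
correction by default; Benjamini–Hochberg can be applied to the
returned p columns) with all of that group's anchors. No data points
are ever dropped silently; outlier exclusion is an explicit input.

**Threshold assignment.** Max VAF over carpel/sepal/stamen samples
(petals excluded: the two layers' VAF distributions overlap there);
above 21.0% ⇒ Group 2 (L2), below ⇒ Group 1 (L1); petal-only or ≤ 2
records ⇒ unassigned. The 21.0 default can be recomputed as the max
non-petal VAF of designated flower-wide Group 1 mutations, which is how
the value arises in the first place.

**Founder classification.** Per-sample ratio of mutation VAF to the
mean VAF of one or more same-group anchors, over the mutation's own
flower (zero-VAF samples inside the flower are genuine observations and
enter as zeros); median ratio in [0.75, 1.25] ⇒ founder event, in
[0.35, 0.65] ⇒ first daughter, else indeterminate. Averaging the two
deep anchors steadies the denominator for the low-abundance lineage,
whose per-sample alt counts are small. The windows are deliberately
non-exhaustive: a median in the gaps is reported as indeterminate
rather than forced into a class.

**CVF sum check.** For an opposite-layer marker pair,
CVF_A + CVF_B per shared sample; the mean approaches 100 when the two
marked lineages partition the cell population. Samples where neither
marker is seen (off the marked branch, e.g. canopy controls) are
excluded as uninformative about the partition; same-layer pairs
(sums ≈ 2× one lineage's CVF) are a diagnostic outcome, not an error.

**Deming regression.** Closed-form total least squares with error-
variance ratio 1 (both subsamples are measured identically); verified
against an eigen-decomposition oracle to 1e-9. R² is reported on the
0–100 scale from the Pearson r, with the p-value from the Pearson test;
whether to report orthogonal-residual R² instead is left to the caller,
as the two conventions differ only in reporting, not in the fitted
line.

**Sectors.** The sharing matrix keeps mutations present in ≥ 2 organ
units of one flower (split subsamples collapse to their organ unit);
organs carrying none of the shared mutations are dropped by default
because zero rows collapse the dendrogram — the carpel typically exits
here, consistent with its early genetic isolation. K-means is plain
Lloyd from caller-stated initials (deterministic; ties to the lowest
cluster index) with seeded k-means++ as fallback; k is the user's
choice, with silhouette only advisory. The dendrogram is neighbor
joining on Hamming distances (Euclidean optional); bootstrap resamples
mutation columns with replacement and supports are the percent of
replicates containing each internal bipartition. Identical rows make
within-group resolution arbitrary — such splits carry mid-range support
honestly, as the degenerate-tie analogue of a weakly supported sector,
while genuinely separating bipartitions reach 100% in the zero-noise
limit. An all-zero distance matrix raises an explicit star-tree error.
The petal-sharing test is χ² = Σ(o−e)²/e with e = total/3, df = 2, and
an upper-tail p.

## Numerical and engineering choices

All randomness flows from a single seed per run (simulation and
analysis seeds are logged; fixed seed ⇒ bit-identical tables).
Coordinates are 1-based inclusive (VCF convention); missing VAF is
written `NA`, never 0; output tables carry the config hash, which
covers analysis parameters but not file paths. Zero-total cells are
missing, not zero, throughout. VCF I/O goes through pysam with
AD/ADF/ADR per-sample fields and the seven site annotations in INFO;
the TSV dialect carries the same information and the two round-trip to
identical tables.

## Problem sizes

The default study scenario is 2 flowers × 16 organ units, 8 branch
leaves, 8 canopy controls and 3 split pairs (51 samples) at 64.3x, with
~30 mutations. The test suite and acceptance script use 20 seeded
replicates of that scenario for parameter recovery, 1,000 null
replicates at 999 permutations for calibration, 1,000 bootstrap
replicates for sector supports, and a 3-wedge, 16-markers-per-wedge
flower for the zero-noise sector audit; the whole suite runs in well
under a minute on one core.

## Known limitations

Nesting by permutation correlation has ~60–70% per-candidate power at
the default 64x depth with 16–19 within-flower samples: the shared
layer-share signal is comparable to binomial read noise, particularly
for the high-abundance lineage whose VAFs sit near 45%. This is a
property of the study conditions, not of the implementation — at
300x (see `examples/05_lineage_nesting.py`) the same machinery nests
every flower-wide mutation correctly. Threshold assignment and founder
classification, which pool more information, recover truth at ≥ 90%
accuracy at 64x. The first-daughter/founder windows leave deliberate
gaps, so a minority of low-abundance comparisons return indeterminate
rather than a wrong class. Real data add artifact classes the
simulator does not model (chimeric reads, amplification error spectra);
the split-pair logic detects their qualitative signature but the
package makes no claim to remove them.
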