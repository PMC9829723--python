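# Methods

This note documents the models and procedures implemented in `soilhealth`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Data model

The canonical orientation of every count table is **samples × OTUs**;
readers transpose on a flag. Ratings follow the CASH registry of twelve
0–100 properties in three classes: biological (organic matter, respiration,
ACE protein, active carbon), chemical (pH, phosphorus, potassium, minor
elements) and physical (aggregate stability, available water capacity,
surface and sub-surface hardness). The total health score is the unweighted
mean of the twelve ratings and is missing whenever any rating is missing —
missing ratings are never imputed, because hardness ratings in real surveys
are present only for sample subsets and imputing them would manufacture
signal. Hardness ratings can be inverted (x → 100 − x) so that more
compacted soils score *higher*; the operation is an involution.

Taxonomic lineages are seven-rank tuples with a single `UNCLASSIFIED`
sentinel; once a rank is unclassified every lower rank is too. The
placeholder tokens treated as unclassified ("uncultured", "metagenome",
empty or prefix-only fields) are a configurable dialect list, since
classifier outputs vary; candidate-clade labels such as `KD4-96` or `RB41`
are preserved as valid names because they carry real information in soil
communities.

## Bioindicator calling

OTUs are screened before correlation: removed when present in fewer than
`min_samples` (default 10) samples, or when their mean count falls below
`min_relabund_frac` (default 1e-4, i.e. 0.01 %) of the mean per-sample
read depth. The abundance rule is interpreted on *mean* counts relative to
*mean* depth; a per-sample interpretation would make the filter depend on
sequencing-depth variance, which is noise, not biology.

Counts are normalized to counts per thousand reads (rows sum to 1000).
Spearman ρ is computed with average ranks for ties (verified against a
rank-then-Pearson oracle and against `scipy.stats.spearmanr`), two-sided
p-values from the t approximation, pairwise-complete over missing ratings.
Constant abundance vectors are skipped with a log entry rather than
erroring, so sparse OTUs cannot abort a run.

Benjamini–Hochberg is applied **within each rating across OTUs** (twelve
separate families) by default, because indicator sets are reported per
rating; a pooled family is available. Records must pass both |ρ| ≥ `r_min`
(default 0.3) and adjusted p ≤ `alpha` (default 0.05).

Direction "consistency" of an OTU is defined as: all of its significant ρ
values share one sign. This is one of several defensible conventions (an
alternative would align signs with each rating's health polarity first);
it is deliberately the simplest and is applied uniformly. Under the
simulator's strong single-axis effects most planted OTUs respond to *all*
ratings with class-dependent signs, so the reported consistency fraction on
synthetic data is low — that is a property of the convention plus the
planted structure, not a bug.

## Indicator-species analysis

For OTU *o* and level *k*: fidelity B = fraction of level-*k* samples with
count > 0; specificity either A = (total abundance in k)/(total abundance)
(`indval`) or the group-size-corrected A = (mean abundance in k)/(Σ over
levels of mean abundance) (`indval_g`, the default, matching the common
default of the reference R implementation); the statistic is √(A·B). Only
singleton levels are scored (no level combinations): for the two-level
factors this package targets, combinations add nothing.

The permutation null shuffles sample labels. When the number of distinct
label arrangements is ≤ 20,000 the null is enumerated exhaustively and p is
the plain proportion of arrangements whose best-level statistic meets or
exceeds the observed one (so a perfect 2+2 indicator gets p = 2/6: the true
labeling and its complement tie the maximum). Otherwise Monte-Carlo
sampling with the add-one estimator p = (1 + #{≥ obs})/(1 + n_perm) is
used, which can never return 0. Each OTU is reported at the level
maximizing its statistic, ties broken by declared factor order. BH is
applied across OTUs.

## Genomic traits

Per-genome records (genome size in bp, coding density in (0,1], *rrn*
copies, CRISPR arrays, BGC counts) are aggregated to per-taxon means at
every rank. With size normalization on (default), CRISPR-array and BGC
counts are divided by genome size and reported per Mb *before* averaging;
*rrn* copies and coding density are never size-normalized (they are not
gene abundances). Ranks above genus are aggregated from genus-level means
with each genus weighted equally, which damps the cultivation bias of
heavily sequenced genera; genome-pooled averaging is available behind a
flag and both schemes are exercised in tests.

OTU assignment walks genus → family → order → class → phylum → domain and
takes the first rank with a database entry; the assigned rank is recorded.
Unassigned OTUs are excluded from profiles, and community-weighted means
renormalize the relative-abundance weights over the assigned OTUs — the
alternative (treating unassigned abundance as zero-trait) would bias every
profile toward zero by an amount driven by annotation coverage rather than
ecology. Per-sample coverage (the un-renormalized assigned fraction) is
always reported so users can see how much abundance the profile rests on.

Community-weighted means are convex combinations, hence bounded by the
assigned trait extrema; a constant trait is returned exactly regardless of
composition. Both properties are tested.

## EWAS

Each external study contributes one two-level factor. The sign map — which
level of each factor is assumed beneficial to soil health — ships as YAML
with defaults for tillage (no-till +), water regime (drought −), organic
matter amendment (+) and fertilizer type (organic +); it is data, not code,
because these are scientific assumptions the user should be able to audit
and change. Categories are management, disturbance, plant association,
biome, other. Studies with fewer than 15 samples or with factors missing
from the sign map are skipped with warnings, never silently.

Signed scores (statistic × level sign, kept only at adjusted p < alpha) are
averaged per OTU across contributing studies within a category. Averaging
is across *studies*, not factors-within-category first; with balanced
synthetic designs the two coincide. Study OTUs join the survey by exact
ASV sequence identity after verifying all sequences share one length;
duplicate sequences within a table violate the dereplicated-ASV contract
and raise. OTUs scored in external studies but absent from the survey are
retained in the score table for audit and ignored at profiling. Flipping
every sign in the map exactly negates every community-weighted EWAS
profile; this is asserted end-to-end.

## Community statistics

PERMANOVA uses the Gower-centered form: G = −½ J D² J, SS_total = tr(G) =
(1/N) Σ_{i<j} d²_ij, sequential (Type-I) sums of squares tr((H_f − H_{f−1})G)
from cumulative hat-matrix projections of dummy-coded factors. Pseudo-F is
(SS_f/df_f)/(SS_res/df_res); the null permutes sample labels freely (no
strata), 999 permutations by default, with automatic exhaustive enumeration
when n! is small. Because sequential SS depends on factor order, R² is also
averaged over 50 seeded random factor orders; a single factor averages to
its own R² exactly. The hand-checkable 2+2 toy (within-group d = 0.5,
between 1.0) gives SS_total = 1.125, pseudo-F = 7.0, R² = 0.7778 and is
frozen in the tests, alongside a cross-check of pseudo-F against scikit-bio.

Mantel correlates upper-triangle entries (Pearson) with a joint row/column
permutation null, two-sided on |r|, exhaustively enumerated up to the same
arrangement budget.

LMG relative importance is computed exactly for up to 10 predictors via the
subset-weighting identity share_j = Σ_S k!(p−1−k)!/p! · (R²(S∪{j}) − R²(S)),
equivalent to averaging sequential R² increments over all p! orderings
(verified against factorial brute force for p ≤ 6). Shares sum to the
full-model R². Rank-deficient predictor sets raise an error naming the most
collinear pair.

Group contrasts (till vs. no-till on health score or trait profiles) use
Welch's t or the Mann-Whitney/Wilcoxon rank-sum test from scipy; nothing
bespoke.

## Co-occurrence networks

Indicator OTUs are aggregated to their lowest resolved rank. An edge joins
two taxa when OTUs from each share at least one common indicated rating in
the requested direction; the weight counts the unordered co-indicating OTU
pairs, checked against brute-force pair enumeration. Positive and negative
directions build separate graphs. Self-loops are excluded — within-taxon
co-indication is exposed as a node attribute instead. Node class labels
follow majority rule over the member OTUs' rating classes, with ties
hyphenated in the fixed order biological-chemical-physical. A
described-species flag marks labels that are not placeholders, candidate
clades (digit-bearing tokens such as `KD4-96`), or `Candidatus` names.
Export is GEXF 1.2 or GraphML via networkx; layout is left to the consumer.

## Synthetic data

One latent health axis h ~ Uniform(0, 100) per sample drives all twelve
ratings through per-rating loadings (biological ratings ≈ +0.9, aggregate
stability +0.8, chemical mildly negative, inverted hardness ≈ −0.8) plus
Gaussian noise (sd 8 rating points) and clipping to [0, 100]. A single
axis is used because real CASH ratings are strongly inter-correlated;
per-rating noise keeps them distinguishable. A planted fraction of OTUs
(default 10 % positive + 10 % negative) responds through expected log
relative abundance = baseline + direction · beta_scale · z(h) + noise,
with baseline sd 1.0 log-units, beta_scale 1.2 and residual sd 0.5 by
default; counts are multinomial at Poisson(depth_mean = 5000) depth — the
simplest mechanism that induces the compositionality of real amplicon data.
Tillage labels and a DNA-yield covariate are generated as noisy functions
of h.

Taxonomy is a balanced random tree (60 genera / 20 families / 8 orders for
500 OTUs) with 20 % of OTUs unclassified at genus so rank propagation is
exercised. Genus genome size couples to the genus's mean planted direction
with correlation `trait_coupling` (default 0.9): health-positive genera get
smaller genomes, denser coding and fewer *rrn* copies, placing them at the
oligotroph end of the life-history spectrum; CRISPR and BGC counts scale
with genome size. One to three genomes per genus are drawn around the genus
means.

The external-study emulator reuses survey ASV sequences for a configurable
overlap fraction (default 0.8 of 300 study OTUs), assigns each study one
registry factor, and multiplies planted OTUs' abundance by `shift_factor`
(default 8) in the level matching their health direction, in studies of 20
samples (10 per level). Effects are recorded in the ground truth for
scoring.

What the generator does **not** emulate: sequencing error and chimeras,
phylogenetically realistic trait evolution (traits are genus-level means
with noise), multi-level or confounded study factors, uneven study designs,
and the taxonomic composition of real soils. Passing tests therefore
demonstrate correctness of the estimators and recoverability of planted
effects under a clean generative model — not field performance on real
surveys, where effect sizes are smaller and confounding is real.

## Problem sizes and determinism

Default test and reproduction runs use 200-sample × 500-OTU surveys, 10
external studies of 20 samples × 300 OTUs, and 999 permutations — sizes at
which every planted effect is comfortably identifiable while a full
pipeline run takes seconds. All randomness flows from a single integer
seed through `numpy.random.default_rng`; reruns are byte-identical.
Exhaustive enumeration thresholds (20,000 label arrangements; 45,000 sample
permutations for PERMANOVA) are chosen so that designs up to 8 samples are
always exact.

## Known limitations

* Two-level factors only in indicator scoring; multi-level factors must be
  recoded as contrasts.
* Trait assignment is name-matching at ranks; no phylogenetic placement.
* The EWAS sign map encodes assumptions, not estimates; conclusions
  inherit them.
* PERMANOVA permutes freely; nested or repeated-measures designs need
  restricted permutation that is not implemented.
* The abundance filter and BH-family choices are configurable because the
  field's usage varies; defaults are declared in every run manifest.
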