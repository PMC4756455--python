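# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the design decisions behind `twinmeta`, in the spirit of a
statistical-software methods appendix. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort model and data types

The unit of analysis is a monozygotic-twin cohort sampled at up to two time
points. Five tables describe a cohort: species relative abundances
(samples × pipe-delimited clade lineages, proportions), KEGG-module
relative abundances, per-species marker-gene abundance matrices in reads
per kilobase (RPK), per-sample metadata (subject / twin pair / time point,
age, sex, smoking, BMI, fasting blood sugar and insulin, HOMA, blood
pressure, triglycerides, hsCRP), and a species × module genome-carriage
matrix (fraction of a species' reference genomes carrying the module).
Taxonomic input follows the upstream profiler convention of percentages;
conversion to proportions happens once at the I/O boundary and all internal
arithmetic uses proportions. Missing clinical values stay as explicit
missing and are dropped listwise per model, never globally, to maximise n
per association. The HOMA insulin-resistance index is
(fasting insulin [µU/mL] × fasting glucose [mg/dL]) / 405.

## Community analysis

Bray-Curtis dissimilarity Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ) is used throughout; it is a
semimetric (identity, symmetry, boundedness in [0,1] hold; the triangle
inequality need not). Ordination is classical PCoA: Gower double-centering
and eigendecomposition; axes with eigenvalue below 1e-10 — including the
negative axes a semimetric produces — are dropped, retained axes are sorted
by decreasing eigenvalue, and each axis is oriented so its
largest-magnitude coordinate is positive, giving a reproducible embedding.

Sample pairs are typed as *self* (same subject, both time points), *twin*
(co-twins, restricted to time point 1) and *unrelated* (different pairs,
time point 1). Group contrasts use Welch's unequal-variance t-test — the
robust default where only "t-test" is conventional. Pooled pairwise
distances are not independent (each sample appears in many unrelated
pairs); the tests deliberately ignore this, as is standard for this figure
style, and the synthetic null studies below measure how far that
miscalibrates the pooled contrast in practice. Two degenerate-variance
groups are handled by continuity: equal means give (t, p) = (0, 1),
unequal means (±∞, 0).

Cohort summaries use prevalence = percent of samples with relative
abundance strictly greater than 0.001 and the mean abundance over only the
passing samples (undefined, NaN, when a clade never passes); two cohorts
are compared by Pearson correlation over shared clades, separately for
prevalence and conditional abundance.

## Association model

Per feature, the response is arcsin√(relative abundance), the
variance-stabilising transform for proportions. Candidate predictors are
the clinical variables; age, sex and smoking are always included as forced
confounders, and the twin pair enters as a random intercept to absorb both
the shared-pair environment and the repeated-measures structure (a random
slope is not identifiable at these sample sizes and is not fit).

Variable selection is componentwise L2 boosting with univariate linear
base learners: 1000 iterations at learning rate 0.01 by default, the
candidate best correlated with the current residual updated each step.
Slow componentwise boosting converges to the saturated least-squares fit,
so an unstopped path would eventually "select" every candidate; the path is
therefore cut at the step minimising a BIC in which model size is the
number of distinct candidates entered so far. A candidate is selected when
it is chosen in at least 5 % of the retained iterations. The procedure is
deterministic; an optional bag fraction < 1 introduces seeded subsampling.

The per-feature model is fit by REML as a linear mixed model
(random intercept per pair); when the random-intercept variance estimate
collapses to ~0 or the fit fails, the model falls back to OLS with a
warning — with one time point and no planted pair structure this is the
common, correct outcome. Perfectly collinear columns are dropped greedily
by rank; a constant response returns zero slopes with p = 1. Only
boosting-selected candidate variables are tested and reported;
Benjamini-Hochberg is applied across all (feature, variable) tests of a
run as a single family (the family choice is configurable). Because only
selected variables are tested, the per-test p-values are post-selection
quantities; the calibration target for the screen is therefore the number
of q < 0.2 calls per screened feature, which the null simulation study
measures. Features are pre-filtered to those exceeding 0.001 abundance in
strictly more than 10 % of samples (both comparisons strict — the only
reading consistent with keeping a 4-of-36 feature at threshold 0.1 while
removing an all-zero feature at threshold 0). Samples are processed in a
canonical sorted order so results are exactly invariant to input row and
column order.

## Strain fingerprinting

Marker abundance is RPK = mapped reads / (marker length / 1000); fold
coverage ≈ RPK × read length / 1000, anchored by 10 RPK ≈ ×1 coverage for
100-nt reads. Eligibility: a (species, sample) enters comparisons only
when the median RPK over *all* the species' markers — zero-RPK markers
included — is strictly greater than 5 (≈ half-fold coverage), so absence
calls are not depth artefacts; both samples of a pair must pass, and
raising the threshold never adds comparisons. Distances are Bray-Curtis
over the full marker RPK vectors (not a presence-intersection), pooled
across species for the unrelated/twin/self Welch contrasts; per-species
mean divergence tables are reported separately. For display, profiles are
binned into absent/low/mid/high at a presence threshold of 0 RPK and
bounds 1 and 10 RPK (the coverage anchor); bins never enter distances.
Barcode difference reports mark markers present in exactly one sample of a
pair (twin- or self-discordant depending on the pair compared).

## Taxon-function classification

Spearman correlation (average ranks under ties, t-approximation p) is
computed for every species × module cell; BH is applied over the whole
matrix as one family, with tiers at nominal p < 0.01 and FDR q < 0.2. The
species co-occurrence network is Spearman over species profiles with its
own BH family; its significant-positive edges (ρ > 0, q < 0.2) support
the 'associated' call. A significant positive record is **encoded** when
the carriage fraction reaches the threshold (default 0.5 — the carriage
matrix gives a fraction of reference genomes but no conventional cutoff
exists, so the threshold is exposed and the fraction reported per record),
otherwise **associated** when the taxon has a significant-positive edge to
a taxon whose own record for that module is encoded, otherwise
**unexplained**. Negative and non-significant records are reported but
left not-classified: no formal rule for negative correlations is defined,
though the co-occurrence network's anti-correlations can be inspected
alongside them. Raising the encoded threshold can only shrink the encoded
set.

## Synthetic cohort generator

The generator is the package's ground-truth instrument; its defaults are
the documented study conditions (10 pairs × 2 time points − 4 dropped
samples = 36 metagenomes; dropped samples remove whole pairs' later time
point first, emulating pairs sampled only once).

*Species abundances.* Per-subject species log-abundances are lognormal:
baseline per-species means (SD 1.5) plus a subject latent (SD 1.0) plus
per-sample noise (SD `noise_sd`, default 0.3), exponentiated and closed to
sum 1. The subject latent mixes a pair-shared component with weight
`twin_species_correlation` (default 0.5), inducing twin similarity, and a
species-group component with weight `cooccurrence_strength` (default 0.6)
shared within blocks of `cooccurrence_group_size` = 3 species — the
co-abundance structure real gut communities show and the 'associated'
classification requires. Planted clinical effects overwrite the target
feature on the arcsin-sqrt scale (centre 0.35 ≈ 11 % abundance, slope =
sign × size per SD of the clinical variable, plus a pair intercept and
residual noise at `noise_sd`) before renormalisation, so the association
model is approximately correctly specified under the generator; the
renormalisation echo on the other features is the usual compositional
artefact and is left in deliberately.

*Strains.* Each pair has an ancestral barcode per species, markers present
with probability p = 0.8. Each twin copies an ancestral marker with
probability ρ and redraws it from Bernoulli(p) otherwise, with ρ chosen so
the expected twin discordance equals `strain_twin_divergence`; this
symmetric copy-or-resample model keeps every subject's marginal presence
frequency at p, which the obvious alternative — flipping twin B's markers
away from twin A — does not (flipping drags B's presence rate toward 0.5
and makes unrelated comparisons systematically more distant than twin
comparisons even at matched divergence, poisoning the null contrast). The
attainable twin divergence is therefore capped at the unrelated ceiling
2p(1−p) = 0.32, where twins become independent. The standalone
`generate_strain_barcodes` helper keeps the plain flip model and its exact
expected-Hamming-distance contract for testing divergence arithmetic in
isolation. Across time points, a subject's time-2 barcode flips each
marker with probability `strain_self_divergence` (default 0.02, rare
element gain/loss). Marker RPK = depth factor (default 1000, i.e. a
species at 1 % abundance sits at the ×1-coverage anchor) × species
relative abundance × barcode presence × lognormal noise, tying strain
distances mechanistically to abundance; a barcode-absent marker has
exactly zero RPK in all of that subject's samples.

*Modules.* Module mass per sample is Σ_s abundance(s) × carriage(s, m)
under a random binary carriage matrix (carrier probability 0.25, every
module guaranteed one carrier), with multiplicative lognormal noise and
row renormalisation. *Metadata.* Age (30-48 y), sex and smoking are drawn
per pair (identical twins share them); BMI has pair, subject and visit
components clipped to 18-28 kg/m²; glucose, insulin, blood pressure,
triglycerides and hsCRP are drawn from plausible healthy ranges; HOMA is
computed from glucose and insulin. All randomness flows from one seed
through spawned substreams; identical configuration and seed give
bit-identical cohorts.

What the generator does *not* emulate: read-level sequencing artefacts,
taxonomic misassignment, variable sequencing depth per sample beyond the
single depth factor, diet, or real phylogenetic correlation structure.
Passing recovery studies therefore demonstrate the statistical machinery
is correct under its own assumptions, not that the biological findings of
any particular cohort would be reproduced.

## Simulation studies and problem sizes

The validation studies (in `twinmeta.simstudy`, exercised by both the
acceptance tests and `scripts/acceptance.py`) use problem sizes chosen to
resolve each qualitative pattern in seconds to minutes on one CPU:

* association recovery — 20 replicates of a 20-pair, one-time-point cohort
  (40 samples, 50 species) with one planted BMI effect (|β| = 0.5 per SD
  of BMI, residual SD 0.1); the null uses the same layout without planted
  effects and reports q < 0.2 calls per screened feature;
* strain contrasts — 50 replicates of the default 36-sample layout with 12
  species × 60 markers; power condition: twin divergence 0.3, self
  divergence 0; null condition: twin divergence at the unrelated ceiling
  **and** twin species correlation 0 (strain distances are Bray-Curtis
  over raw RPK, so twin-correlated abundances alone would shrink twin
  distances; the null scenario removes both twin structures);
* classification recovery — 20 replicates, 21 species in 7 co-occurrence
  triples × 15 modules at module noise SD 0.05;
* community ordering — 50 replicates of the default cohort with stable
  self strains, checking mean(self) < mean(twin) < mean(unrelated);
* oracle agreement — 1000 random small instances comparing the fast
  Bray-Curtis / Spearman / BH paths against naive reference
  implementations (agreement to ≤ 1e-12).

## Known limitations

Pooled pairwise-distance t-tests ignore pseudo-replication (documented
above). Post-selection p-values in the association screen are not
calibrated per test; FDR control is assessed at the screen level.
Threshold-like associations are only surfaced as linear trends (no
changepoint model). The encoded/associated rules apply to positive
correlations only. The co-occurrence 'associated' call depends on the
network's q threshold and inherits its multiplicity choices. Strain typing
is marker-presence based; SNP-level haplotyping is out of scope.
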