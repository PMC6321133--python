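# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Statistical conventions

All two-group comparisons are two-sided Mann–Whitney U tests.  The exact
permutation null is used when the pooled sample size is ≤ 12 and there are
no ties (both branches are exercised in practice: per-timepoint group sizes
are 6 and 5, pooled analyses use 30 vs 25); otherwise the normal
approximation with midranks, tie correction and continuity correction.
Multiplicity is controlled by Benjamini–Hochberg within each family — one
family per block per analysis, never pooled across blocks — and q < 0.05 is
the significance criterion throughout.  Spearman correlations use midranks;
p-values use the t approximation with n − 2 degrees of freedom, which is
accurate at the n ≥ 55 sample sizes of the intended use and is applied
consistently in both the scalar routine and the vectorised network code.
Sample standard deviations use n − 1 everywhere.

Repeated measures: the default pools the five timepoints per animal as
observations (30 vs 25), accepting that within-animal correlation makes the
rank test anticonservative to a degree governed by the intraclass
correlation; `differential_table(..., subjects=...)` /
`select_differential(..., per_subject_mean=True)` instead average per animal
first (6 vs 5), the conservative alternative.  The null-calibration tests
therefore run with the subject effect switched off, isolating the
calibration of the test itself.

## Metabolome stage

Quantification: conc = (area / IS_area) / std_rel_area × std_conc, with the
cationic and anionic internal standards applied per metabolite ion mode; a
sample with a missing internal-standard area is rejected.  Metabolites must
be detected (non-missing) in at least `min_detect = 4` samples of every
group; "not detected" is NaN in memory and an empty cell on disk, and is
distinct from a measured zero.  Remaining missing values are imputed as half
the feature's minimum observed value — standard metabolomics practice for
below-detection-limit censoring — before Pareto scaling.

PCA is plain SVD on the scaled matrix with a deterministic sign convention
(the largest-magnitude loading of each component is positive).  OPLS-DA
follows the Trygg–Wold NIPALS recipe: class-orthogonal components (default
1, configurable; the number is a free modelling choice) are stripped before
a single predictive component is extracted, so t_pred ⟂ t_orth by
construction.  The feature-ranking statistic is cov(xⱼ, t_pred) with t_pred
rescaled to unit variance (the S-plot convention), making the reporting
thresholds (0.16 for metabolites, 0.11 for genus relative abundances in
percent) scale-meaningful.  Q² uses 7-fold cross-validation with
venetian-blind fold assignment after a seeded shuffle; folds are reduced
with a log entry when there are fewer samples than folds.

Enrichment is over-representation analysis: for a pathway of size K in a
universe of N metabolites and a significant list of size n with k hits,
expect = K·n/N, fold = k/expect and p is the hypergeometric upper tail
P[X ≥ k].  The universe size N is a property of the pathway library and
must be supplied with it; query metabolites outside the universe are
dropped with a warning.

## Microbiome stage

Rarefaction subsamples every sample to 16,014 reads without replacement
(multivariate hypergeometric); shallower samples are dropped with a
warning.  Alpha diversity reports observed taxa, bias-corrected Chao1
(S + F₁(F₁−1)/(2(F₂+1))) and Shannon entropy (natural log); the three
metrics are the conventional defaults since no single metric is canonical.
UniFrac is computed by scikit-bio on the rarefied table (the default input;
rarefied vs raw is configurable by the caller): unweighted is the unique
fraction of covered branch length, weighted is Σ_b l_b |A_b/A_T − B_b/B_T|,
raw by default with normalisation as a flag — raw being the historical
default of the pipelines this mirrors.  The test suite pins both variants
to an exhaustive branch-walk oracle on every rooted binary topology with up
to five leaves.

PCoA double-centres the squared distances (Gower) and eigendecomposes;
negative eigenvalues — expected for raw weighted UniFrac, which is not
Euclidean — are reported in the eigenvalue vector rather than zeroed, and
explained-variance ratios are taken over the positive part.  ANOSIM uses
ranked distances, R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2, and
a seeded permutation p-value with the +1 correction (999 permutations by
default).

The LDA effect-size screen is the published two-class recipe without the
subclass step (the emulated design has none): Kruskal–Wallis at α = 0.05,
then 30 bootstrap rounds of two-class LDA on abundances rescaled to sum
10⁶; the per-feature effect averages the LDA-axis displacement and the raw
class-mean difference, and the reported score is log₁₀(1 + |effect|) with
a 2.0 threshold.  Shrinkage LDA (Ledoit–Wolf) keeps the within-class
covariance invertible when features outnumber samples.

Metagenome prediction divides each taxon's counts by its 16S copy number,
multiplies by the reference taxon × KO matrix and sums KOs into pathways
(a KO contributes to every pathway it maps to; unmapped KOs to none).  The
operation is linear in the counts by construction.

## Integration stage

Procrustes superimposes the microbiome PCoA onto the metabolome PCA
(reference = metabolome, matching the visual convention of drawing
microbiome points onto metabolome points) over the first min(k, 3)
dimensions, with both configurations centred and scaled to unit Frobenius
norm, so M² ∈ [0, 1] and M² = 0 iff the configurations differ only by a
similarity transform.  M² depends on this normalisation convention and is
comparable only within it.

Autocorrelation maps are feature × feature Spearman matrices per block;
features are then clustered on the rows of that matrix (so two features
cluster together when they correlate similarly with everything else) by
Euclidean-distance hierarchical clustering with complete linkage, cut to
exactly k clusters — 7 for metabolites, 5 for genera, 3 for gene sets by
default.  Clustering raw abundance profiles instead is available by passing
the (transposed) abundance table; the correlation-row default was chosen
because the cluster map is derived from the correlation structure.  Cluster
labels are renumbered by first appearance, making the assignment
deterministic in the input order; complete linkage was preferred over
average as the common Euclidean default, with average available.

The network computes Spearman rho and p for every **cross-block** pair of
differential features (within-block pairs optional, off by default — the
cross-omics links are the object of interest), applies BH jointly over all
pairs computed in the run, and keeps edges with q < 0.05, signed by rho.
Nodes carry their block, cluster and direction of change (which diet group
the feature is elevated in).

## Synthetic data generator

The generator emulates the design the analysis targets: 6 control and 5
test-diet ("AD") animals sampled at weeks 8, 12, 24, 36, 52 → 55 samples;
184 metabolites; 106 genera.  Values it does **not** take from any source
are chosen once as field-plausible defaults:

* metabolites: log-normal concentrations, base log₂ level ~ U(−2, 6),
  residual SD 0.8 log₂ units, per-(animal, feature) random intercept SD 0.4
  (repeated measures), 40 diet-affected features with |log₂ fold| = 2, 80%
  decreasing in AD (most changed fecal metabolites drop under the test
  diet in the emulated design); ~5% of values masked as not-detected,
  preferentially at low concentrations (P(miss) ∝ 1 − within-feature rank).
* genera: Dirichlet-multinomial counts, p ~ Dirichlet(θ·w) with θ = 300
  (moderate overdispersion), log-normal base weights (SD 1.5 natural-log),
  read depths U(18,000, 26,000) so 16,014-read rarefaction is always
  exercised; 15 diet-affected genera with 4-fold weight effects, planted
  only among genera holding ≥ 0.2% of the baseline community — an effect on
  a taxon at the sequencing floor is not an observable effect; a random
  bifurcating tree with Exp(0.05) branch lengths.
* couplings: 6 (metabolite, genus) pairs tied through a shared bivariate
  normal latent factor, both regenerated as monotone functions of their
  latent with a common diet shift of 2 latent SD.  The latent correlation is
  calibrated a priori — Spearman→Pearson conversion 2·sin(πρ/6), then
  de-attenuation for the Dirichlet-plus-multinomial counting noise of a
  genus at the configured ~3% share — so the observed Spearman rho lands
  near the 0.7 target; the realised value is checked empirically (±0.1,
  seed-averaged) in the tests.
* references: 16S copy numbers U{1..7}; Poisson(1.5) background gene
  content over 60 KOs in 6 pathways, with the coupled genera given an extra
  25-copy dose of the designated pathway's KOs so its predicted abundance
  tracks the coupled metabolite; a metabolite library of 8 pathways over
  the 184-metabolite universe, one loaded with 12 planted diet-affected
  metabolites (size 15) as the enrichment truth.

Everything is derived from one master seed via spawned seed sequences, so a
dataset is byte-identical across reruns.  What the generator does *not*
emulate: compositional closure is real (a strong effect on abundant genera
shifts every relative abundance, so more genera than the 15 planted ones
differ significantly — as in real compositional data); there is no
taxonomic correlation structure beyond the random tree, no batch or
measurement drift, no zero-inflation beyond the detection mask, and
metabolite–metabolite dependence arises only through shared diet effects.
Passing the recovery tests therefore shows the statistical machinery is
correct and calibrated on data with the designed structure, not that the
pipeline is robust to every artefact of real measurements.

## Problem sizes and runtime choices

The default study (55 samples, 184 + 106 + 6 features) runs the full
pipeline in ~1–2 s, so the end-to-end recovery suite uses 20 seeds and the
network FDR-calibration suite 100 seeds of 15 × 10 null features.  The
UniFrac oracle covers all 124 rooted binary topologies with ≤ 5 leaves; the
Mann–Whitney oracle enumerates all splits of up to 10 distinct values.

## Known limitations

* Pooling timepoints treats repeated measurements as independent (see
  above); the per-subject-mean option trades power for validity.
* OPLS-DA Q² is estimated on the same scaled matrix used for fitting the
  scaler; scaling inside each CV fold would be stricter.
* The LEfSe-style screen omits the multi-subclass Wilcoxon step and is
  restricted to two classes.
* Raw weighted UniFrac is not a metric; PCoA on it reports the resulting
  negative eigenvalues but does not apply a correction (Lingoes/Cailliez
  corrections are out of scope).
* The enrichment test assumes the library universe is the measurement
  universe; with an external library whose universe differs from the
  detected metabolite set, N must be chosen by the user.
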