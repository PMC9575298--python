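# Methods

## Scope and data model

The pipeline consumes post-annotation artefacts only: a genus-level count
table, a functional-module count table (or KO-level counts plus module
definitions), and per-sample metadata. Read-level processing (quality
filtering, host removal, taxonomic and functional profiling) is upstream
and out of scope. Tables are tab-separated UTF-8, samples as rows, features
as columns, dense (no missing abundance cells); metadata may have empty CRP
and faecal-calprotectin cells, which become missing values and are handled
pairwise downstream. Module abundance is the sum of reads over the
module's KO members; KOs shared between modules count in each (KEGG modules
overlap), so count conservation holds only for disjoint definition sets,
and that is how the invariant is tested. An SCFA-production extension set
is merged with the curated definitions by id, curated version winning on
collision with a warning.

## Preprocessing

**Sample QC.** A sample must have at least `qc_min_features` (default 50)
features with nonzero counts in *both* modalities. The default refers to
full annotation tables (hundreds of genera); when the input is already
restricted to a prevalent-feature panel (as the synthetic tables are), the
cut should be rescaled to the same ~20–25 % fraction of the feature
universe — the calibration simulations use 15 of 59 genera accordingly.

**Prevalence filter.** Features present in fewer than `prevalence_min`
(default 15) samples are dropped, computed on the QC-passed sample set.
This is deliberately aggressive: with ten nuisance covariates and n ≈ 57,
rare features would otherwise be adjusted with almost no residual degrees
of freedom.

**CLR.** Proportions are obtained per sample; zeros are replaced by
0.5 × the smallest nonzero proportion of the whole table of that modality,
rows re-closed, and the centred log-ratio taken. The policy is the simplest
multiplicative replacement that keeps the transform well defined; it is
configurable, and it is applied per modality separately (a cross-modality
CLR is not defined here). Transformed rows sum to zero within 1e-9 and the
transform is invariant to sample-wise count rescaling — both asserted in
tests. Worth knowing: a feature absent from a sample lands at
ln(pseudo-proportion), far below any observed value, so presence/absence
churn dominates the CLR variance of rare features. This is a property of
the transform on real data too, and it is why the prevalence filter
matters.

**Nuisance adjustment.** Each feature is regressed (OLS with intercept) on
ten covariates — age, sex, diagnosis, CRP, and six medication flags — and
the residuals carry forward. Sex, diagnosis and the flags are 0/1; CRP is
untransformed. Samples missing a covariate are dropped with a log entry;
rank-deficient designs and residual df < 3 are hard errors naming the
offending columns. Psychometric scores are *not* adjusted; they enter the
association tests raw. A per-feature report (t statistic per covariate,
model R²) is available for post-hoc inspection of what the adjustment
removed.

## The association Bayes factor

Evidence for a pairwise association is the Zellner–Siow one-covariate
regression Bayes factor, a function of the squared Pearson correlation r²
and the pairwise-complete sample size n:

    BF10 = ∫0^∞ (1+g)^((n−2)/2) (1+g(1−r²))^(−(n−1)/2) π(g) dg,
    π(g) = InverseGamma(1/2, n·s²/2),  s = rscale = 0.354.

0.354 = √2/4 is the conventional "medium" prior width for a single
continuous covariate. The integral is computed on the log axis u = ln g by
adaptive quadrature (SciPy QUADPACK) after normalising by the integrand's
peak, to relative tolerance better than 1e-8; a vectorised variant
(`quad_vec`, per-component peak normalisation) evaluates whole edge
matrices and agrees with the scalar path to < 1e-7. An independent
Monte-Carlo oracle — sampling g from its inverse-gamma prior and averaging
the likelihood ratio — agrees to < 1e-3 at 10⁷ draws across
n ∈ {10, 30, 57, 100}, |r| ∈ {0, 0.2, 0.457, 0.7, 0.9}.

An alternative *correlation* Bayes factor with a stretched-beta(1/rscale)
prior on ρ (the form used by `BayesFactor::correlationBF`) is available via
`method="stretched-beta"`; the published analysis names only "JZS prior, r
scale 0.354", which matches the regression form's conventions, so that is
the default. The two differ numerically but share sign and ordering.

Properties that matter for interpretation:

* BF depends on r only through r²; direction is reported separately as
  Spearman's ρ (midranks for ties, recomputed on the pairwise-complete
  subset when values are missing).
* log10 BF is strictly increasing in |r| at fixed n.
* It is *not* strictly increasing in n at small fixed |r|: below the
  evidence point, additional observations initially favour the null (e.g.
  r = 0.2: −0.263 at n = 10 vs −0.272 at n = 30). This is a genuine
  property of the statistic; the test suite documents it as a known
  deviation from the idealised monotonicity property it also checks.
* At n = 57 and threshold log10 BF ≥ 0.5, the critical correlation is
  |r| = 0.3155, corresponding to a two-sided p ≈ 0.017 — the evidence rule
  behaves like a fairly strict per-pair test.
* Degenerate pairs (zero variance, |r| = 1) are rejected as errors at the
  pair level and skipped with a log entry in whole-matrix mode.

## Network and motifs

Edges with log10 BF ≥ 0.5 (inclusive — the weakest published edge sits at
0.509) form an undirected graph over taxa (T), modules (M) and
psychopathology scores (PP); nodes without surviving edges stay in the
graph as isolated nodes. A triangle motif is a 3-clique with exactly one
node per modality; T–T and M–M edges are computed and reported but never
form motifs. Enumeration is exhaustive over the PP node's T and M
neighbourhoods, sorted by taxon then module id, and is tested against a
brute-force oracle over all (T, M) pairs on random graphs. Published edge
lists can be replayed directly (`run_from_edge_list`); duplicate rows are
collapsed, and conflicting duplicates (same pair, different BF — present in
the shipped reference transcription) are resolved by the maximum with a
warning.

## Markers and diversity

Shannon diversity (−Σ p ln p, natural log) is computed on the QC-passed,
*pre*-prevalence-filter relative genus abundances: within-sample diversity
should not depend on a cross-sample filter, and the choice is configurable
by passing a different table. CRP, calprotectin and Shannon are tested
against HADS-D and WEIMuS raw, through the identical Bayes factor code
path, pairwise-complete per marker.

## The synthetic cohort generator

Defaults emulate the study conditions: 57 samples, 59 prevalent genera,
209 modules, mean depth 10⁶ (deep shotgun sequencing; counting noise is
negligible next to biological variance), log-scale feature noise
σ = 1.0 CLR units, overall zero fraction 0.3.

* **Rank-abundance and presence.** Log-baselines follow a power-law decay
  (slope 1.2 for genera, 0.8 for the more even modules). Absence is
  abundance-dependent: top-quartile features are always present, below
  that the dropout probability rises quadratically (capped at 0.8), with
  feature-average equal to `zero_inflation`. This mirrors the
  prevalence–abundance coupling of prevalent-feature tables; a uniform
  dropout would make every feature an occasional extreme CLR outlier,
  which real prevalent genera are not.
* **Covariates.** Age, sex, diagnosis, CRP, calprotectin (missing for a
  few samples, as published) and six medication flags are drawn to match
  the study population's moments; each flag is guaranteed non-constant so
  the adjustment design stays full rank. Configurable covariate effects
  add `effect × standardised covariate` CLR units to chosen features.
* **Planted motifs.** Each motif has a latent factor z ~ N(0,1) per
  sample, loading on one taxon, one module and one symptom with loading
  chosen so each arm's correlation with z is √|ρ|, hence each planted
  *pair* correlates at |ρ| — the minimal mechanism producing all three
  edges without asserting causal direction. Negative ρ flips the feature
  loadings (low abundance ↔ high severity, the published pattern). Scores
  are scaled to the published clinical moments (HADS-D 6.5 ± 4.5, WEIMuS
  31.5 ± 14.7), rounded and clipped to their ranges. Infeasible target
  sets (total |ρ| on one symptom near 1) are rejected.
* **What it does not emulate:** phylogenetic correlation between taxa,
  taxon→module functional coupling under the null, longitudinal structure,
  batch effects. Passing calibration here shows the statistics behave as
  designed on exchangeable compositional noise, not that real cohorts are
  free of structured confounding.

## Calibration and power at the study's dimensions

Measured by the acceptance script (200–1000 seeded replicates):

* Per-pair false-edge rate at n = 57: ≈ 1.6 % — the threshold is
  conservative pairwise.
* Family-wise, however, the joint network screens 59×209 + 2×(59+209)
  cross-modality pairs. With per-pair rate α ≈ 0.017 (≈ 0.03 after
  adjustment, which widens the null |r̂| distribution by using n = 57 in
  the BF while residuals have ~46 free dimensions), the expected number of
  chance triangles is roughly 2·59·209·α³ ≈ 0.1–0.7, so ~1/3 of no-signal
  cohorts show at least one chance triangle. Triangle findings at this
  scale need the motif-level context, not just per-edge evidence; the
  acceptance suite records the measured zero-triangle rate (≈ 0.66)
  against the idealised ≥ 0.95 expectation precisely to keep this visible.
* Recovery of a planted |ρ| = 0.5 motif: ≈ 0.75 over 200 cohorts. The
  realised planted pair correlations come out at ≈ 0.44–0.49 (within the
  generator's ±0.15 contract): features are residualised against 10
  covariates but scores are not, which shrinks feature–score correlations
  by ≈ √((n−k)/n) = √(46/57) ≈ 0.90 — an attenuation inherent to the
  adjust-features-only design, not removable by the generator without
  misrepresenting its targets. Per-edge power at the realised ≈ 0.45 is
  ≈ 0.86, and all three edges jointly cross in ≈ 0.75 of cohorts. At
  |ρ| = 0.2 recovery collapses to ≈ 0.03, so the power ordering is sharp.

## Numerical and reproducibility choices

Quadrature tolerances as above; evidence classes at 0.5/1.0/2.0 with
inclusive boundaries; pairwise-complete n stored per edge (n ≥ 4 enforced);
motif output sorted lexicographically for reproducible diffs; all
randomness flows from explicit integer seeds through
`numpy.random.default_rng`, and identical configs give byte-identical
artefacts. Replicate seeds in the calibration drivers are derived from the
base seed by a fixed affine map modulo 2³¹−1. Floats are written with six
significant digits.

Problem sizes used by the test and acceptance runs — 1000 replicates for
the null edge rate, 200 cohorts per calibration/power scenario, 10⁷ draws
per Monte-Carlo grid point — keep every estimate's Monte-Carlo error well
below the margins being asserted while completing in a few minutes.

## Known limitations

* The published Bayes factors cannot be re-derived exactly from the
  printed tables (they were computed from unavailable Pearson
  correlations); only rank-level agreement with recomputation from the
  printed Spearman values is checked (observed ≈ 0.99).
* The reference transcription contains one internally inconsistent
  duplicate pair and a motif count that disagrees with its own text by
  one; both are surfaced, not silently repaired.
* BIOM input, ILR/ALR transforms, partial correlations, posterior effect
  estimation and graph summaries beyond triangles (centrality, modularity)
  are out of scope.
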