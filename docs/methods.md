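# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices and the known limitations of `netmdmr`.

## Model and assumptions

The pipeline tests group structure in a multivariate outcome
Y (n participants × q ROI-volume columns) through the geometry of a
pairwise distance matrix rather than through a parametric multivariate
model.  The only distributional assumption of the inference is
exchangeability of participants under the null hypothesis (conditional on
covariates, via the permutation scheme below); no normality or
homoscedasticity of Y is required.  The analysis assumes:

- group labels are fixed inputs (they come from an upstream longitudinal
  classification and carry no uncertainty here);
- ROI volumes are complete — rows with missing volumes are rejected with
  a report, never imputed (listwise rejection mirrors analyzing complete
  scans only);
- head size is a nuisance: volumes enter as proportions of TBV, and
  between-region scale differences are removed by T-scoring per column.

### Normalization

ROI volumes (mm³) are divided by TBV (cm³ × 1000; the unit conversion
happens exactly once) and each column is mapped to T-scores
t = 50 + 10·(x − x̄)/s with the sample (n−1) SD, computed on the analyzed
subsample.  The 50/10 convention is the standard psychometric T; any
affine convention yields the same Manhattan geometry up to a global
scale, and every MDMR statistic is scale-invariant (tested).  T-scoring
is idempotent and commutes with column permutation.

### MDMR

With A = −½·d²_ij and C = I − J/n, the Gower matrix is G = CAC
(McArdle–Anderson convention; for Euclidean distances G equals the
centered Gram matrix Y_c Y_cᵀ, which supplies the classical oracle: the
single-outcome Euclidean pseudo-F equals the OLS/ANOVA F, and the trace
tr(HGH) equals the summed OLS model sums of squares).  The full-model
statistic uses df₁ = rank(X) − 1 and df₂ = n − rank(X); a term's
statistic is its pseudo-R² increment over the reduced model with
F_term = (ΔR²/df_t)/((1 − R²_full)/df₂).

Under the Manhattan metric G is generally indefinite; a pseudo-R² outside
[0, 1] is therefore possible, reported as computed and flagged.
Permutation inference is rank-based and unaffected.

### Permutation scheme

Covariate-adjusted terms are tested with Freedman–Lane permutation: with
H_r the reduced-model hat matrix, R_r = I − H_r, and P a random
permutation matrix, each permuted Gower matrix is
G* = (P R_r + H_r) G (R_r Pᵀ + H_r) — the distance-space image of
permuting reduced-model residuals while holding the reduced fit.  This
keeps covariates (age, sex, and the ordinal covariates of models 2–3)
fixed, so exchangeability holds under the adjusted null.  Expanding G*
into three precomputed matrices lets every permuted trace be assembled in
O(n²), so B in the thousands costs seconds.  Defaults: B = 9,999 (the
analysis drivers use 1,999, the calibration studies 199–499), add-one
p-value (1 + #{F* ≥ F_obs})/(1 + B), ties counted as ≥ (conservative).  A
`scheme="raw"` flag permutes G wholesale for comparison.  Pairwise
contrasts subset the distance matrix and re-center G on the subset
(centering is subset-dependent; subsetting a full-sample G would be
wrong, and a test asserts the recomputation).

Calibration: under the null generator (no planted effects, n = 60,
B = 499, 500 replicates) the empirical type-I error of the group term and
of the sex×group interaction at α = .05 falls inside the binomial 95% CI
around .05 (asserted in the acceptance suite).

### Effect sizes (δ)

δ_q = pseudo-R²(observed) − mean over K shuffles of column q of the
term's pseudo-R² when that column alone is dissociated from the design.
Shuffling is a uniform permutation of the single column across all
participants (unstratified; stratified shuffling within covariate strata
is not implemented), independent for each of the K draws.  K defaults to
1,000 (drivers use 200–500); the Monte-Carlo SE of the shuffled mean is
reported so users can judge stability.  Both shipped metrics decompose
additively over columns (Manhattan in d, Euclidean in d²), so one shuffle
costs O(n²) and the intercept-containing designs let the Gower centering
drop out of the increment algebraically.  δ is relative — it scales with
q and with the covariance of Y and must not be compared across studies.

### Ordination and centroid geometry

Partial dbRDA: covariates are projected out of G (G_p = R_cov G R_cov)
and of the constraint block; the constrained axes are eigenvectors of
H_c G_p H_c with scores scaled by √λ.  Three groups give at most two
axes.  Centroid uncertainty is shown as per-axis SEs (score SD within
group / √n_g) — axis-aligned by design, matching the plot contract of an
SE ellipse per centroid; covariance ellipses are a flag away in the CLI
figure.  Exact centroid distances are computed directly from G via
d²(u,v) = e_uᵀGe_u + e_vᵀGe_v − 2e_uᵀGe_v with e_g the group indicator
over n_g, which uses the full (possibly negative-eigenvalue) geometry; a
negative d² is flagged rather than clipped, and no Cailliez/Lingoes
correction is applied by default because the identity needs none.
For Euclidean distances the constrained eigenvalues equal those of an RDA
on fitted values, and centroid distances equal distances between group
mean vectors (both asserted; `vegan::dbrda` agrees up to its 1/(n−1)
inertia scaling).

### Post-hoc regressions

OLS of the standardized column on a two-group indicator plus age and sex,
on the two-group subset, no multiplicity correction (descriptive
framing).  The outcome is (T − 50)/10, i.e. unit-SD: coefficients are
standardized mean differences whose SEs are ≈ √(1/n_a + 1/n_b), the scale
on which the reported effects (−0.65, −0.56, +0.44, +0.58, ±0.35, +0.29)
live.

### Cohort summary

Group×sex counts, mean (SD) for TBV and any supplied continuous scores,
one-way ANOVA across groups, pairwise OLS contrasts, and Pearson χ²
(no continuity correction) for the ordinal covariates; degrees of freedom
follow the observed non-empty levels (7 income brackets and 4 education
levels give df 12 and 6).  A constant or absent covariate is reported as
not applicable.

## Synthetic cohort generator

The generator defines the study conditions; every downstream validation
runs against it.

- **Design**: group×sex cells 30/18, 76/32, 70/39 (n = 265, 89 female);
  age ~ N(3.2, 0.5) years identically across groups; TBV ~ N per
  group×sex with means/SDs 1063(68), 1011(90), 1087(103), 1001(112),
  1072(93), 1011(121) cm³ — so TBV differs by sex but not materially by
  group.  Income (7 brackets) and education (4 levels) are drawn
  independently of group, matching a cohort in which these do not differ
  between groups; planting them is possible but off by default.
- **Volumes**: one latent standardized score per participant×column,
  z = √ρ·f + shift + noise, with a single shared factor f per participant
  (loading ρ = 0.3, a moderate value for structural covariance of
  TBV-proportioned regional volumes) and noise SD √(1−ρ) so the marginal
  variance is 1.  Volumes are p_q·(1 + 0.10·z)·TBV mm³, where p_q are
  plausible per-region base proportions (synthetic defaults of the right
  order for LPBA40-style parcels) and 0.10 is a typical between-subject
  coefficient of variation.  Unit latent variance makes planted shifts
  equal standardized post-hoc coefficients, up to a small (<3%)
  attenuation from the shift's own variance contribution.
- **Planted effects** (defaults): left middle occipital −0.65 (changers)
  / −0.56 (P-low) vs P-high; left inferior temporal +0.44 / +0.58;
  bilateral middle temporal −0.35 in changers; right angular +0.29 in
  females.  A truth record accompanies every draw.
- **What it does not emulate**: anatomically structured covariance
  (one global factor instead of network- or lobe-level blocks),
  segmentation noise, site/scanner effects, age-volume growth curves, and
  any group difference in covariate distributions.  Passing tests
  therefore validate the statistics under a clean, exchangeable null and
  known planted signal — not robustness to those real-data features.

## Numerical choices

- Hat matrices via SVD with relative tolerance 1e-10; aliased design
  columns dropped greedily with a log message before any statistic.
- Distance matrices validated (symmetry, zero diagonal, non-negativity)
  at 1e-8; Gower row sums vanish to the same tolerance.
- Permutations are drawn as argsort of uniform variates from
  `numpy.random.default_rng(seed)`; every stochastic quantity is
  bit-reproducible given its seed, and the pipeline derives stage seeds
  from one master seed via `SeedSequence` spawning in a fixed order,
  recorded in the run manifest.
- CSV IO parses floats in round-trip mode so write→read is bit-exact.
- Constant outcome columns: T-scoring refuses them (named error); the
  jack-knife assigns δ = 0 with a warning (a shuffle is a no-op).
- δ ranking ties break lexicographically by column name (logged
  deterministic order).

## Problem sizes in the shipped studies

Chosen as the package's own defaults for its validation studies: type-I
calibration at n = 60, B = 499, 500 replicates; planted-effect recovery
at the full design (n = 265 / two-group subsets), K = 200, 100
replicates; external-oracle fixtures at n ≤ 40.

## Design decisions that were genuinely open

- The reported per-contrast "β" is implemented as the term's pseudo-R²
  increment: its magnitudes (.003–.009) match R² increments, and the
  effect-size procedure is itself defined through pseudo-R² changes.
  dbRDA canonical coefficients were the alternative reading; they are not
  implemented.
- Pairwise contrasts are fit on two-group subsets (matching the layout of
  paired-comparison tables) rather than as within-three-group contrasts;
  the omnibus three-group fit is also available.
- T-scoring uses the combined analyzed sample, not per-analysis
  subsamples (configurable).
- The FPN's "pars opercularis and pars orbitalis of the inferior frontal
  gyrus" count as two regions — required to reach 11 — and the two middle
  frontal segments are likewise distinct; the DMN's "prefrontal and poles
  of the superior frontal gyrus" are two regions, which places the
  prefrontal superior frontal gyrus in both networks alongside the
  precuneus and angular gyrus.
- dbRDA partials out the model-1 covariates before ordination
  (consistent with the MDMR adjustment); a flag disables partialling.

## Known limitations

- Under the planted scenario's published effect magnitudes (0.35–0.65 SD
  on unit-variance outcomes), the top-2 δ ranking is not a
  high-probability event at these sample sizes: a null column's realized
  group difference has SE ≈ √(1/n_a + 1/n_b) ≈ 0.13–0.17, and the
  maximum over ~20 null columns is comparable to the smaller planted
  shifts.  Replicate-level recovery rates are therefore ~50–65% per
  contrast (the acceptance suite measures and reports them); a single
  dataset's observed top-2, as in any one real cohort, is a draw from
  that distribution.
- Manhattan-metric pseudo-R² lacks the [0, 1] guarantee (indefinite G);
  interpret flagged values with care.
- No longitudinal or mixed-effects extension; no kernel/graph metrics
  beyond Manhattan and Euclidean; no per-region permutation p-values
  (δ only, by design).
- Multiple testing across contrasts and networks is uncorrected by
  default, mirroring the descriptive framing of the follow-ups; a Holm
  adjustment is available behind `posthoc_table(..., correction="holm")`.
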