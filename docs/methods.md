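# Methods

## The connectivity domain

Connectomes are pairwise Pearson correlations of regional time series on
a 17-network cortical parcellation (Schaefer-style region names of the
form `17Networks_<LH|RH>_<Network>_<area>_<k>`). The triple network model
(TNM) keeps eight subnetworks — SalVentAttn A/B (salience, SN),
Cont A/B/C (frontoparietal, FPN), Default A/B/C (default mode, DMN) —
and every other label (visual, somatomotor, dorsal attention, limbic,
temporo-parietal, subcortical) is excluded; with the full 300-region
cortical + 32-region subcortical lookup this reduces 332 regions to 145.
Edges are the within-SN, within-FPN, within-DMN, SN–FPN and SN–DMN
region pairs; the FPN–DMN block is excluded because the TNM treats that
communication as SN-mediated. Edge order is row-major over the upper
triangle restricted to allowed pairs, with the region-table file order
canonical for all indexing (0-based, contiguous). Ingested matrices must
be symmetric to 1e-12 with a unit diagonal; asymmetry is an error, not
silently repaired, so upstream problems surface.

## The phenotypic domain

Eight predictors in fixed order: sex (1 = male, 0 = female), age,
education, family history density, AUD symptom count, Drinking, Urgency,
Alcohol seeking.

- **FHD** = Σ weights of affected relatives / number of counted
  relatives, with 0.5 per affected parent or full sibling and 0.25 per
  affected grandparent or parent's sibling; bounded in [0, 0.5]. All
  supplied pedigree records count in the denominator, affected or not
  (whether unknown-status relatives count is not specified anywhere; we
  count whatever the caller supplies).
- **Drinking** is PC1 of five drinking measures (drinks/drinking day,
  heavy drinking days/week, drinks/week, greatest drinks in a day,
  lifetime kilograms), each transformed by ln(1+x) — a plain log is
  undefined at 0, and several measures (e.g. heavy drinking days/week,
  range 0–7) include zeros — then z-scored. Drinking days/week is carried
  in the raw table but is not a PCA input.
- **Urgency** is PC1 of the positive/negative urgency subscales;
  **Alcohol seeking** is PC1 of the neutral and aversive
  alcohol-preference contrasts (work for alcohol − work for water).
- PCA is an eigendecomposition of the sample correlation matrix of the
  z-scored inputs, retaining eigenvalues > 1 (Kaiser), with a forced
  minimum of one component so each group always yields a composite.
  Retained loading vectors are oriented with positive mean loading, so
  higher composite scores mean more of the construct. All sample
  statistics use n−1 denominators, which keeps z-scores and correlation
  eigenvalues consistent.

All eight final columns are z-scored; a constant column is an error
naming the variable.

## The rPLS model

With z-scored domains C (n × E) and P (n × 8), each component maximizes
cov(C w_c, P w_p) = w_cᵀ M w_p with M = CᵀP/(n−1) under ‖w‖₂ = 1 and
per-domain L1 budgets λ ∈ [1, √|D|]. Design choices:

- **Variant**: symmetric PLS-SVD. The unregularized solution is the
  leading singular pair of M; latent scores are the plain projections
  Φ = C w_c, Ψ = P w_p.
- **Connectivity standardization**: edge columns are z-scored like
  phenotype columns. Centering-only is a defensible alternative; we chose
  the symmetric convention.
- **Regularization**: L1 ball on the unit L2 sphere, solved by
  alternating updates w ← S(Mv, δ)/‖·‖₂ where the soft threshold δ is
  found by binary search (60 bisections, evaluated in O(log E) per step
  via prefix sums over the sorted magnitudes). Convergence at max-change
  < 1e-8 or 500 iterations; a period-2 support oscillation is detected by
  comparing to the iterate two steps back and exits early with the
  non-convergence warning. Because the alternating fixed point can depend
  on the start when the top of the singular spectrum is nearly
  degenerate, the solver restarts from every singular pair within 10 % of
  σ₁ and keeps the best objective (on well-separated spectra this is a
  single start, so the cost is negligible).
- **Budget selection**: λ_C by grid search (≥ 50 log-spaced points over
  [1, √E]) for the component-1 nonzero fraction closest to 50 %, ties to
  the smaller (more strongly regularizing) budget; λ_P as the largest of
  ≥ 100 log-spaced points in [1, √8] keeping component-1 w_p to ≤ 3
  nonzeros. λ_C is selected with the phenotype domain unregularized,
  λ_P with λ_C fixed at its selected value; both are then held fixed for
  all components and all LOOCV folds.
- **Deflation**: projection deflation of each domain on its own scores,
  which guarantees cross-component score orthogonality (verified to 1e-6
  in tests).
- **Sign convention**: each component is oriented so cov(Φ, Ψ) ≥ 0 and
  the largest-|entry| of w_p is positive (lowest index on ties); this
  removes SVD sign indeterminacy for serialization and LOOCV alignment.

## Substrate inference

Per component, block contributions are Σ|w| over unique (upper-triangle)
edges of the five TNM blocks. The null model uniformly permutes the full
coefficient vector — zeros included, since sparsity is part of the
fitted object — over the allowed edge positions and recomputes block
sums; a block is significant iff its observed contribution strictly
exceeds the 99th percentile (linear interpolation) of its own ensemble
of 1000 permutations. No further multiplicity correction is applied.
Permutations are realized as the row-wise argsort order of an
(n_perm × E) uniform draw from `default_rng(seed)`, which is
distributionally identical to sequential shuffling and vectorizes well.

Signed strengths are per-region sums of positive and of negative row
coefficients. Top-region selection pools the R positive and R negative
entries (2R values) and takes the top ⌈0.05·2R⌉ by absolute value — the
convention under which 5 % of a 145-region profile is 15 entries; 5 % of
145 single entries would give ~7. The circuit summary reports each
significant block with sign = sign of its plain coefficient sum
(an exact zero is flagged "mixed") and, for between-network blocks, the
SN-origin direction the TNM imposes; within-network entries carry no
direction.

## LOOCV stability

n folds, each dropping one participant, re-standardizing both domains
within the fold (no leakage from the held-out row) and refitting at the
full-sample budgets (they are not re-selected per fold, matching the
single reported budget pair). Fold components are aligned to the
full-sample reference by flipping both weight vectors when
w_pᵀw_p(ref) < 0, falling back to the w_c overlap on an exact zero. A
fold whose re-standardization fails (e.g. a column going constant) is
recorded as an error without aborting the ensemble. Summaries: per-fold
phenotype coefficients (long format and box statistics), per-edge
coefficient SDs, and a per-component "stable" flag set when the dominant
phenotype set — the top-2 nonzero |coefficients|, the same rule that
names a component — matches the reference in ≥ 90 % of folds.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: n = 55
(31 female), 145 TNM regions split 47/44/54 across SN/FPN/DMN (the
published count is the 145 total; the split is a configurable placeholder
and real atlas counts take over when a lookup file is supplied).

Raw phenotypes match the cohort's published marginals: drinking
variables are lognormal on the ln(1+x) scale (moment-matched to the
printed means/SDs, truncated to the printed ranges) with a common
log-scale equicorrelation of 0.6375; urgency subscales are a bivariate
Gaussian at r = 0.50 discretized to the scale ranges; alcohol-preference
contrasts have r = 0.48 and are added to lognormal work-for-water
baselines to produce integer trial counts; pedigrees (2 parents, 4
grandparents, 0–2 siblings, each affected with p = 0.19) give FHD values
in [0, 0.5] with mean ≈ 0.07. The three correlation targets are the
unique values for which the PCA composites explain 75 % / 71 % / 74 %
of variance ((1+r)/2 for the pairs, (1+4r)/5 for the quintet);
cross-group phenotype correlations default to 0.

Connectomes are generated on the Fisher-z scale: per edge, a block
baseline (0.45 within-network, 0.15 between-network, giving the
within > between cohort profile), plus Σ_k β_k s_ik w*_ck for the planted
components, plus N(0, 0.15²) noise; FC = tanh(z) guarantees couplings in
(−1, 1) without clipping. Planted component k couples a sparse unit-norm
phenotype composite w*_pk (scores s_ik are the standardized phenotypes
projected on it) to a unit-norm edge pattern w*_ck supported on chosen
blocks; supports are disjoint across components so the planted circuits
are identifiable.

**Effect-size defaults.** With per-edge z-scoring, the cross-covariance
of pure noise has leading singular value ≈ (√E+√8)/√(n−1) ≈ 12.6 at
E = 8064, n = 55 — independent of the generator's noise SD — while a
planted covariance saturates at √m for support size m (the per-edge
z-scoring caps each edge's contribution). Recoverable planted structure
therefore requires supports of O(10³) edges and latent covariances well
above the noise floor; defaults are edge fractions (0.50, 0.35, 0.45)
and β = (12, 5.5, 3.2), giving planted covariances ≈ 41/28/19 with gaps
of ~3 standard deviations of the sample score-variance fluctuation.
These per-edge effects are deliberately stronger than typical empirical
brain–behavior correlations: the generator's purpose is a recovery
oracle that emulates the *stable, dominant* components the original
analysis reports, not a power study. Correspondingly, passing recovery
tests shows the pipeline is correct and well-calibrated, not that
comparable effects are detectable in arbitrary real cohorts.

The generator does not simulate BOLD time series (no temporal
autocorrelation), scanner/site effects, head-motion artifacts, or
spatially correlated noise; edges are conditionally independent given
the planted scores.

## Problem sizes in the test suite

Unit and property tests run on toy instances (6–24 regions). The
end-to-end checks use: full-size recovery (145 regions, n = 55) over 20
seeds; LOOCV at 35 regions (E = 463), n = 55; null calibration from 500
replicate null cohorts (21 regions, n = 20) with 500 permutations each —
at that permutation count the analytic exceedance rate of the
interpolated-percentile rule is (5−0.05)/501 ≈ 1.19 %, which is the rate
the binomial band is centered on; it approaches the nominal 1 % as the
permutation count grows. Monte-Carlo PCA calibrations use 200 replicates
at n = 55.

## Known limitations

- The alternating L1-constrained solver is not guaranteed globally
  optimal; the near-degenerate multi-start covers the observed failure
  mode on small instances, and the brute-force oracle test bounds the
  gap at 1e-3 on 4×3 problems.
- "Preserves 50 % of the solution" is read as 50 % of coefficients
  nonzero; an L1-mass reading would select different budgets.
- Budget-selection ties go to the stronger regularization, so a target
  fraction of 1.0 returns the smallest budget that already keeps every
  coefficient, not the grid maximum.
- The deflation variant is projection deflation; regression (Wold)
  deflation would give slightly different later components.
- Block significance inherits the discreteness of its permutation null;
  with all-equal |coefficients| no block can ever be significant.
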