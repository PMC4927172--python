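# Methods

This note documents the models, conventions and numerical choices
behind `waveconn`, in the order the pipeline applies them.

## Wavelet filters

The three orthogonal, compactly supported families are tabulated at
double precision: Daubechies Extremal Phase (`D`, lengths 2–20),
Daubechies Least Asymmetric / symlets (`LA`, 8–20) and Coiflets (`C`,
6, 12, 18, 24).  Coefficients follow the Percival–Walden convention —
the scaling filter `g` sums to √2, and the wavelet filter is the
quadrature mirror `h[l] = (−1)^l g[L−1−l]` — which makes the pyramid
recursions below exact.  Every pair is validated at construction
against unit energy, the sum rules, the QMF relation, orthogonality to
even shifts (all to 1e−10) and the spectral tiling
`|G(f)|² + |H(f)|² = 2`.

Vanishing moments are computed numerically as the largest p with
`Σ l^m h[l] = 0` for all m < p (tolerance 1e−8 on normalised moment
sums).  D and LA filters of length L have L/2 vanishing moments;
Coiflets of length 6K have 2K (C6 → 2, C12 → 4, …).  A sometimes-quoted
"p moments at length 2p for Coiflets" does not hold for the standard
tables and is not enforced.

## Transforms

Both pyramids use periodic (circular) boundary handling, which makes
the energy and reconstruction identities exact and is the convention of
the classical MODWT literature.  Boundary-influenced coefficients
(first `(2^j − 1)(L − 1)` at level j for the MODWT) are flagged in
`boundary_mask_per_scale`; they are *included* in downstream
correlation estimation by default, with exclusion available as a
configuration switch (`exclude_boundary`).  Decomposition depth is
J = 4 by default, parameterisable.

- **MODWT** — non-downsampled, with rescaled filters g/√2, h/√2.  It
  conserves energy (`Σ_j ‖W_j‖² + ‖V_J‖² = ‖x‖²`), is exactly
  equivariant under circular shifts, and is defined for any series
  length.
- **DWT** — orthonormal and downsampled.  Arbitrary lengths are
  handled by an odd-length carry rule: when an intermediate scaling
  sequence has odd length its last coefficient is set aside untouched
  and re-appended after the level's filtering, so at most one extra
  scaling coefficient is kept per level and the transform remains
  orthonormal for every N (at the study length N = 177 the coefficient
  counts are 88/44/22/11 + 12).
- For N a multiple of 2^J the two transforms are linked exactly by
  `W^DWT_j[t] = 2^{j/2} · W^MODWT_j[2^j (t+1) − 1]`; this identity is a
  standing test.
- **Cross-check**: PyWavelets' normalised stationary transform equals
  this MODWT conjugated by time reversal with a per-level circular
  advance of `(2^j − 1)(L/2 − 1)` samples; the suite asserts equality
  to 1e−8 under that documented mapping.

The additive multiresolution analysis (details `D_j` and smooth `S_J`,
`Σ_j D_j + S_J = x`) is defined for the MODWT, where each component has
length N; correlations can be computed on coefficients (default) or on
details.  No phase-alignment correction is applied before correlation:
a common circular shift of both sequences leaves their correlation
unchanged.

The scale→frequency mapping uses Nyquist = 1/(2·TR): scale j covers
`(fs/2^{j+1}, fs/2^j]` with fs = 1/TR.

## Connectivity

The wavelet correlation is the plain Pearson correlation of the
scale-j coefficient sequences of two regions — no bias-corrected
estimator is applied, matching common neuroimaging practice.  Regions
with zero-variance coefficients are flagged and their entries set to
NaN, never silently zeroed.  Partial correlation (standardised negative
inverse covariance) is provided for sensitivity analyses; it requires
more coefficient samples than regions or an explicit ridge penalty
(`ridge · mean(diag(cov))` added to the diagonal).  Wavelet coherence
is out of scope.

## Graph construction and metrics

Matrices are binarised by keeping `round(density · M)` of the
`M = n(n−1)/2` signed upper-triangular weights (half-away-from-zero
rounding; ties broken lexicographically by (i, j) so the edge set is
deterministic).  "Strongest" ranks most-positive first; "weakest" is
the complementary mode.  At 30% density a 90-region matrix keeps 1202
edges.

Metric conventions, where printed formulas in the source literature are
ambiguous or unnormalised:

- characteristic path length averages geodesics over ordered pairs of
  *distinct* vertices within each connected component, pooled with
  denominator `Σ_m n_m(n_m − 1)` (not `Σ n_m²`, which would deflate the
  average with zero self-distances);
- local efficiency of node i is the mean inverse geodesic *within the
  subgraph induced by its neighbours*; nodes of degree < 2 contribute 0
  to both clustering and local efficiency;
- modularity is the normalised `Q = (1/2l) Σ_ij (A_ij − k_i k_j / 2l)
  δ(c_i, c_j) ∈ [−1, 1]`;
- Q is reported as the mean over 20 seeded Louvain restarts by default
  (`max` and the restart count are configurable).

The consensus partition builds the module-allegiance matrix (fraction
of restart partitions placing each pair together), zeroes entries at or
below the mean allegiance of label-permuted copies of the same
partitions (the permutation null preserves community-size
distributions), re-clusters the thresholded matrix with weighted
Louvain, and iterates until all restarts agree (cap 20 iterations; the
null-model detail is an interpretation, as the source procedure is
under-specified).

## Statistical battery

- Length-variation statistic: `Σ_k |v_{k+1} − v_k|` over ascending
  filter lengths, per subject; MODWT and DWT are compared by a paired
  t-test across subjects (df = n−1).
- Two-sample tests are pooled-variance t (df = n_a + n_b − 2); with 29
  subjects per group the designs give df = 28 (paired) and 56
  (two-sample).
- The sign test is the exact two-sided binomial test on the signs of
  non-zero paired differences.
- The length effect is a one-way repeated-measures ANOVA with filter
  length as the within-subject factor: F on df (k−1, (k−1)(n−1)) — for
  29 subjects, (9, 252) for the 10 D lengths, (6, 168) for 7 LA
  lengths, (3, 84) for 4 C lengths.  No sphericity correction is
  applied by default.  The closed-form implementation is cross-checked
  against `statsmodels.stats.anova.AnovaRM` in the suite.
- Family-wise correction is Bonferroni (the most conservative standard
  choice).
- Group sensitivity is reported as −log10 p of per-cell two-sample
  t-tests.

## Classification

The reference protocol (a C5.0-style boosted tree classifier) is
reproduced with an openly specified equivalent: a C4.5-style learner —
axis-aligned binary splits on continuous features chosen by gain
ratio, pessimistic pruning via the Wilson upper confidence bound on
leaf error (CF = 0.25) — boosted by AdaBoost.M1 for 10 trials with
early stopping at weighted error 0 or ≥ 0.5.  Evaluation is stratified
6-fold cross-validation (stratification prevents single-class folds at
n = 58; plain random folds would occasionally degenerate), with the
2×2 confusion counts pooled across folds and the patient group as the
positive class.  One classifier is trained per (family, length) cell
at the analysis scale.

Note on permutation nulls at this sample size: when the features are
strongly predictive, a label permutation retains a hypergeometric
overlap with the true labels (sd ≈ 6.6% at n = 58), so pooled
null accuracies centre slightly above 0.5 (≈ 0.55 in expectation)
rather than exactly on it.  The chance-band checks in the suite account
for this.

## Synthetic cohort generator

Each region signal is `x_i = a·g + b·u_{m(i)} + c·e_i` with a global
factor g, module factor u_m and idiosyncratic noise e_i — all
independent unit-variance fractional Gaussian noise with common Hurst
exponent, sampled by exact circulant embedding of the fGn
autocovariance (order-2N Davies–Harte; the embedding spectrum is
checked and any negative rounding residue clipped).  With
`a² = ρ_between`, `a² + b² = ρ_within`, `a² + b² + c² = 1` the implied
region correlation matrix is exactly the block target; it is checked
for positive semi-definiteness before simulation.

Defaults mirror the reference study's dimensions and plausible
resting-state values: 29 subjects per group, 90 regions, 177
timepoints at TR = 2 s, H = 0.8 (fMRI-like long memory), 4 modules,
ρ_within = 0.4, ρ_between = 0.1, and a patient-group connectivity
elevation of +0.15 applied to both within- and between-module
correlation.  The broadband effect is exact in the target matrix; the
optional band-restricted variant swaps a fraction of each patient
region's scale-j idiosyncratic detail for a shared module detail, so
the elevation appears in that band only (with small leakage into
adjacent bands from filter overlap) and is described directionally in
the emitted ground truth.

What the generator does *not* emulate: hemodynamic response shape,
motion and physiological artifacts, spatial autocorrelation of the
parcellation, frequency-dependent cross-spectra (all factors share one
H, so true correlation is flat across scales), and between-subject
heterogeneity of connectivity strength beyond sampling noise.
Consequences worth keeping in mind: filter-length effects on the
*group-mean* correlation are far smaller here than on real fMRI, where
band-structured cross-spectra make length smoothing consequential; and
sign tests between same-length filter types can flag tiny but
consistent estimator differences that subject-level noise would swamp
in real data.  Passing the qualitative replication checks therefore
demonstrates correctness of the machinery and the direction of the
method effects, not their clinical effect sizes.

The Hurst estimator regresses log2 wavelet variance on log2 scale
(slope 2H − 2), using interior (non-boundary) coefficients when at
least 16 remain per scale, which also makes it exactly invariant to
polynomial trends annihilated by the filter's vanishing moments.

## Orchestration and reproducibility

`CohortStudy.fit()` executes decompose → connectivity → threshold →
metrics for every sweep cell, with the pyramid run once per subject
across all regions.  All stochastic stages (Louvain restarts, consensus
nulls, cross-validation folds, simulation) draw from named substreams
derived from the single global seed, so the entire sweep — including
cached re-runs keyed by a content hash of the configuration and data —
is bit-reproducible.  Problem sizes used by the acceptance script
(10 replicate cohorts for the method comparison, one cohort with graph
metrics at LA8/scale 2 for classification, 1000-replicate calibration
nulls in the suite) were chosen to give stable Monte-Carlo estimates at
desk scale.

## Known limitations

- The DWT odd-length carry rule is one deterministic realisation of
  "keep at most one extra scaling coefficient per level"; other
  toolkits may place the carried coefficient differently, changing
  individual coefficients but not the method-comparison conclusions.
- Partial correlation uses a simple ridge, not shrinkage estimators.
- The consensus permutation null is an interpretation (see above).
- Louvain is a heuristic: on tiny graphs its restarts attain the
  exhaustive modularity optimum in ≥ 90% of runs but not always.
- The classifier reproduces the observable protocol of the reference
  (gain-ratio boosted trees, 10 trials, 6-fold CV), not any proprietary
  refinements of C5.0 (rule sets, winnowing, costs).
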