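# Methods

## The comparability problem and the standardization model

A repeated-measures study observes each of *n* subjects at *T* ordered
sessions on *M* outcome measures with arbitrary native units. To compare
the measures' responsiveness to the manipulation, each measure's
observations are pooled over all subjects × sessions (the repeated-measures
structure is deliberately ignored at this step) and converted to standard
scores

    z_ijm = (X_ijm − X̄_m) / σ_m ,

where X̄_m and σ_m are the grand mean and grand SD of measure *m* over all
*n·T* pooled values. After the transform every measure has grand mean 0 and
SD 1, so between-session changes are expressed in pooled-SD units and are
directly comparable across measures.

**SD denominator.** σ_m uses the sample SD (denominator *n·T* − 1) by
default. The choice is immaterial for inference: any positive affine map
of a measure leaves every ANOVA F and p statistic unchanged; only the z
magnitudes rescale by √(nT/(nT−1)). The population-SD convention is
available via `ddof=0` throughout (`pool_and_standardize`, the QC check,
the `--sd-ddof` CLI flag).

**QC gate.** Affine invariance means the per-measure one-way
within-subject ANOVA must give identical F and p before and after
z-scoring. `qc_equivalence_check` asserts this to 1 × 10⁻⁹ — "identical"
is read as equal up to floating-point round-off — together with
|mean z| ≤ tol and |SD − 1| ≤ tol. The pipeline aborts on a QC failure
(downgradable to a warning), since a failure means the transform was
misapplied, not that the data are unusual.

## ANOVA decompositions

One-way (per measure, sessions as levels): SS_total = SS_subjects +
SS_session + SS_error, F = MS_session/MS_error on (k−1, (k−1)(n−1)) df.

Two-way (time × measure, fully within-subject): each effect is tested
against its own subject-crossed stratum — time against subject × time,
measure against subject × measure, the interaction against the three-way
residual. On z-scored input the measure main effect has SS ≡ 0 in exact
arithmetic (every measure's marginal mean is exactly the grand z mean, 0),
so F sits at floating-point-noise level and p = 1.000; the package treats
this forced null as an end-to-end correctness check.

**Sphericity.** The Greenhouse–Geisser estimate
ε̂ = (Σλ)² / ((k−1)Σλ²) over the eigenvalues λ of the double-centered level
covariance multiplies both df of the F reference distribution;
ε ∈ [1/(k−1), 1], with 1 iff sphericity holds. In the two-way design each
effect gets its own ε from its own contrast covariance: the time and
measure epsilons from the covariance of per-subject level means (collapsed
over the other factor), the interaction epsilon from the covariance of
(T−1)(M−1) Kronecker-product orthonormal contrast scores. Both corrected
and uncorrected p-values are always reported; downstream significance
decisions default to the corrected one. Mauchly's test and the Huynh–Feldt
correction are out of scope.

**Degenerate designs.** Zero error variance with a nonzero effect SS is
reported as F = +∞, p = 0 with a `degenerate` flag (and F = 0, p = 1 when
the effect SS is also zero) rather than raising, so batch runs over many
measures never abort on one pathological measure.

## Follow-up tests

**Polynomial trends.** Contrast coefficients for degrees 1..k−1 on equally
spaced sessions are built by Gram–Schmidt in exact rational arithmetic and
scaled to smallest integers (k = 4: (−3,−1,1,3), (1,−1,−1,1), (−1,3,−3,1)).
Each subject's contrast score L_i = Σ_j c_j x_ij is tested against 0 with a
one-sample t, df = n−1. The quadratic trend encodes the inverted-U
expectation: departure from baseline under stress, return at recovery.

**Pairwise comparisons.** For every session pair, a paired t-test on the
within-subject differences, two-sided, df = n−1, with *no* multiplicity
adjustment — the count of significant results across trends and pairs is
itself the sensitivity index, so alpha-protection would distort the very
quantity being measured.

**Error terms.** Contrasts and pairwise tests default to their own error
term (score/difference variance), the standard default of mainstream
statistics software for within-subject designs and robust to sphericity
violation; a pooled-error variant using the omnibus MS_error on
(k−1)(n−1) df is available (`error_term="pooled"`). With four sessions,
trend tests are reported up to the cubic, the highest order the design
supports.

## Sensitivity indices and ranking

Per measure: the one-way (GG-corrected) p; the trend p's; the pairwise
p's; the significance counts n_sig_contrasts ≤ k−1 and
n_sig_pairwise ≤ k(k−1)/2 computed at α regardless of the one-way outcome;
and |Δz|, the absolute difference of session-mean z between designated
pairs — by default baseline→stress1 (1,2) and baseline→stress2 (1,3).
Baseline→recovery is excluded by default because a return to baseline is
the expected pattern there and the comparison carries no information about
sensitivity.

Ranking is descending lexicographic on
(one-way significant, n_sig_contrasts + n_sig_pairwise, max |Δz| over the
stress pairs), with the key tuple recorded per measure so the ordering is
auditable; ties share a rank and ranking is invariant to input order. The
key is an explicit operationalization of three qualitative evidence
classes (omnibus significance, significance counts, standardized change
magnitudes); no formal test of "measure A is more sensitive than B" is
attempted, and `expected_direction` metadata affects report grouping only,
never any statistic.

## Synthetic data generator

The generator exists so every pipeline stage is testable without external
data. Model for subject *i*, session *j*, measure *m*:

    X_ijm = μ_m + σ_m · (dir_m · δ_jm + b_im + e_ijm),
    b_im ~ N(0, subject_sd²),  e_ijm ~ N(0, within_sd²).

Effects δ are injected in baseline-SD units, so simulated "true
sensitivity" is comparable across measures regardless of native scale —
the exact problem the z-score method addresses. In variance-normalized
mode (default) subject_sd² + within_sd² = 1, so σ_m is the total null SD
and the between-session correlation equals subject_sd² (compound symmetry;
sphericity holds and GG ε ≈ 1). Defaults: subject_sd² = within_sd² = 0.5,
a mid-range test–retest correlation of 0.5 for behavioural measures.

The default panel is 18 measures at their published baseline means/SDs —
four sustained-attention (PVT) metrics, seven mood (POMS) sub-scales,
three spatial-memory (match-to-sample) metrics, four salivary hormones —
with inverted-U trajectories δ = (0, d, d, d/4); the d/4 recovery value
encodes near-return to baseline. Per-class effect sizes are a package
choice reflecting the qualitative sensitivity ordering such a stressor is
expected to produce: d = 0.9 for mood sub-scales and cortisol, 0.45 for
response-timing measures and testosterone/NPY, 0.25 for premature
responses, 0.15 for accuracy counts, 0 for BDNF. Directions follow the
expected sign of a stress response (mood disturbance, cortisol, reaction
times up; vigor, accuracy, testosterone, NPY down).

What the generator does **not** emulate: hormone-distribution skewness
(e.g. a baseline SD exceeding the mean implies a skewed positive variable;
the default residuals are Gaussian, with an optional standardized
log-normal mode `residual_skew` for robustness checks), floor effects in
count measures, session-specific variance changes under stress (available
via `session_sd_scale`, which breaks sphericity and exercises the ε
machinery), dropout, and any real covariance between measures (measures
are generated independently given the session). Passing tests on this
generator therefore demonstrate the *procedure's* correctness and
calibration under a clean compound-symmetric Gaussian design, not
robustness to every pathology of real field data.

## Numerical and testing choices

- Exact integer arithmetic for contrast coefficients; eigenvalue route for
  ε with clamping to [1/(k−1), 1]; ε = 1 returned when the centered
  covariance is numerically zero (identical levels).
- An SS term is treated as null below 1e-12 × SS_total (degeneracy
  detection); SS conservation holds to 1e-9 relative in tests.
- All statistical routines are validated against independently coded
  brute-force oracles (explicit mean-loop SS formulas, a QR-contrast-basis
  ε formula, explicit score-vector t-tests) on 100 random designs to
  1e-8, and the one-way ANOVA additionally against pingouin.
- Type-I calibration is asserted on the *uncorrected* F test: under the
  compound-symmetric null generator sphericity holds exactly, so the
  uncorrected test is exactly calibrated, whereas the GG-corrected test is
  mildly conservative (ε̂ < 1 by sampling bias even under sphericity) —
  the suite checks the uncorrected rejection rate falls in the 99%
  binomial interval around α over 1000 replicates of the 34-subject
  design, and that the GG rate does not exceed it. Effect-recovery is
  checked at n = 100 over 50 replicates with graded effects
  d = 0/0.3/0.8: group median ranks must order correctly in ≥ 95% of
  replicates. These problem sizes keep the default suite fast while
  leaving the binomial/rank tolerances meaningful.
- The analysis path contains no randomness: identical inputs yield
  byte-identical reports. Simulation seeds enter only through the
  generator.

## Known limitations

- Balanced complete-case designs only; no between-subject factors, no
  imputation, no unbalanced estimation.
- Sessions are assumed equally spaced for trend contrasts.
- The ranking key is one defensible operationalization; measures tied on
  counts but differing in *which* trend is significant are ordered only by
  |Δz|.
- No permutation-based global test of whether the observed number of
  significant results exceeds chance.
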