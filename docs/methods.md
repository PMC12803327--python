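# Methods

## The estimand

Two observers view the same stimuli drawn from N ≥ 2 classes. Under signal
detection theory each observer, for a given pair of classes, condenses its
internal representation into a scalar decision variable (DV) and thresholds
it to choose. The estimand is the trial-by-trial Pearson correlation of the
two observers' *latent* DVs, conditional on class — a measure of whether
the two decision strategies waver on the same trials, deliberately
insensitive to overall accuracy, to decision bias, and to representational
variance along task-irrelevant directions.

## Decoding decision variables

For each unordered class pair (taken one at a time; the method is defined
pairwise and no multi-class decoder is involved):

1. Restrict to the pair's trials.
2. Reduce by PCA to k dimensions. Default
   k = min(50, n_pair_trials / 10, matrix rank), applied identically to
   both observers. LDA with many dimensions and few trials latches onto
   noise directions with spuriously good class separation, which
   deflates DV correlations between observers; the shared data-limited cap
   prevents this while keeping the comparison symmetric. k is exposed
   everywhere and must be equal for the two observers of a comparison.
3. Fit a two-class Fisher discriminant on the reduced trials:
   w ∝ S⁻¹(μ_b − μ_a) with S the pooled within-class covariance, w
   normalized to unit length. The offset places the midpoint of the
   projected class means at zero, so the two class means project
   symmetrically. When cond(S) > 1e6, S is blended with (trace(S)/k)·I at
   the Ledoit–Wolf analytic shrinkage intensity (floored at 1e-4);
   otherwise no regularization is applied.
4. The DV of a trial is its signed projection; the lexicographically later
   class projects positive on average.

PCA and LDA are fit per class pair on that pair's trials only, and the DV
decoder is fit **in-sample**: the DV describes the representation's
task-relevant axis rather than making a generalization claim.
Cross-validation enters only where choices or accuracies are reported:
binary choices come from stratified 5-fold cross-validated logistic
regression on the PCA-reduced trials (held-out probability vs 0.5, ties
toward the first class), and classification accuracy from the held-out LDA
sign rule.

Determinism: PCA component signs are fixed by making each component's
largest-magnitude loading positive, so all outputs are bit-stable across
reruns with the same seed.

## Raw DVC and the split-half correction

The raw DVC for a class pair is the Pearson correlation of the two decoded
DV series computed separately within each class. Conditioning on class
removes the shared class-separation component — pooled correlation would be
inflated by the fact that both observers separate the classes at all. A
pooled mode is exposed (`mode="pooled"`) but is not the default. The final
reported number is the arithmetic mean over all per-class values, two per
pair, N(N−1) values for N classes.

Decoded DVs carry measurement noise, which attenuates the correlation. Each
observer's features are split into two random disjoint halves and the DVs
are decoded from each half, giving DV_A1, DV_A2, DV_B1, DV_B2 and six
correlations per class. The corrected value is

    rho_corrected = r_cross / r_self,
    r_cross = (rho_A1B1 · rho_A1B2 · rho_A2B1 · rho_A2B2)^(1/4),
    r_self  = (rho_A1A2 · rho_B1B2)^(1/2).

If the noise in each decoded half is additive, symmetric and independent
across halves and observers, every cross correlation equals
rho·√(rel_A·rel_B) and each reliability equals rel, so the ratio is an
unbiased estimate of the latent rho. The package draws `n_splits = 10`
random splits by default and Fisher-z averages each of the six correlations
across splits *before* forming the ratio; averaging reduces split-sampling
variance, and `n_splits = 1` reproduces the single-split procedure.

Numerical choices:

- **Geometric-mean sign handling.** The fourth root is taken on the
  absolute product with the sign of the Fisher-z mean of the four cross
  correlations. This is continuous, reduces to the plain geometric mean
  when all signs agree, and sets a `cross_sign_disagreement` flag when they
  do not.
- **Reliability floor.** If either split-half reliability is ≤ 0.05 the
  ratio explodes; the corrected value is reported missing (NaN, flagged
  `low_reliability`) rather than clipped, the raw value is still reported,
  and missing values are excluded from means and counted in a coverage
  field.
- **Values above 1.** Corrected magnitudes above 1 arise from noise in the
  reliabilities; they are reported as computed with an `exceeds_unity` flag
  and never clipped, preserving the estimator's averaging properties.
- **Self-comparison.** The diagonal of an observer-by-observer matrix is
  defined as 1 rather than estimated. Note that comparing an observer with
  a literal copy of itself violates the independence assumption (the
  "two" observers share noise, so cross-half correlations exceed what the
  reliabilities predict); only the raw DVC (= 1 exactly) is meaningful
  there.
- **Raw DVC vs the attenuation relation.** The raw value is decoded from
  the *full* feature set, whose DV reliability is the Spearman–Brown
  step-up 2r/(1+r) of the split-half reliability r (a full set has twice
  the units of a half). Validation therefore checks
  raw ≈ rho·√(SB(rel₁)·SB(rel₂)); using the half reliabilities directly
  would misstate the prediction by up to ~0.1 at high rho.
- **Symmetry.** Split seeds derive from (run seed, observer id) and
  per-pair seeds from (run seed, pair label), so swapping the observer
  arguments or reordering pairs reproduces identical numbers exactly.

## Error consistency (Cohen's kappa) and its ceiling

For contrast, the package computes Cohen's kappa between two binary choice
series: kappa = (p_o − p_e)/(1 − p_e) with p_e from the product of each
observer's own marginal choice frequencies (Cohen's definition, not
Scott's pooled pi, since per-observer bias is exactly what is at issue).
When p_e = 1 (both observers constant and identical) kappa is defined as 0
with a degeneracy flag; a constant single rater is also flagged. Decision
bias is reported as the signed over-choice of the positive class relative
to its base rate.

Kappa is bounded above by a function of the two accuracies and the class
balance. Writing a_1y, a_2y for the per-class accuracies (which must
average, weighted by balance, to the observed overall accuracies), the
choice marginals — hence p_e — are fixed once the a_iy are fixed, and p_o
is maximized by the maximal coupling within each class,
p(agree | y) = 1 − |a_1y − a_2y|. The bound therefore reduces to an exact
two-variable maximization over the per-class accuracy allocations, solved
by a vectorized 401×401 grid over the feasible box followed by a
Nelder-Mead polish (xatol 1e-10). Identical accuracies admit perfect
agreement (bound 1) at any balance.

## The simulator

`simulate_latent_dvs` draws balanced trials from two classes; per trial the
two observers' DVs are bivariate normal with unit variances, correlation
rho, and class means ∓d′/2 (scalar or per-observer d′). A shared criterion
c converts DVs to choices (class b when DV > c); shifting c biases both
observers identically, lowering accuracy and kappa while leaving the DVs —
and hence DVC — untouched. Defaults rho = 0.5, d′ = 2, criteria in
[0, 1.5] produce that qualitative pattern at comfortable effect sizes and
are exposed in the config.

`embed_representation` maps a DV series into n_features dimensions:
x_t = dv_t·w + Σ_j z_tj·u_j + ε_t with a fixed unit signal axis w, optional
nuisance axes u_j orthogonalized against w (task-irrelevant trial variance
with standard-normal loadings z scaled by nuisance_sd), and i.i.d. Gaussian
feature noise ε of scale noise_sd. Axes derive from `signal_axis_seed` and
noise from the call's `seed`, so two observers embedded with different
seeds have independent noise — independent across feature-split halves by
construction, matching the correction's assumptions. For a unit signal
axis, each half's decoded-DV reliability is approximately
1/(1 + 2·noise_sd²), which is how validation targets reliabilities in
[0.3, 0.9].

What the simulator does *not* emulate: spiking/Poisson variability,
noise correlated across feature halves or between observers, non-Gaussian
class-conditional structure, and any image-computable front end. Passing
tests therefore certify the estimator under the independent-additive-noise
model it was derived for; behavior under correlated noise is not asserted
anywhere.

## Validation scale and observed behavior

The validation suite simulates at 1000–2000 trials per class with 64
features, 10 splits, and 9–20 replicates per condition — sizes at which the
Monte-Carlo standard error of a corrected-DVC mean is well below the 0.05
bands asserted. Under these conditions the corrected DVC recovers latent
rho ∈ {0.2, 0.5, 0.8} to within ±0.05 with reliabilities anywhere in
[0.3, 0.9]; the raw DVC follows the classical attenuation relation; the
corrected value stays flat (sd < 0.03) across criterion sweeps that move
kappa by > 0.15; and empirical kappa never exceeds the polytope bound.
`scripts/acceptance.py` recomputes all of these from scratch at run time.

## Data interfaces and limitations

Observer data enters as delimited-text matrices (full double precision;
reads use round-trip float parsing because split-half correlations are
sensitive to last-ulp rounding) with labels in a separate two-column file.
Trials align across observers by stimulus id string, never by row
position; classes reduced below 2 shared trials by alignment are dropped
with a warning. No loaders for neurophysiology or checkpoint formats are
provided — users export matrices themselves; if responses were recorded
over repeats, averaging (or not) across repeats is the user's choice and
happens before export.

Known limitations: the corrected estimator is a ratio of noisy correlations
and becomes volatile at low reliability (hence the floor and the missing
values rather than silent clipping); the correction assumes noise
independent across halves, so shared nuisance variance within an observer
inflates reliabilities relative to cross correlations and biases the
corrected value downward; and no confidence intervals are attached to DVC
values — the SEs reported in summaries are descriptive dispersions across
per-class values.
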