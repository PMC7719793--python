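# Methods

## Model

A trial is a real matrix X ∈ ℝ^{p×q} (for EEG: spatial filters × time
segments of band power) with a binary label y ∈ {−1, +1}. The classifier
is linear in the matrix, f(X) = tr(WᵀX) + b, and the plain support
matrix machine (SMM) fits (W, b) by

    min_{W,b}  ½ tr(WᵀW) + τ‖W‖* + C Σᵢ ξᵢ
    s.t.       yᵢ [tr(WᵀXᵢ) + b] ≥ 1 − ξᵢ,  ξᵢ ≥ 0,

the spectral elastic net (squared Frobenius plus nuclear norm) with the
hinge loss. The nuclear norm is the convex surrogate for rank: it keeps
W low-rank, so the classifier exploits correlated rows/columns of the
feature matrix instead of treating every entry independently, which is
the point of not vectorizing the trials.

The knowledge-leverage variant (KL-SMM) adds a model-parameter transfer
term λ tr[(W_s − W)ᵀ(W_s − W)] pulling W toward a *source subject's*
fitted matrix W_s. Only W_s crosses the subject boundary — never the
source recordings — so calibration data from other subjects improves a
new subject's classifier without sharing their raw EEG. λ = 0 recovers
the plain SMM exactly; λ → ∞ pins W to W_s.

## Optimization

The objective splits as F(W, b) + G(S) with S = W enforced by ADMM.
Each iteration:

1. **(W, b) step.** With S and the multiplier Λ fixed, the subproblem is
   an SVM-like QP. Its dual over the hinge multipliers α is
   max −½αᵀKα + Hᵀα subject to 0 ≤ α ≤ C and αᵀy = 0, with
   K_ij = yᵢyⱼ tr(XᵢᵀXⱼ)/(2λ+ρ+1) and
   hᵢ = 1 − yᵢ tr[(Λ+ρS+2λW_s)ᵀXᵢ]/(2λ+ρ+1). Then
   W = (Λ + ρS + 2λW_s + Σ αᵢyᵢXᵢ)/(2λ+ρ+1) in closed form, and b is
   averaged over on-margin support vectors.
2. **S step.** Singular value thresholding: S = (1/ρ)·D_τ[ρW − Λ],
   where D_τ soft-thresholds the singular values by τ. (The 1/ρ factor
   follows from the optimality condition of the prox objective
   τ‖S‖* + tr(ΛᵀS) + ρ/2‖S−W‖²_F; tests verify the subgradient
   condition directly.)
3. **Multiplier step.** Λ ← Λ + ρ(S − W).

The dual QP is solved by SMO-style pairwise coordinate ascent on the
maximal-KKT-violating pair, which preserves the single equality
constraint exactly and is warm-started across ADMM iterations. A
general-purpose SQP solver serves as an independent oracle in the test
suite only. KKT residuals are measured by minimizing the worst
stationarity violation over the equality multiplier μ (a convex
piecewise-linear 1-D problem, solved by ternary search).

An optional accelerated mode extrapolates (S, Λ) Nesterov-style with a
momentum scalar v and an η-triggered restart (η = 0.999): the momentum
step is rejected and reset whenever the combined residual fails to
shrink by the factor η. Both modes reach the same optimum (asserted to
1e−5 in the tests); plain ADMM is the default.

### Numerical choices

- ρ = 1, fixed across iterations; it only reweights the split, and
  keeping it fixed keeps the dual well-scaled.
- Convergence: ‖S − W‖_F ≤ 1e−4·max(1, ‖W‖_F) and relative objective
  change ≤ 1e−6, max 500 iterations. The oracle-equivalence tests
  (τ = 0 vs. linear SVM) tighten these to 1e−8/1e−12 because the τ = 0
  fixed point is approached geometrically at rate ρ/(ρ+1).
- b is averaged over {i : ε < αᵢ < C−ε}, ε = 1e−8·C (on-margin
  vectors, where yᵢ = tr(WᵀXᵢ) + b holds), falling back to the active
  set, then to all trials, with a logged warning.
- Gram matrices are nudged by 1e−10·I when the smallest eigenvalue
  estimate is negative (near-duplicate trials).
- W, S, Λ start at zero; b at 0; the optimizer contains no randomness.
- A decision value of exactly 0 predicts the positive class.
- Labels are mapped to {−1, +1} internally (first-seen order, recorded
  in the model); native ±1 labels keep their sign.

## Transfer workflow and λ selection

`fit_source` fits the plain SMM on the pooled source trials;
`fit_transfer` fits the KL-SMM on the first-k prefix of the target
calibration session using only W_s. λ is selected by stratified 5-fold
CV accuracy on the labeled target trials over the grid
{1e−4, 5e−4, …, 5e−1, 1e0}; fold count reduces to the smallest class
count, degrading to leave-one-out (with single-class training folds
skipped) when a class has a single trial — unavoidable at 8 labeled
trials with label noise. Ties break toward the smallest λ (least
reliance on the source). C lives on {1e−6 … 1e1} and τ on the 16-point
grid {1e−5 … 1e0}; CV ties break toward smaller C, then τ, then λ
(simplest model).

## Synthetic task generator

The generator emulates the cross-subject transfer setting: a unit-norm
rank-r matrix A Bᵀ is the source truth W_s*; the target truth is
normalize(W_s* + shift·E) with E a unit-norm Gaussian matrix. Trials
are i.i.d. standard Gaussian matrices labeled by sign(tr(W*ᵀX));
trials with |decision| < 0.1·margin_scale·‖W*‖_F are rejected
(enforcing a margin so 8-trial fits are meaningful), then labels flip
independently with probability `label_noise`. Defaults: p = q = 4,
rank 2, shift 0.2, noise 0.05, N_source = 200, 20 target calibration
trials (8/14/20-trial conditions take prefixes), 200 test trials. The
calibration draw additionally guarantees both classes within the
shortest protocol prefix (8 trials), as a real cued paradigm's balanced
cue order would.

Shift interpretation: at shift ≲ 0.8 the source is good enough that
trusting it fully never hurts within λ ≤ 1, so test accuracy rises
monotonically in λ. The rise-then-fall profile — transfer helps, then
source–target discrepancy dominates — appears once the perturbation is
comparable to the signal itself; shift = 1.0 is used as the
moderate-shift scenario in the tests and acceptance script.

The EEG generator plants an ERD-like effect: band-limited (8–30 Hz)
unit-variance noise sources mixed into channels by a random matrix,
with the variance of one latent source multiplied by `effect_size` in
class +1. It emulates the band-power contrast CSP exploits; it does not
model volume-conduction geometry, 1/f background spectra, artifacts, or
non-stationarity, so passing tests show the pipeline recovers a planted
variance contrast, not that it handles real recordings' nuisance
structure.

## Feature front-end

Zero-phase (forward–backward) 5th-order Butterworth band-pass at
8–30 Hz — the field-standard design for motor imagery; forward–backward application
squares the magnitude response and removes phase distortion of the
analysis window. CSP filters come from the generalized eigenproblem of
the two class-average trace-normalized covariances (shrunk toward the
identity by 1e−6), taking n/2 filters from each end of the eigenvalue
spectrum. Band power is the log-variance of each projected signal over
n_windows equal segments (default 6 filters × 5 segments; variance
floored at 1e−12 before the log). Feature matrices are z-scored
per entry with statistics frozen on the labeled training split
(toggleable, default on).

## Known limitations

- Binary classification only; multiclass and sparse variants are out of
  scope.
- The dual QP is dense O(N²) per sweep; fine for calibration-scale N
  (≤ a few hundred), not for large datasets.
- The ASVM baseline's transfer knob placement (scaling the source
  decision) is one of several forms in the literature; it is documented
  as the adopted convention.
- The rank-shrinkage and transfer-benefit guarantees are statistical
  (asserted over seed ensembles), not per-instance.
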