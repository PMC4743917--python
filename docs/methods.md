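# Methods

## The adaptive-ridge relaxation of L0 selection

Model selection with generalized information criteria minimises a penalized
contrast

    C(β) + λ ‖β‖₀,      C(β) = −2 log L(β) (up to constants),

which is NP-hard in the number of candidate regressors. `l0ridge` implements
the adaptive-ridge (AR) relaxation: starting from weights w⁽⁰⁾ = 1, iterate

    β⁽ᵏ⁾ = argmin_β  C(β) + (λ̃/2) Σⱼ wⱼ⁽ᵏ⁻¹⁾ βⱼ² ,
    wⱼ⁽ᵏ⁾ = (|βⱼ⁽ᵏ⁾|^γ + δ^γ)^((q−2)/γ) ,

so that each penalty summand wⱼβⱼ² tracks |βⱼ|^q. For the selection case
q = 0 (with γ = 2) the weight update is wⱼ = (βⱼ² + δ²)⁻¹ and the products
wⱼβⱼ² — the *selection indicators* — converge to 1 for retained and 0 for
dropped coordinates. Each step is a weighted ridge problem: closed-form for
Gaussian linear regression, a few damped Newton steps for Poisson
regression, and an O(n) tridiagonal recursion for least-squares
segmentation on successive differences.

Under an orthogonal design (XᵀX = nI, known σ²) the iteration decouples per
coordinate, and AR at penalty λ̃ < n/σ² selects exactly the coordinates an
L0 criterion at penalty λ = 4λ̃ selects; a surviving coordinate converges
(as δ → 0) to the stable root

    β̃ = sign(β̂) (|β̂| + √(β̂² − 4λ̃σ²/n)) / 2 ,

i.e. the AR estimate is shrunk relative to OLS, which is why criteria are
always evaluated at the ML *refit* on the selected support, never at the
shrunken coefficients. `l0_equivalent_penalty` exposes the λ/4 mapping
(BIC: λ̃ = log(n)/4, AIC: λ̃ = 1/2); `orthogonal_fixed_point` exposes the
closed-form limit and serves as the reference for the iterative solver.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 0 | penalty exponent; only q = 0 is exercised by the selection machinery (q is exposed up to 2 for completeness; q = 2 degenerates to plain ridge) |
| `delta` | 1e-5 | smoothing constant separating "zero" from "non-zero" effect sizes on standardized data; results are insensitive to its exact value in this range |
| `gamma` | 2 | sharpness of the thresholding approximation; 2 is markedly better than 1, larger values add little |
| `tol` | 1e-12 | sup-norm tolerance on successive selection indicators |
| `max_iter` | 5000 | outer-iteration cap; non-convergence warns and returns the last state |
| `init_weights` | 1 | initial weights; an entry of exactly 0 forces the coordinate into every model (never penalized, always selected) |
| `sigma2` | 1 | Gaussian error variance, treated as known; an explicit plug-in estimator (`linear.estimate_sigma2`) exists but is never applied silently |

### Stopping rule and tolerance

No canonical stopping rule exists for the AR iteration; convergence is
declared on the selection indicators (scale-free, converging to {0,1})
rather than on β. The tolerance is deliberately tight: coordinates near the
selection threshold traverse *metastable plateaus* where the per-iteration
indicator change drops to ~1e-9 while the coordinate is still en route from
the neighbourhood of 1 down to 0. A tolerance of 1e-8 freezes such
coordinates on the wrong side (measurably inflating both power and false
positives in the small-p benchmark); at 1e-12 the extracted supports are
identical to those at 1e-14 in every design exercised by the test suite,
so 1e-12 is taken as "converged". Typical iteration counts remain modest
(median ≈ 20, occasionally a few hundred for near-threshold coordinates).

A coordinate is selected when its indicator strictly exceeds 1/2 — the
midpoint of the limits, insensitive to δ; an indicator exactly at 1/2
(|β| = δ) is not selected. The AR map is not a contraction and its limit
can depend on w⁽⁰⁾; `ar_fit_restarts` re-runs from w⁽⁰⁾ ~ U(0.5, 1.5) draws
and keeps the best-scoring fit. The default remains the single all-ones
start.

## Regularization paths and criterion choice

Paths traverse a strictly *increasing* penalty grid (the reverse of the
LASSO convention), warm-starting each fit from the previous (β, w). Since
a coordinate whose indicator has collapsed carries an enormous weight, zeros
are absorbing along the path and supports shrink as the penalty grows. The
default grid is 100 log-spaced values on [1e-4·n/σ², n/σ²]; the upper end
exceeds every OLS coefficient's retention threshold, so paths end at the
empty model. The Poisson runners default to a 50-point grid on [1e-4·n, n]
— the inner Newton solver makes each point costlier and the selected
supports plateau over wide penalty ranges, so the coarser grid does not
change the chosen models appreciably.

A criterion (AIC, BIC, or mBIC(c) = −2 log L + |M| log(n p² c⁻²)) is then
minimised over the distinct supports on the path, each evaluated at its ML
refit. Ties prefer smaller supports, then larger penalties. When marginal
preselection reduces the candidate set before the path is fit, the mBIC
penalty keeps the *original* p: preselection is part of the search, not of
the model space.

Gaussian −2 log L is RSS/σ² (known variance, additive constants dropped);
an estimated-variance form n log(RSS/n) is selectable but never the
default, for consistency with the known-variance theory and the σ = 1
generators. Poisson −2 log L drops the Σ log yᵢ! constant. Criterion
*differences* are therefore meaningful within a run; absolute values carry
no likelihood constants.

## Numerical choices

* Weight updates use a two-branch log1p form, equal to the naive formula to
  ≥ 12 significant digits across |β| ∈ [1e-12, 1e6] (verified against a
  60-digit evaluation) but stable when |β| and δ differ by many orders of
  magnitude.
* Ridge systems are solved by Cholesky factorisation, never an explicit
  inverse. An unpenalized solve on a rank-deficient design raises; inside
  `ar_fit` with λ̃ = 0 a diagonal jitter of 1e-10·n is added with a warning.
* The Poisson Newton update is safeguarded by step-halving (accepted steps
  never decrease the penalized log-likelihood) and stops at a gradient
  sup-norm below 1e-8; the safeguard does not move the fixed point. The
  unpenalized refit on a support is solved by the same Newton routine.
* The segmentation smoother uses the forward recursion μᵢ = aᵢ + bᵢμᵢ₊₁
  (O(n), no factorisation), matching a dense tridiagonal solve to 1e-10.
  Segment means are refit as arithmetic means after breakpoint extraction,
  since the final μ retains shrinkage toward its neighbours.
* The exact segmentation reference is a k-segment dynamic program (prefix-sum
  costs, O(kmax·n²)) minimising RSS + λ·(#segments − 1) over at most kmax
  segments; ties prefer fewer segments, then leftmost segment starts.
* Breakpoints are 1-based indices i ("the mean changes between positions i
  and i+1"), equal to the 0-based start of the next segment, so
  `numpy.split(y, breakpoints)` recovers the segments; BED output converts
  to 0-based half-open intervals.

## What the generators emulate — and what they do not

The synthetic scenarios fix the study conditions used throughout the tests
and `scripts/acceptance.py`:

* **Small-p correlated designs** — n = 50, p = 15, five effects of 0.5,
  σ = 1, compound-symmetry or AR(1) correlation ρ ∈ [0, 0.8); AR run at
  λ̃ = log(n)/4 and compared with exhaustive all-subset BIC (known σ² = 1),
  500 replicates.
* **High-dimensional i.i.d. designs** — n = 100, p up to 10⁴, 24 effects
  drawn N(0, 0.5) (variance), σ = 1.
* **Path scenarios** — n = 300, Xᵢⱼ ~ N(0, 0.1²), non-zero effects
  N(0, 1.5²) on the first k coordinates; Gaussian with σ = 1 or Poisson
  counts with rate exp(Xβ), 200 replicates; for p = 500, marginal
  preselection to 75 columns precedes the path. The Gaussian noise standard
  deviation is an assumption (the generating family is described only as a
  standard linear model); it is consistent with the observed power levels.
* **Segmentation** — n = 500, breakpoints after positions 100/250/375,
  segment means (−0.3, 0.7, 1.5, 0.5), σ = 1, 200 replicates. The penalty
  rescaling λ̃ = λ/6 for λ = 2 log n is *calibrated*, not derived: the
  calibration score is the mean excess of the AR penalized criterion over
  the exact DP optimum, minimised over integer divisors of λ. The
  mean-excess curve is nearly flat between divisors 5 and 6, so the integer
  argmin can land on either depending on the replicate draw; the factor may
  also drift slowly upward with n. Each divisor is fit cold (all-ones
  weights): warm-starting across divisors carries absorbed zeros between
  penalties and systematically biases the calibration toward smaller
  divisors.

Gaussian designs are standardized (columns to squared norm n, response
centered — never rescaled, so a known σ² stays meaningful); Poisson designs
are left raw because centering covariates of an intercept-free log-linear
model changes the model.

The generators draw fully synthetic Gaussian/Poisson data. They do not
emulate discrete genotypes, linkage-disequilibrium block structure, missing
data, or population stratification, so passing benchmarks here demonstrates
the selector's statistical behaviour under the stated designs — not
performance on real GWAS matrices. (Forced-in covariates via zero initial
weights stand in for the usual adjustment-covariate workflow.)

Every replicate derives its RNG from `(seed, stream tag, replicate index)`,
so any subset of replicates reproduces independently, bitwise.

## Design choices on genuinely open points

* **Per-replicate "best method" ties** count for every tied method, so
  best-fractions can sum above 1 across methods.
* **FDR of an empty selection** is 0.
* **mBIC default c = 4**; c is exposed because larger values (e.g. 10) are
  reasonable when more causal regressors are expected.
* **Marginal screens**: Gaussian single-regressor t statistics; Poisson
  score statistics against the constant-rate null.
* **Stepwise baseline**: screen to the top-40 marginal regressors, greedy
  backward elimination to size 1 recording every visited model, then greedy
  forward addition over all p from the best visited model.
* The warm-start/cold-start consistency of path points is asserted only on
  orthogonal designs; on correlated designs the AR limit may legitimately
  depend on the start.

## Known limitations

* Only q = 0 is exercised end-to-end; q ∈ (0, 2) paths run but carry no
  selection semantics and no guarantees.
* The λ = 4λ̃ equivalence is exact only for orthogonal designs; under
  strong correlation or p ≫ n the path + criterion-minimisation route is
  the supported way to target a criterion.
* No cross-validated penalty choice, no elastic-net-style mixed penalties,
  no overdispersed or multinomial count models.
* `all_subset_select` is guarded at p ≤ 20 (2²⁰ models); beyond that use
  `stepwise_select` or the AR path.
* The segmentation loss is homoscedastic Gaussian; no 2-D segmentation.
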