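# Methods

## Model

Both models are Gaussian linear mixed models with partially crossed random
factors — subjects, sentences, and words — and *independent* (diagonal)
variance components: each random-effects block (a grouping factor crossed
with an intercept or one covariate) carries a single variance, no
correlation parameters. Estimation is maximum likelihood throughout (REML
is available on the fitter but unused by any default, because model
comparison across fixed-effect structures requires ML).

The location model predicts relative fixation location — character index
coded as `x/(ℓ+1) − ½`, so 0 is the word's middle character and −½ the
preceding space — from launch-site distance (log₂ characters), skipping of
word n−1 (treatment contrast, non-skipping reference), and length
(reciprocal), frequency (log₁₀(f+1)) and predictability (half-logit, after
boundary adjustment by the number of complete cloze protocols) of words
n−1 and n. Covariates are centered on the analysis sample; centering
constants are stored and reusable for new data. The full preset adds
skipping-by-covariate interactions (products of the 0/1 contrast and the
centered covariate, so main effects estimate non-skipping slopes) and
subject variance components for every main effect — 16 fixed effects and
11 variance components. A slim spec (mains + intercept components only) is
used in simulation loops for speed.

The duration model predicts log fixation duration of single first-pass
fixations from the length/frequency/predictability of words n−1, n, n+1
plus a location covariate entered as a second-order orthogonal polynomial.
The *link mode* selects that covariate: none, the observed location, the
first model's predictions x̂, its residuals ε̂, or both legs (each with its
own polynomial). The preset family's parameter counts are 23 / 25 / 27
(none / observed / both): fixed effects + variance components + the
residual variance.

## Fitting

For fixed relative standard deviations θ (one per block), β and σ² are
profiled out by penalized least squares: a sparse LU factorization of
A = Λ'Z'ZΛ + I and a dense Schur complement for the fixed effects. The
profiled deviance `log|A| + n(1 + log(2π r²/n))` is minimized over θ ≥ 0
with Powell's method (start 1, deviance tolerance 1e-12, parameter
tolerance 1e-8). Boundary estimates θ̂ = 0 are reported and flagged, never
refitted without the component, so parameter counts stay comparable across
a model family. Standard errors condition on θ̂ (the large-sample t ≈ z
argument); significance uses the two-tailed |t| ≥ 1.96 criterion. The
fitter agrees with lme4 (ML) to 1e-3 in log-likelihood and 1e-4 in fixed
effects on randomized crossed designs (tested).

Replicate loops (recovery, reliability, model-comparison sweeps) warm-start
θ from the previous replicate's solution; this changes only iteration
counts, not optima.

Degenerate inputs: with group-constant responses and no noise the ML
deviance is unbounded below (σ̂² → 0); the fitter returns the boundary
solution with near-zero residuals and group means absorbed by the
conditional modes, and linear algebra falls back to pseudo-inverses.

## Decomposition and linking

The decomposition is definitional: x̂ = fitted values (fixed + random
parts), ε̂ = y − x̂, so x̂ + ε̂ = x holds to machine precision and ε̂ sums
to ~0 whenever the model has an intercept. Orthogonal polynomial bases for
x̂ and ε̂ are built separately on each variable's realized values
(orthonormalized centered monomials), which makes linear and quadratic
coefficients separable; alongside the basis-scale estimates, the package
reports raw monomial-scale coefficients (via the stored basis-to-monomial
map) with delta-method standard errors, because basis-scale coefficients
are not comparable across data sets.

The joint fit treats the linked pair as one nonlinear model and ascends
the joint profiled log-likelihood by block coordinates from the sequential
solution: (a) re-optimize the first model's θ against model-1 likelihood
plus model-2 profiled likelihood at the current model-2 θ (the
decomposition, hence model 2's design, changes with every candidate θ);
(b) refit model 2 on the updated decomposition. Steps are accepted only on
improvement (tolerance 1e-6), so the joint log-likelihood can never fall
below the sequential plug-in value. A full simultaneous Laplace
optimization is out of scope; on linked-generated data the two agree
within a fraction of a standard error (tested), which is the point of the
comparison.

The reliability simulation is a parametric bootstrap of the *pair*: sample
a location vector from the first model's estimated distribution (random
effects and residuals redrawn; a conditional variant keeps the modes),
refit the first model, decompose, simulate log durations from the fitted
second model driven by the new decomposition (raw-scale link polynomials,
resampled random effects and noise), refit the second model, and record
the link coefficients. Resampling only the location side would decouple
the new residuals from the durations and trivially zero out every link
coefficient, so it cannot be what a stability check means. Seeds are
mandatory for every stochastic operation; there is no global default seed.

The covariate-removal experiment refits the pair with one location
covariate dropped from model 1. Its contribution then moves from x̂ to ε̂.
Note a subtlety the experiment exposes: if the dropped covariate also
appears in model 2's fixed effects (as the word properties do), model 2
re-absorbs the moved *linear* structure into its own coefficient and the
residual-path coefficients barely move; the clean demonstration drops a
covariate absent from model 2, such as launch-site distance.

## Synthetic corpus

The generator emulates the corpus the method was developed on: 273
subjects × 144 sentences of 5–11 words (mean 7.9, SD 1.4), log₁₀ word
frequency mean 2.1 / SD 1.3 (drawn from a Gamma with exactly those
moments, support ≥ 0), predictability mean 0.20 / SD 0.28 (moment-matched
Beta), 26.7 % skipping, and the published location/duration coefficient
estimates as generative fixed effects. Quantities no source states were
chosen once, for realism, and then frozen:

- word lengths: rounded log-normal (median ≈ 4.7 letters), clipped to 2–12;
- launch distance: log-normal (median ≈ e ≈ 2.7 characters, min 1), plus
  the skipped word's length + 1 on skipping saccades;
- an eligible word yields a single-fixation row with probability 0.6;
- oculomotor-error SD 0.15 relative units (≈ 1 character on a 6-letter
  word); location variance-component SDs 0.03 (subject) and 0.01
  (sentence, word) — item components several times smaller than the
  subject one, as the source material states qualitatively;
- duration side: residual SD 0.30 log-ms, component SDs 0.15 / 0.03 / 0.05,
  intercept 5.303 log-ms (≈ 200 ms);
- raw-scale link coefficients (linear, quadratic): (−0.55, +1.0) on x̂ and
  (+0.25, −0.9) on ε̂ — the sign dissociation of the quadratics encodes
  the OVP-versus-IOVP pattern the linked analysis is designed to separate.

The location model is generated as the *unbounded* Gaussian it is written
as, so simulated character indices are fractional and occasionally fall
outside the word (about 8 % at desk scale). This is deliberate: clamping
locations onto the word boundary attenuates the first model's coefficients
by ~6 % and inflates the prediction-leg link coefficients by ~13 %, and
dropping such rows (a mislocated-fixation emulation) selects on the
residual and biases even more — both measured before the generator was
frozen. Real corpora would assign those fixations to neighboring words;
the strict location-bounds check therefore remains the default for
recorded-data dialects (`strict_location=True`) and is relaxed only for
simulator output. Consequently a green recovery test establishes that the
two-stage estimator recovers the generative link structure *when the
first model is correctly specified*; it does not establish robustness to
boundary truncation, covariate cross-correlations (word properties are
drawn independently), or any oculomotor dynamics (no saccade-program
simulation).

Known residual limitation: even in this self-consistent world the
two-stage estimator carries a small generated-regressor bias
(BLUP shrinkage makes x̂ slightly flatter and ε̂ slightly smaller than
their true counterparts), measured at roughly 0.5–2 % of the coefficient
values — i.e. about 0.1–0.2 of the Monte-Carlo SD — at the 40 × 60 desk
scale, and shrinking with group sizes. The recovery test's bias bound sits
exactly at this magnitude, so it is tight by design rather than
comfortable.

## Numerical choices

- Orthogonal polynomial bases: QR of the centered monomial matrix, signs
  fixed so the linear column increases; a rank error is raised below
  degree+1 distinct values.
- Deviance evaluations reuse precomputed cross-products (Z'Z, Z'X, Z'y,
  X'X); one evaluation costs one sparse factorization.
- r² is floored at the smallest positive float to keep the deviance finite
  at degenerate optima; Schur systems fall back to pseudo-inverse when
  singular.
- Ties in the model-comparison report are broken by parameter count; rows
  sort by AIC ascending.
- Effect-curve confidence bands use only the fixed-effects covariance of
  the involved coefficients (no variance-component uncertainty) — standard
  practice, stated limitation.
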