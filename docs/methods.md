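# Methods

## Model

Let blocks $X^{(1)}, \dots, X^{(B)}$ be feature-by-sample matrices over a
shared sample universe, each with its own set of *assayed* samples, and
let $(t_i, \delta_i)$ be a right-censored survival outcome for every
sample. The model assumes a proportional-hazards structure
$\lambda(t \mid x) = \lambda_0(t)\, e^{\eta(x)}$ in which the log relative
hazard $\eta$ is linear in a small set of latent components, and each
component is linear in the standardized features of one block.

### Per-block components (PLS Cox)

For block $b$ with $D_b$ features, standardized to zero mean and unit
variance on its assayed training samples, components $t_1, \dots, t_K$
are extracted sequentially. At step $h$, each feature's weight is its
coefficient in a Cox model containing that feature together with
$t_1, \dots, t_{h-1}$ as free covariates; the weight vector is normalized
to unit length, the component is the corresponding score, and the block
is deflated by regression on the new component. This is the
score-based construction of survival PLS: the first direction is driven
by univariate Cox associations, later directions by associations residual
to the components already found. Through the deflation identity
$W^\* = W (P^\top W)^{-1}$ the K scores remain an exact linear map of the
standardized features, which the rest of the pipeline relies on.

$K = \max(2, \lceil \log_{10} D_b \rceil)$ by default. The rule grows
logarithmically so that narrow clinical tables contribute 2 components
and genome-wide blocks of a few thousand features contribute 4; for a
typical seven-platform study with block widths
{3, 75, 133, 1064, 1329, 1690, 2291} it yields 23 components in total.
It is overridable per block (`PlasmaConfig.n_components`).

On top of the component-level Cox model, two convenience models are kept
per block: a *risk model* (Cox on the continuous risk) and a *split
model* (Cox on the median-dichotomized risk), used for per-block
Kaplan–Meier diagnostics.

### Cross-extension and averaging

For every ordered pair (target, source), a multi-response PLS linear
regression learns the target's component scores from the source's
features, trained on the samples assayed on both and using
$K = \max(2, \lceil \log_{10} D_{source} \rceil)$ components. Pairs whose
intersection has fewer than `min_intersection` (default 10) samples are
skipped. The self pair is included, so each component has one prediction
per block; it is represented by the block's own exact feature-to-component
affine map rather than a refitted PLS. This choice is deliberate: a
fitted K-component PLS regression of a block's components on its own
features does *not* in general reproduce them exactly (only a full-rank
fit, equivalent to least squares, would), whereas the stored map is exact
by construction and is also the natural reading of "one prediction per
source" — a block predicting its own components should simply use them.

Component predictions are averaged unweighted over every source block on
which a sample is assayed and whose pair model exists. A sample assayed
anywhere therefore receives every component; precision weighting is
intentionally not used.

### Final model and risk groups

A Cox model is fitted on all averaged components and pruned by backward
elimination on the AIC ($-2\log PL + 2k$): at each round the removal
that lowers the AIC most is applied, down to the null model if warranted;
AIC ties drop the earliest column, making the procedure deterministic
given component order. Collinear components (a component nearly linear in
others, as happens when several blocks express the same factor) are
eliminated this way. The final linear predictor, centered at the training
component means, is the integrated risk; the training median is the
stored cutpoint, with ties assigned to the low-risk group.

### Composite weights

Both layers are linear, so for a fully assayed sample
$\eta(x) = \sum_b x_b^\top w_b + c$ with
$w_b = \sum_{c\,\text{retained}} \frac{\beta_c}{S_c}\, a^{(c \leftarrow b)}$,
where $\beta_c$ is the final Cox coefficient, $S_c$ the number of
averaged sources for that component's target, and $a^{(c\leftarrow b)}$
the raw-scale affine coefficients of the (target ← b) extension. The
identity `risk = Σ x·w + c` is verified to 1e-8 in the tests. Weights are
z-scored within each block for cross-platform display; the top fraction
by |standardized weight| (boundary ties included) is exported for
enrichment upload. The weights describe the all-sources regime; when a
sample misses blocks its effective weights differ, which is a known
limitation of this interpretation.

## Survival machinery

Cox models maximize the Efron-tied partial likelihood by Newton–Raphson
(tolerance 1e-9 on the log-likelihood change, at most 50 iterations, step
halving). With distinct event times the Efron and Breslow likelihoods
coincide and a fully vectorized cumulative-sum path is used; this matters
because the PLS Cox construction performs one small adjusted fit per
feature per component. Monotone likelihood (separation) is handled by
capping coefficients at |15| and flagging the model rather than failing;
zero-variance predictors are dropped with a warning; singular information
matrices fall back to the pseudo-inverse. Kaplan–Meier estimation,
log-rank testing and Harrell's concordance delegate to lifelines;
brute-force risk-set oracles in the test suite verify all of them, and
the Cox fitter is cross-checked against an independent implementation.

## Imputation

PLS prediction requires complete feature vectors, so missing cells within
assayed samples are imputed per feature: by the mean when a feature has
more than five distinct observed values, otherwise by the mode (smallest
value on ties) — or by sampling uniformly from the feature's observed
values (seeded). Whole-sample missingness is never imputed; it is what
the extension machinery is for. The imputer choice has little downstream
effect in this setting, which is why only these two simple methods are
offered. Imputation operates along the feature axis (across samples),
matching the feature-major layout of the matrices.

## Synthetic studies

The generator draws latent factors $Z \sim N(0, I)$; continuous blocks
are $L Z + \varepsilon$ with sparse Gaussian loadings (default 30%
nonzero, unit scale) and noise sd 1.0; binary mutation-like blocks
threshold the same construction at a per-feature quantile to hit a target
positivity rate (default 10%). Event times are exponential with hazard
$\lambda_0 e^{\gamma^\top Z}$ (a Weibull shape is exposed as an option);
censoring is an independent exponential whose rate is solved numerically
so the expected censored fraction matches the target. Per-block dropout
is independent Bernoulli with a re-draw guard so every sample stays
assayed somewhere; low-level missing cells are then injected at a small
rate (default 2%).

The reference design — three continuous blocks of 50/200/500 features,
two factors with log hazard-ratio effects 1.0 each, 500 samples split
60/40, 30% dropout, 20% censoring — is the study size used throughout
the end-to-end tests and the acceptance script. What the generator does
*not* emulate: realistic feature–feature correlation (LD, co-methylation),
batch effects, non-proportional hazards, or informative censoring and
informative (outcome-dependent) platform dropout. Passing tests therefore
demonstrate the mechanics and statistical behaviour of the pipeline under
its own assumptions, not performance on real cohorts.

## Numerical choices and edge cases

- Feature standardization divides by the training sd (ddof=1); constant
  features get scale 1 and hence weight 0 everywhere.
- PLS component extraction stops early when the remaining covariance is
  numerically zero; requested K above the rank bound min(n−1, p) is
  clipped with a warning.
- PLS weight sign is fixed (largest-magnitude entry positive) for
  reproducibility.
- Risk ties at the cutpoint go to the low-risk group.
- The train/test splitter never re-draws silently: an imbalanced split
  (log-rank p < 0.05) is reported, and re-splitting with seed+1 happens
  only under an explicit flag.
- Every stochastic step (sampling imputer, splitter, generator) takes an
  explicit seed; identical seeds and inputs give bit-identical model
  bundles.

## Known limitations

- The component-count rule and the score-based PLS Cox variant are this
  package's normative choices among several reasonable reconstructions
  of survival PLS; both are overridable or replaceable at the module
  surface.
- Stepwise AIC selection inherits the usual caveats of stepwise
  procedures (no selection-adjusted inference on the retained
  coefficients).
- Composite weights are defined for the fully-assayed averaging regime
  only.
- No time-varying covariates, stratification, frailty, or competing
  risks.
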