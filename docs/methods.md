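# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `phylosyndrome`.

## Trait coding

Observers score up to three salient body colours per species from a fixed
11-colour vocabulary (brown, green, white, red, orange, yellow, black,
grey, pink, blue, purple) and the presence of five pattern elements
(stripe, band, spot, stipple, blotch).  Colour sets are expanded into
single-colour traits plus all unordered two-colour composites — a set of k
colours yields k + k(k−1)/2 traits (at most 6) — because colour pairs can
carry signals their components do not.  Three-colour combinations are
never expanded: the full triple/dual/single factorization produces far too
many levels to test meaningfully.  Composite names are canonical
(lexicographic join, `black/yellow` never `yellow/black`) so column
identity is stable across observers and bootstrap replicates; by
construction a pair column equals the logical AND of its two component
columns in every species.

Colour columns present in fewer than `min_occurrences` species (default 5;
the inequality is strict, so a column summing to exactly 5 survives) are
excluded and reported.  The filter's scope is colour traits only by
default — pattern and ecology columns are retained regardless — with a
switch to widen it.  Ecology categoricals (diet breadth: mono-, oligo-,
polyphagous; tissue: reproductive, interior, leaves, other; growth form:
forb, graminoid, woody) are one-hot expanded so every model is
binary ~ binary.  Growth form is a non-exclusive set: a species feeding on
both forbs and woody plants carries a 1 in both columns.  Species missing
ecology records are excluded from ecology models only, not from the
colour/pattern analysis.

## Phylogenetic logistic regression

For a binary tip trait y with design matrix X (intercept + one or more
binary/continuous predictors):

* margins: y_i ~ Bernoulli(μ_i), logit(μ_i) = x_i'β;
* dependence: working correlation R(α)_ij = exp(−α d_ij), the stationary
  correlation of a two-state switching process on the tree, with d the
  patristic distance on the height-normalized tree.  α ≥ 0 is therefore in
  units of inverse tree height: α → ∞ is tip independence, small α strong
  shared history.

β solves the Firth-penalized estimating equations

    U*(β) = X' W^{1/2} R^{-1} W^{-1/2} (y − μ) + X' (q ∘ (1/2 − μ)) = 0,

with W = diag(μ(1−μ)) and q = diag(W^{1/2} R^{-1} W^{1/2} X F^{-1} X'),
F = X' W^{1/2} R^{-1} W^{1/2} X.  The penalty term is the exact gradient of
the Jeffreys-prior penalty ½ log det F(β); at R = I it reduces to the
textbook Firth score X'(y − μ + h(1/2 − μ)).  Two properties motivated
this exact form rather than a whitened-space leverage heuristic: it keeps
estimates finite under complete separation, and it is invariant to tip
ordering (leverages computed after Cholesky whitening are not, because the
factor depends on row order).

The update is damped Newton iteration (step clipped at 5 log-odds units,
convergence at 1e-8 on the coefficient step, 50 iterations), initialized
at the ordinary Firth-logistic solution, so fits are deterministic without
seeds.

### Estimating the signal parameter

α is a working-correlation parameter, estimated by residual moment
matching: the standardized residuals r_i = (y_i − μ_i)/√(μ_i(1−μ_i)) have
unit variance, and E[r_i r_j] is the binary-scale between-tip correlation.
α minimizes

    Σ_{i≠j} (r_i r_j − exp(−α d_ij))²

over a bounded log range (default [1e-3, 1e3]; hitting a bound sets a
reported flag, never a silent clamp), alternating with the β update until
the change in log α is below 1e-5 (at most 100 rounds).  The scalar
minimization is Brent's bounded method on log α with the interval
endpoints checked explicitly.

We first implemented profiling α by a penalized Gaussian working
likelihood and rejected it: for 0/1 data the Gaussian quadratic form is on
the wrong scale, and as R(α) approaches singularity (small α) the
criterion can reward configurations whose working Fisher information — and
hence the Wald standard errors — collapse by orders of magnitude,
producing wholesale false positives.  Matching α to the *observed*
binary-scale residual correlation keeps the model-based covariance F^{-1}
consistent with the realized correlation of y, so model-based and sandwich
covariances approximately coincide.  Monte-Carlo checks in the test suite
confirm the calibration: Wald type-I error 0.02–0.08 at nominal 0.05, and
|bias| < 0.1 for a planted log-odds effect of 1.5 on 300-tip trees.

Standard errors are √diag(F^{-1}) at the solution; p-values are two-sided
normal (Wald).  Parametric-bootstrap intervals are out of scope — the
pipeline consumes p-values only.

Degenerate inputs: a constant response raises "degenerate response"; a
rank-deficient design raises; non-convergence returns partial results with
`converged=False`.  Cholesky factorizations of R get an escalating
diagonal jitter (1e-10 → 1e-6) if needed; patristic distances of exactly
zero between distinct tips (zero-length terminal branches are common in
GenBank-derived trees) are set to 2·ε·T with ε = 1e-8 so R stays
non-singular.

### Batched fitting

The observer bootstrap refits tens of thousands of intercept + one-predictor
models on the same tree.  These share the Cholesky factors of R(α) on a
fixed 13-point log-spaced α grid, and the Newton iterations vectorize
across models.  The batched path mirrors the single-fit alternation: solve
all models at independence, select each model's grid α by the moment loss,
re-solve the models grouped by selected grid point, and repeat the
selection once with updated residuals.  The single-fit estimator
(`PhyloLogisticRegression`, a scikit-learn style estimator) uses the
continuous optimizer and is used for all full-data fits; tests pin the
batched path to the per-model solver at fixed α to 1e-5.

## Association pipeline

Models are bivariate: coloration (single or pair colour) as response with
a pattern or ecology trait as predictor, plus pattern ~ ecology.  The
direction convention (coloration responds) is a package decision, settable
to the reverse for sensitivity analysis.  Each model belongs to one of two
hypothesis families — *a priori* (literature-predicted pairs, supplied as
configuration) or exploratory — and Benjamini–Hochberg FDR is applied
within each family separately, over whatever models ran and converged in
that replicate.

The observer bootstrap draws, per replicate, one observer's colour/pattern
scores per species (uniformly, from seeded per-replicate substreams of a
master seed, so replicates are independently reproducible).  The trait
universe is frozen from the pooled data — a trait is present in the pooled
matrix if any observer scored it — before resampling, and the rarity
filter is not re-applied per replicate, so the model list is identical
across replicates (a flag enables per-replicate re-filtering).  A
replicate counts toward a pair's support only if the pair is
FDR-significant at the configured level (default 0.05) *and* its
coefficient sign matches the full-data fit: signed associations should not
accumulate support from replicates of opposite sign.  Support is the
significant fraction among converged replicates; non-converged replicate
fits are excluded from the denominator and a pair with under 50% converged
replicates is flagged unreliable.  A pair is **supported** when support ≥
the consensus threshold (default 0.90, inclusive).

Outputs: an edge list of supported associations (response, predictor,
sign, support, family), a node-link graph JSON (colours drawn as circles,
patterns as squares, ecology as diamonds), and a full JSON of all fits.

## Synthetic data

* **Trees**: Yule or birth–death via dendropy, conditioned on the tip
  count; because that process stops at the instant of the n-th split
  (leaving an exact zero-length cherry), all terminal branches are
  extended by the waiting time to the next event, keeping the tree
  ultrametric with strictly positive terminal branches.  Height is
  normalized to 1 before any trait simulation so the generating and
  fitted signal parameters share units.
* **Predictors** (host-use traits): either a clade block (one internal
  clade spanning 30–70% of tips set to 1; falls back to the Markov switch
  with a warning if no such clade exists) or a two-state Markov switch
  with configurable rate (default 2.0 per unit height, giving realistic
  clustering of host use at ~50% prevalence).
* **Responses**: a latent-Gaussian threshold scheme — z ~ MVN(0, R(α_true))
  on the patristic distances, y_i = 1 iff Φ(z_i) < logistic(β₀ + β₁x_i).
  Margins are *exactly* logistic under any covariate (Φ(z_i) is marginally
  uniform), while the binary-scale correlation decays with distance but
  does not exactly equal exp(−α_true·d) — a deliberate mismatch with the
  fitted working correlation, so recovery tests exercise realistic model
  misspecification.  An exact switching-process generator (whose binary
  correlation is exactly exp(−rate·d)) is included for pure
  signal-parameter recovery checks.
* **Observers**: two observers each reproduce the true colour/pattern sets
  with every trait independently toggled at the disagreement rate (default
  0.10); colour toggles respect the three-colour cap by random eviction.
  Two observers then disagree on a trait with probability 2r(1−r), which
  the tests verify empirically.

Default generator settings are the package's definition of the study
conditions: 300 tips, planted effect β₁ = 1.5 (2.0 in the pipeline power
checks), observer disagreement 0.10, and signal α_true = 4.0.  The signal
default deserves a note: on a height-1 tree, α = 4 means trait correlation
halves by ~0.17 tree heights and is ~0.02 across the full tree — moderate
conservation consistent with colour strategies that re-evolve repeatedly
across clades.  Much smaller α (≈1) would imply correlation ≈0.4 between
lineages separated by half the tree; in that regime the effective sample
size of a 300-tip study is a few dozen and *any* marginal estimator of a
log-odds effect carries substantial small-sample bias — a property of the
data, not of a particular fitting algorithm.

What the generator does not emulate: polymorphism (one morph per
species), within-species variation in ecology, non-ultrametric trees,
observer biases that are systematic rather than independent per trait, and
the empirical trait frequencies of any real dataset.  Passing tests
therefore demonstrate correctness of the machinery and calibration under
controlled misspecification, not fidelity to any particular fauna.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run, on one CPU, with: 200
replicates of 300-tip trees for bias and type-I error; 50 (tests) or 20
(script) null datasets of 100 tips × 20 trait pairs × 100 bootstrap
replicates for consensus calibration; 10 (tests) or 10 (script) planted
datasets of 300 tips for power; 25 end-to-end recovery runs.  These sizes
give Monte-Carlo standard errors comfortably inside the asserted margins.

## Known limitations

* The working correlation family exp(−α·d) is single-parameter; traits
  whose correlation decays non-exponentially are approximated, not
  modelled.
* Wald inference relies on the model-based information; for very rare
  traits (prevalence ≪ 5/n) the normal approximation degrades — the rarity
  filter exists partly for this reason.
* The moment estimator of α is noisy on small trees (n ≲ 50); the
  regression remains valid but α itself should not be over-interpreted.
* The batched bootstrap fitter profiles α on a 13-point grid rather than
  continuously; support fractions are insensitive to this in testing, but
  per-replicate α values are grid-quantized.
* FDR families are configuration data; with the pair-to-family mapping
  unspecified, all pairs default to the exploratory family.
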