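# Methods

`mkelm` implements a family of closed-form neural classifiers for
tabular data built from three ingredients: extreme-learning-machine
(ELM) random feature maps, reduced (reference-point) kernel similarity
maps, and ridge regression. On top of the classifiers sits a
cost-sensitive decision layer that converts scores to class posteriors
and picks the class of minimum expected misclassification cost. This
note records the model, its assumptions, the parameters that matter,
the numerical choices, and the places where the design was genuinely
open and a choice had to be made.

## Core model

**ELM / ridge core.** A random hidden layer `h(x) = σ(Wx + b)` with
fixed i.i.d. weights maps inputs to L features; output weights β solve

    min ‖Hβ − T‖²_F + (1/C)‖β‖²_F,

in closed form, either through the N×N sample Gram matrix
`β = Hᵀ(I/C + HHᵀ)⁻¹T` or the p×p feature Gram matrix
`β = (I/C + HᵀH)⁻¹HᵀT`. The two are algebraically identical; the
solver inverts whichever is smaller (`gram_n` iff N < p). The
regularizer enters as `I/C` added to the Gram matrix, so **larger C
means weaker shrinkage**.

**Reduced kernel autoencoders.** A kernel autoencoder reconstructs X
from its similarity representation. The full variant (`kelm_ae`) solves
`Γ = (I/C + Ω)⁻¹X` with Ω the N×N kernel matrix — O(N³). The reduced
variant (`rkelm_ae`) computes similarities only against N̂ randomly
chosen reference rows, giving a rectangular Ω̂ (N×N̂) and an N̂×N̂
solve. The reduced *expectation*-kernel variant (`rekelm_ae`) first
expands the input through a random layer of L₁ nodes with N(0,1)
weights and sigmoid activation, then applies the kernel to the mapped
rows; applying a standard kernel to randomly mapped inputs is a
finite-sample realization of an expectation kernel, combining random
and similarity mapping in one encoder. Sizing is expressed through two
ratios: the expansion ratio R1 = L₁/d (default 10) and the compression
ratio R2 = N̂/N, with N̂ = round(R2·N) clamped to [1, N].

**Kernels.** Four families are fused: Gaussian RBF
`exp(−‖x−r‖²/2σ²)`, squared Euclidean distance, Manhattan distance,
and cosine similarity. The distance families are used directly as
similarity features without conversion to a decaying kernel; the ridge
solve downstream is indifferent to monotone orientation. The cosine
family ships in two variants because the source formula divides by the
product of *squared* norms, which is unusual and possibly a typo; the
printed form is the default and the standard form is available as
`cosine_standard`. RBF σ defaults to the median pairwise Euclidean
distance of the rows the kernel is applied to (raw X for `rkelm_ae`,
the mapped H for `rekelm_ae`), the standard median heuristic.

**MKP — parallel fusion.** One REKELM-AE per kernel, all fitted on the
input with identical sizing; the classifier consumes the concatenation
of the activated read-outs `σ(XΓᵢᵀ)`, in kernel order. Two design
points deserve justification:

* *Activated read-out.* The raw read-out `XΓᵀ` is linear in X, so a
  concatenation of raw read-outs is a rank-≤d linear map of X and the
  choice of kernels cannot contribute any information the classifier
  could not get from X itself — measured on the synthetic benchmark,
  the 4-kernel model was then *worse* than every single-kernel model,
  inverting the architecture's central claim. Passing the read-out
  through the hidden activation (the universal convention in
  multilayer-ELM stacks) makes each block a distinct bounded nonlinear
  transform, and the multi-kernel accuracy gain materializes. The
  `encode` function in the autoencoders module keeps the literal linear
  contract; the activation is applied in the model-level feature path.
* *Read-out vs kernel-row features.* Encoding a sample by its kernel
  row Ω̂ᵢ (available via `encode(..., via_kernel=True)`) was evaluated
  and performed worse for fusion; the read-out path is the default.

**MKR — residual fusion.** The encoders are stacked in series with
residual connections. With Y⁽⁰⁾ = X, block i fits its encoder on a
[0, 1] min-max *view* of the running stream (bounds learned during
training, stored in the model) and adds the view's reconstruction back
onto the raw stream:

    Y⁽ⁱ⁾ = Y⁽ⁱ⁻¹⁾ + reconstructᵢ(normᵢ(Y⁽ⁱ⁻¹⁾)).

The classifier consumes the [0, 1]-normalized Y⁽ᵏ⁾. Rationale: the
bare recursion Y ← Y + rec(Y) doubles the stream's magnitude at every
stage (a good autoencoder has rec ≈ identity), so by stage k the
stream sits at ≈2ᵏX and every downstream N(0,1)-weight sigmoid layer
saturates — measured accuracy collapsed with depth. Normalizing the
encoder's *view* rather than the stream keeps all sigmoid layers in
their active regime while preserving the shrinkage limit exactly: as
C → 0 every Γ → 0, all reconstructions vanish, and Y⁽ᵏ⁾ = X
unchanged. The residual sum uses the encoder's dimension-preserving
reconstruction (N×d); the encoding (N×N̂) cannot be added to the
stream unless N̂ = d.

`transform` returns the classifier-ready feature path (activated
concatenation for MKP, normalized Y⁽ᵏ⁾ for MKR) so that the training
and inference paths are bit-identical; the raw residual stream is
exposed separately as `residual_cascade`.

## Cost-sensitive decision layer

Scores become posteriors by a per-class sigmoid followed by row
normalization; probabilities are clamped to [1e-12, 1−1e-12] first so
expected risks stay finite. Given an m×m cost matrix with `c_ij` the
cost of predicting j when the truth is i, the decision is
`j* = argmin_j Σᵢ P(i|x)·c_ij`, ties broken to the lowest class
index. With 0-1 costs this is exactly the MAP rule; decisions are
invariant to positive rescaling of the cost matrix.

The per-class sigmoid of a ridge-fitted ±1-coded score is a crude
posterior estimate: scores concentrate near ±1, so posteriors
concentrate near σ(±1) ≈ 0.73/0.27 and never reach the extreme
regions. Under a strongly asymmetric cost matrix the minimum-risk rule
therefore shifts many borderline (and some clear) samples to the
expensive class, trading substantial raw accuracy for a large cost
reduction. This is inherent to sigmoid posterior conversion without
calibration; calibrated posteriors are out of scope.

Target coding is ±1 by default (+1 true class, −1 otherwise) so the
sigmoid is centered; 0/1 coding is available.

**Cost matrices.** Generated matrices have zero diagonal. Four
families: `uniform_range` (off-diagonal integers uniform in
[1, max_cost], default 20), and three structured families with maximum
value 10 — `type_a` (uniform integers in [1, 10]), `type_b`
(row-severity: one severity per true class), `type_c`
(imbalance-linked: costs proportional to inverse class frequency,
rescaled to a maximum of 10, requiring class counts). The three typed
constructions are this package's own stand-ins for benchmark designs
whose exact construction is not published; they are labeled
non-canonical and should not be treated as reference definitions.

**Weighting baselines.** Four per-sample weighting schemes feed the
weighted-ridge CELM baseline and related imbalance corrections:
inverse class frequency (`class_balance`), the true-class row sum of
the cost matrix (`row_sum`; the `per_sample_cost` scheme resolves to
the same quantity), and a hierarchical-ELM weighting (`helm`) read as
`w = 1/(p + (N_y − p)·N_y/max N)` with `p = N − N_y` — the printed
source formula is typographically ambiguous and this reading is the
one that is strictly positive for every class distribution, as a
sample weight must be. CELM solves
`β = (I/C + HᵀDH)⁻¹HᵀDT` with D the diagonal of row-sum weights.

**Metrics.** Accuracy `acc = 1 − Σ errᵢ/N`, total misclassification
cost `Tc = Σᵢⱼ errᵢⱼ·cᵢⱼ`, and relative performance
`r_α = Tc_α / max Tc` across a set of compared methods (worst method
gets exactly 1).

## Synthetic data generator

The generator emulates the statistical shape of the tabular benchmarks
the models target: m Gaussian clusters in d dimensions. Class centers
are i.i.d. standard normal vectors rescaled so their mean pairwise
distance equals `cluster_separation`; samples are isotropic Gaussian
around their class center with standard deviation `noise_sd`; class
sizes are multinomial at a given proportion vector (with a guarantee
that no class is empty). Defaults: n=600, d=8, m=3, balanced classes,
separation 3.0, noise 1.0 — a moderately overlapping problem where a
well-configured classifier reaches roughly 80–90 % test accuracy.

What the generator does **not** emulate: heterogeneous feature types
and scales, non-Gaussian class shapes, label noise, feature
correlations beyond those induced by center geometry, and the
across-dataset heterogeneity of real benchmark suites. Consequently,
tests passing on this generator demonstrate correctness of the
computations and the *direction* of the method's effects (multi-kernel
fusion helps; minimum-risk decisions cut cost at an accuracy price),
not the magnitudes reported on real data collections. On Gaussian
clusters every distance-based kernel sees essentially the same
geometry, so the fusion gain is small (fractions of a percentage
point) and noise-dominated at small repetition counts; on
heterogeneous real data the gain is expected to be larger.

## Evaluation protocol

One repetition: 60/40 uniform random train/test split; per-feature
min-max normalization to [0, 1] with bounds learned on the training
side only (a deliberate no-leakage deviation from normalizing whole
datasets; held-out values may exit [0, 1]); model fit on the training
side; scoring on the test side. The classifier is fixed at L = 1000
hidden nodes, C = 100, and R1 = 10, while R2 is calibrated by grid
search over [0.01, 0.2] in steps of 0.01 to optimize the test
objective (accuracy, or total cost when a cost matrix is supplied),
ties to the smaller R2. This search is part of the protocol the
comparative results assume, not an afterthought: at fixed arbitrary R2
the multi-kernel ranking is unstable because N̂ = round(R2·N) is tiny
at a few hundred samples.

Problem sizes used by the test suite and the acceptance script —
n = 300 (3-class trend benchmark), n = 600 (2-class cost benchmark),
10–30 repetitions — were chosen so the full pipeline, including the
R2 grid search, runs comfortably on a single CPU while keeping
standard errors below a percentage point.

## Numerical and engineering choices

* Sigmoid computed in a sign-branched form; no overflow at any finite
  input.
* Both Gram forms of the ridge solve use a symmetric positive-definite
  solver; the regularized system is nonsingular for every finite
  C > 0.
* Seeding: one master seed per model; sub-seeds are the uint32 words
  of `SeedSequence(master).generate_state(k)`, consumed in documented
  positional order (encoder 0..k−1, then classifier). Every component
  is independently reproducible; two fits with the same master seed are
  bit-identical.
* Reference points are sampled without replacement (near-duplicate
  references add redundant similarity features) and stored by value,
  so serialized encoders are independent of the training data.
* Constant feature columns normalize to 0; min-max bounds invert
  exactly on non-constant columns.
* Model archives are versioned JSON; writes are atomic
  (temp-file-then-rename); a corrupt or mismatched archive raises a
  clean error and never yields a partial model.
* Cosine similarity raises an explicit error on zero vectors rather
  than returning NaN. Sigmoid-mapped representations are strictly
  positive, so the REKELM pipeline never produces a zero vector
  internally.

## Known limitations

* Posteriors are uncalibrated sigmoid transforms; the minimum-risk
  layer inherits their compression (see above).
* The `type_a/b/c` cost families are plausible reconstructions, not
  canonical definitions.
* The multi-kernel gain on the synthetic generator is small relative
  to its sampling noise; single-run comparisons at one fixed R2 are
  not informative.
* Only sigmoid and identity activations are implemented; the encoders
  assume sigmoid throughout, which is the configuration the
  comparative protocol states.
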