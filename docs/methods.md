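# Methods

## Data model and conventions

A subject is an N×N symmetric connectivity matrix; its feature vector is
the strictly-upper triangle in row-major order — (0,1), (0,2), …,
(N−2,N−1) — giving p = N(N−1)/2 edges. The ordering is a package-wide
contract: penalty-score vectors, selected-edge indices and counterfactual
diffs all align to it. The diagonal (self-connectivity) is ignored, not
validated. Asymmetry beyond 1e−8 absolute is rejected rather than
symmetrized, so upstream preprocessing errors surface instead of being
averaged away. FC values are treated as opaque bounded reals in (−1, 1);
whether they are raw or Fisher-z-backtransformed correlations is
irrelevant to every downstream computation.

Labels: 1 = normal control, 0 = patient. Sensitivity is the true-positive
rate *on controls* — the opposite of many clinical papers — and is
documented wherever metrics appear.

## Weighted Lasso

The selection objective is ½Σ(yᵢ − β₀ − xᵢᵀβ)² + λΣωⱼ|βⱼ| with 0/1 labels
as reals; classification proper is delegated to the SVM stage, so the
regression is purely a screening device. The solver is cyclic coordinate
descent with residual updates (a numba-compiled kernel with an identical
numpy fallback). Features are always column-centered, which makes the
unpenalized intercept exactly separable from the coordinate updates;
unit-variance scaling is on by default (the penalty then acts on
standardized coefficients, as in standard Lasso practice) and can be
disabled, which the oracle tests use to compare against closed forms.
Convergence is declared when the largest coefficient change in a sweep
falls below 1e−7 (max 10⁵ sweeps), and every converged fit satisfies the
stationarity conditions |gⱼ| ≤ λωⱼ (zero coefficients) and
gⱼ = λωⱼ·sign(βⱼ) (active coefficients) to ≤ 1e−5, checked by
`kkt_violation`. The support is read off standardized coefficients at
threshold 1e−8 and reported in descending magnitude.

## Score transform and the cross-validation guard

Raw penalty scores S > 0 are mapped through W = Sᵠ, φ ∈ {0, …, 5}, then
rescaled to mean 1. The rescale keeps λ grids comparable across φ (powers
of scores otherwise change the overall penalty scale by orders of
magnitude) without altering relative penalization; φ = 0 returns exactly
all-ones. λ is selected jointly with φ — a fixed λ would confound weight
scale with shrinkage level — over a per-φ grid of 20 log-spaced values
from that φ's full-data λ_max down three decades. Validation loss is the
mean squared error of the linear predictor against the 0/1 labels,
consistent with the squared-error fitting objective (misclassification
loss is available). Folds are stratified and seeded; a fold that would
lose a class is rejected. Ties in the (φ, λ) argmin break to the smallest
φ, then the largest λ: least dependence on the external scores, sparsest
model. Because φ = 0 is always in the family, the selected CV loss is
structurally ≤ the plain-Lasso optimum; the code asserts this on every
run. This is the guard against unreliable scores: misleading scores raise
the validation loss for every φ > 0 and the selection falls back to plain
Lasso.

## Score elicitation

Prompts carry a task description, the contrast category, and a fixed
machine-readable output format; feature names are scored in chunks
(default 200) sharing one system context, because thousands of edge names
cannot be scored reliably in a single query. Temperature 0 (greedy
decoding) is requested from live providers for reproducibility. Parsing
is strict: every requested name must receive a positive finite score or
the chunk is rejected naming the first offender; unknown (hallucinated)
names are dropped with a warning; scores outside [1e−3, 1e3] are clipped
to keep all powers up to φ_max finite. Responses are cached on disk keyed
by (provider identity, prompt hash). Providers that return importance
rather than penalty can be inverted via 1/(|imp| + 0.01). The
deterministic mock scores each feature from a seeded hash of its name,
which makes the full pipeline runnable and testable with no network; the
live HTTP provider speaks the common chat-completions JSON shape via the
standard library.

## Classifier

A linear-kernel SVM (C = 1 by default, no nested tuning) supplies the
classification stage. Linearity is a deliberate contract, not a
simplification: the counterfactual objective needs the *unscaled* decision
value to be an affine, differentiable function of the inputs. Protocols
never leak: in the k-fold protocol the entire selection (transform CV,
refit, support) is recomputed from each training fold, and fold results
record their training indices so the provenance is auditable; the
leave-one-dataset-out protocol pools all sites but one, requiring
identical edge maps. If a training split yields an empty Lasso support,
the protocol reports it and falls back to the single best marginal edge so
an evaluation still completes.

## Counterfactual engine

For one subject m, L candidates are optimized jointly by projected
subgradient descent on

(1/L)Σ hinge + γ₁(1/L)Σ dist − γ₂ det(K),

hinge = max(0, 1 − z·logit), dist = mean |Δ|/MAD over the q features,
K_{u,v} = 1/(1 + dist). Defaults L = 5, γ₁ = 0.5, γ₂ = 1, target class 1.
The distance normalizer is the per-feature median absolute deviation of
the training set, floored at 1e−3 (constant features would otherwise make
distances infinite). The kernel diagonal receives one seeded uniform
jitter in [0, 1e−4] per run, fixed across iterations, which keeps K
invertible for the determinant gradient (adjugate identity,
∂det/∂K = det(K)·K⁻¹) and makes runs bit-reproducible. Optimization uses
backtracking line search (start 0.05, halve on non-descent, up to 20
times) from m plus Gaussian noise (sd 0.05), candidates clipped to
(−1, 1) each step; the objective trace is non-increasing by construction.
Three seeded restarts are run and the restart with the most valid
candidates (ties by lower objective) wins. Candidates that fail to cross
the boundary are flagged invalid, never dropped: a subject for whom no
valid counterfactual exists at the given γ₁ is a finding, not an error.

Note one geometric consequence of the subgradients: moving coordinate j
helps the hinge at rate |wⱼ| and costs proximity at rate γ₁/(q·MADⱼ), so
when γ₁ ≥ q·MADⱼ·|wⱼ| the optimizer correctly refuses to move — tests and
examples choose toys on the worthwhile side of that inequality.

Sparsification is an explicit post-stage (off by default in the config,
applied by the pipeline): per valid candidate, changed edges are restored
to their original values in ascending |Δ|/MAD order whenever the
prediction stays at the target. It weakly reduces the changed-edge count
and never invalidates a candidate; on 4-feature models it brings the
median changed-edge count to ≤ 2. Diff reports list per-candidate changes
sorted by |Δ|/MAD descending with an increase/decrease direction.

## Explanation

Each candidate becomes one intervention option. The template ranker orders
options by (number of changed edges, total normalized change) — an
operationalization of "effectiveness and feasibility" chosen because
fewer, smaller connectivity changes are the more plausible intervention.
A text provider may phrase the report (verbatim response kept, structured
"Rank r: Option l" lines parsed when present); any provider failure or
malformed response falls back to the deterministic template, so a report
always exists offline. Reports carry an explicit research-use disclaimer
and contain no numeric value that is not present in the request.

## Synthetic data

The generator emulates edge-level group differences directly rather than
simulating BOLD time series — the method consumes edge features only, so
time-series realism would add nothing testable. Per edge, both groups draw
Gaussians (within-group sd 1.0); on the chosen signal edges the group
means sit at ±effect_size/2 (pre-squash scale), and tanh(z/2) maps all
values into (−1, 1), the range of correlation-valued FC. Defaults: 60
subjects per class, N = 10 regions (45 edges), 5 signal edges, effect
size 1.0 — sample sizes comparable to a single clinical site, scaled-down
edge count so the full transform-CV grid runs in seconds. Score
generation has three regimes: informative (signal edges drawn in
[0.1, 0.3), all others in [1, 2), hence strictly cheaper), misleading
(the cheap set is a random decoy disjoint from the signal), uniform.

What the generator does *not* emulate: inter-regional covariance
structure, site/scanner effects, demographic confounds, or class
imbalance (available but not default). Passing tests therefore show the
machinery is correct and the guard behaves as designed under clean
Gaussian signal; they do not certify performance on real multi-site
clinical data.

## Problem sizes and numerical choices

Tests and the acceptance script run at N = 10, n = 120 (20 seeded
replicates for rate estimates), chosen so the full study — transform CV
over 6 exponents × 20 λ values × 5 folds, 20 replicates — completes in
seconds while keeping n/p in the regime where the guard question is
non-trivial (p ≈ n/3). The oracle comparisons use p = 2 (dense two-stage
grid search, refined around the coarse argmin with 0 included exactly so
the kink is represented) and orthonormal centered designs (QR of a
centered Gaussian matrix), where soft-thresholding is exact. Degenerate
inputs are handled explicitly: zero-variance features get zero
coefficients; empty supports are reported; zero MADs are floored; single
determinants (L = 1) are defined as 1 before jitter.

## Known limitations

- The squared-error screening regression is not a calibrated
  classification model; its validation MSE is a selection criterion only.
- The power family Sᵠ with integer φ is coarse; a continuous trust
  parameter would interpolate but would lose the exact φ = 0 fallback
  cell.
- Counterfactual optimization is non-convex (the diversity term); seeded
  restarts mitigate but do not guarantee global optimality, and the
  boundary-projection agreement is verified only for linear models.
- The leave-one-dataset-out protocol assumes identical atlases across
  sites; cross-atlas harmonization is out of scope.
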