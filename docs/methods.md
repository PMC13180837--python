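# Methods

This note records the modelling assumptions, parameter choices, and
numerical decisions behind `geoexposure`, and what the synthetic-data
experiments do and do not establish.

## Spatial domain and operators

Locations are points in planar coordinates with positive populations;
geographic lon/lat must be projected by the caller. The graph adjacency is
a Gaussian proximity kernel with bandwidth σ and a hard locality cutoff δ;
the diagonal is set to zero so that L = D − A is the standard
combinatorial Laplacian (row sums zero, positive semidefinite). The
population-weighted kernel W(x,x′) = k_σ(x,x′)P(x′) *retains* the self
term, which is what makes the induced nonlocal aggregation operator
Ē(x) = Σ W(x,x′)E(x′)/Σ W(x,x′) preserve constants — a property the test
suite checks. All spatial and temporal integrals are discretized as plain
sums over nodes and steps with unit (or user-supplied area) weights; the
data are discrete samples and no quadrature scheme is assumed. Lookback
windows are inclusive of both endpoints on a 0-based step grid, with no
implicit padding at the series head. Missing values are never imputed; a
boolean mask may be attached to a field and masked entries are dropped
from aggregation means with weights renormalized.

## The predictive network

The lookback window of each node is encoded by two causal 1-D
convolutions (kernel width 3, dilations 1 and 2, ReLU between, linear
output) read out at the window's last step. The stack's nominal receptive
field (7 steps) exceeds the default window τ = 4, so the convolutions use
causal zero-padding *inside* the window; any τ ≥ 1 is valid and the
encoder sees exactly the window, never earlier data. Diffusion applies
Σ α_k L^k by iterated multiplication (never explicit matrix powers);
α initializes to the identity filter (α₀ = 1, rest 0). An optional flag
rescales L by its spectral radius for training stability; it is off by
default so the filter acts on the raw Laplacian. Attention is single-head
scaled dot-product over the time axis, unmasked (relevance may flow from
any time). Contextual integration embeds C(t) with one ReLU affine map,
broadcasts over nodes, adds, and layer-normalizes over the latent axis
(ε = 1e−5, no learnable affine, requiring d ≥ 2); the policy gate is a
sigmoid affine map of P(t) applied elementwise. The head is one residual
block (two dense layers of width d, ReLU) plus a linear readout. The
three stages — diffusion, attention, contextual integration — carry
ablation flags; a disabled stage is an identity pass-through, so the
minimal pipeline is encode → head exactly.

Initialization is uniform fan-in scaling from one seeded generator
(default seed 17); all stochasticity in the package funnels through
explicit seeds and is bit-reproducible.

### Differentiation

Parameters and inputs are differentiated by a compact reverse-mode tape
over numpy arrays (`geoexposure.autodiff`). The engine provides only the
primitives the pipeline composes (broadcast arithmetic, batched matmul,
ReLU/sigmoid/tanh/exp, reductions, indexing, padding); softmax and layer
norm are built by composition so their gradients need no bespoke code.
Finite-difference agreement is asserted in the test suite at 1e−5
relative scale. The engine is first-order only: no gradients of
gradients. Attribution maps — the Euclidean norm of a node's prediction
Jacobian with respect to its own exposure window, per node/time and
optionally per exposure variable — require one reverse sweep per (node,
time, outcome) because diffusion and attention couple nodes and times;
the forward graph is built once and re-swept with cleared gradients.
Cost is O(N·T′·q) sweeps, so command-line vulnerability maps default to
the last prediction time.

## Causal layer

**Treatment.** Exposure assignment is binary in v1 (the synthetic design
shifts one exposure variable by +1 for treated nodes; external unit
tables carry an explicit 0/1 indicator). Continuous generalized
propensities are out of scope.

**Propensities** are logistic in the confounders, fitted by maximum
likelihood (statsmodels) with an intercept. A rank-deficient design,
perfect separation, or implausible coefficients (|w| > 50) trigger a
warning and a ridge-penalized fallback (penalty 1e−4, scikit-learn).
Scores are kept strictly inside (0, 1).

**Weighted loss.** The observational loss is Σ ‖Ĥ−H‖²/(π+ε) over all
observed samples. The `ipw_loss` primitive is the literal formula
(ε ≥ 0, no clipping) so its closed-form micro-cases hold exactly; the
training configuration additionally clips propensities to [0.01, 0.99]
(a standard positivity guard) and uses ε = 1e−3. Note this single-arm
1/π weighting is the training-loss device; the IPTW *estimator* in the
baselines weights treated by 1/π and controls by 1/(1−π),
self-normalized.

**Monotonicity prior.** For each exposure variable j with prior direction
ρ_j ∈ {−1, 0, +1}, the model's sensitivity is the cumulative central
difference of predictions under a uniform ±h shift of variable j
(h = 1e−3) — the sensible target for a monotonicity prior, exact for
piecewise-linear responses, and differentiable with respect to
parameters through two forward passes (avoiding second-order autodiff).
The penalty is the mean over nodes, times and outcomes of
(s(g_j) − sign(ρ_j))², summed over active j and scaled by λ, with s the
exact sign at evaluation and tanh(g/κ), κ = 0.1, during training.

**Spatial coherence.** R_lap = μ·Tr(ĤᵀLĤ) per time slice, averaged over
slices for a series; zero exactly on node-constant predictions,
nonnegative because L is PSD.

**Counterfactuals.** A scenario is a (τ × p) trajectory, row 0 earliest.
Responses come through one interface from either (a) the literal
discrete-sum response kernel — used with the synthetic ground truth,
where it is exact — or (b) a trained-model adapter that substitutes the
trajectory into a node's window and re-runs the forward pass. Scenario
selection minimizes the Euclidean distance of the response to a
benchmark vector; ties break to the lowest index, and indices are
0-based. The vulnerability map is the prior-weighted sum Σ_j γ_{i,j}^t ρ_j
of per-variable gradient norms, linear in the gradients by construction.

**Training** is full-batch Adam. The library default (step 1e−3, 200
epochs) is a conservative general-purpose setting; the reference
experiments described below use step 3e−2, which at their problem sizes
reaches convergence within the same epoch budget. Divergence (non-finite
loss) aborts with the component breakdown in the message.

## Classical baselines

Estimands are labelled explicitly: IPTW targets the ATE, 1:1 greedy
nearest-neighbour matching on the propensity logit without replacement
targets the ATT (unmatched treated units are dropped and counted).
Treated units are processed in descending propensity order and the
caliper defaults to 0.2 standard deviations of the logit. SMD is
|mean_T − mean_C|/√((var_T+var_C)/2) per covariate (n−1 variances
unweighted; weighted moments when weights are supplied); zero pooled
variance reports SMD 0 with a warning. Effect stability is
clip(1 − sd/(|mean|+1e−12), 0, 1) over B per-arm stratified bootstrap
resamples — a package construction for "consistency under repeated
sampling", reproducible by seed, with failing resamples skipped and more
than 20% failures an error.

## Synthetic studies

The generator emulates a monitoring network on the unit square:
log-normal populations; susceptibility covariates drawn standard normal,
spatially smoothed by one adjacency-weighted averaging pass and then
re-standardized (smoothing supplies spatial correlation; standardization
keeps the marginal scale that the confounding design is calibrated in);
exposures are squared-exponential Gaussian random fields (correlation
length 0.3) evolving as a stationary AR(1) (φ = 0.6); outcomes follow a
lagged linear kernel H = Σ_s w_s βᵀE(t−s) + γ_SᵀS + γ_CᵀC(t) + ε with
normalized lag weights, deterministic seasonal context, and i.i.d.
Gaussian noise. Treatment is Bernoulli with probability
σ(c·mean(S(x))) per node and shifts exposure variable 1 by +1 at every
time, so the true ATE equals β₁ exactly.

Defaults: N = 200 nodes, T = 60 steps, p = 2 exposures, q = 1 outcome,
r = 3 susceptibility covariates, τ = 4, β₁ = 2 (0.5 on the second
exposure), lag weights ∝ (4,3,2,1), γ_S = 0.8 per covariate, γ_C = 0.5,
noise sd 0.5, confounding strength c = 1.5. Under these conditions the
unadjusted estimator is materially biased (order +1 on an effect of 2)
while the confounders are fully observed, so correctly-specified
weighting recovers the truth — the regime the causal-recovery tests
measure. An optional `hidden_fraction` masks confounder columns for
stress tests (hidden confounding breaks the recovery guarantee by
design), and an optional `spatial_coupling` mixes neighbour-averaged
exposure into the response for predictive experiments; the node-local
closed-form ATE is exact only at coupling 0.

What passing tests on this generator do *not* show about real data:
confounders here are exactly the outcome-relevant susceptibility
covariates and the propensity model is correctly specified; real studies
face hidden confounding, misspecification, measurement error and
missingness, none of which are exercised by the defaults.

## Reference experiments

*Causal recovery* simulates 20 default studies and compares naive, IPTW
and PSM biases against the analytic truth, plus SMD reduction under
weighting. *Parameter recovery* trains the full network (d = 8, K = 2,
τ = 4) for 200 epochs on a noiseless 40-node, 40-step study inside the
model class (node-local kernel, context on, γ_S = 0 since the network has
no susceptibility input) and reports in-sample MSE against outcome
variance. *The ablation study* compares in-sample MSE of the full network
with each single-stage removal on a design where every stage carries
identifiable signal: an 8-lag uniform kernel against the 4-step model
window under weak temporal autocorrelation (φ = 0.2) so beyond-window
memory is only reachable through attention; spatial coupling 0.5 so the
response depends on neighbours; and the context term. Each variant
trains for 600 epochs from a common seed. On purely node-local in-class
data this ordering is not expected: attention has nothing to recover
there and acts as an optimization handicap. Even on the richer design
the ordering is seed-dependent — with some data draws the full model
settles in a worse basin than an ablated variant — so the reproduction
script reports replicate-averaged MSEs and the fraction of draws where
the full model is best, rather than a single draw. Problem sizes
(40 nodes for training experiments, 200 for causal recovery) are the
package's desk-scale reference designs.

## Numerical choices and degenerate inputs

- Adjacency requires σ, δ > 0 and finite coordinates; duplicate node ids
  are rejected. Laplacian construction tolerates asymmetry only to 1e−12.
- Aggregation errors on all-zero weight rows, naming the node.
- Propensity scores clamp to the open unit interval at machine precision;
  saturated logits (|wᵀZ| ≈ 30) stay strictly inside (0, 1).
- Scenario windows must match the kernel/model window exactly; matrices
  of mixed-window scenarios are rejected.
- Checkpoints are a single JSON document (config, seed, full-precision
  arrays); loading validates every shape against the config.
- CSV readers parse floats in round-trip mode and normalize node ids to
  text, so write→read→write cycles are byte-stable and ids compare
  consistently across files.
- Zero training epochs return the model unchanged; a non-finite loss
  aborts with diagnostics.

## Known limitations

- Binary treatment only; no doubly-robust or instrumental-variable
  estimators; no continuous generalized propensity.
- The monotonicity penalty uses uniform-shift sensitivities, not per-lag
  signs; a response positive cumulatively but negative at one lag is not
  penalized.
- Attribution cost grows as O(N·T′·q) reverse sweeps; full maps at
  hundreds of nodes are minutes, not seconds.
- In-sample fit is the training-experiment metric; no held-out
  generalization claims are made.
- The attention stage's benefit depends on the data carrying
  beyond-window temporal structure, and its optimization can fail from
  some initial conditions/data draws (see the ablation discussion).
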