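# geoexposure

Spatiotemporal exposure–response modelling for environmental epidemiology,
with a causal-aware training and inference layer.

## The problem

Health outcomes such as respiratory morbidity respond to environmental
exposures (pollutants, aeroallergens, heat) in ways that are *lagged* (past
exposure matters over a lookback window), *spatially coupled* (neighbouring
populations share air sheds and mobility), *context-dependent* (season,
policy), and *confounded* in observational data (susceptible populations
are often the more exposed ones). `geoexposure` provides, for desk-scale
studies on a set of monitoring locations:

- a graph-based predictive network mapping exposure histories
  E ∈ ℝ^{N×T×p} on N locations to health indicators Ĥ ∈ ℝ^{N×T′×q};
- a causal layer: logistic propensity scores π(x) = σ(wᵀZ(x)),
  inverse-propensity weighting of the training loss, monotone
  epidemiological priors, counterfactual scenario simulation, and
  gradient-saliency vulnerability maps;
- classical baselines — unadjusted difference of means, IPTW
  (self-normalized Horvitz–Thompson), 1:1 propensity-score matching — with
  standardized-mean-difference balance diagnostics and bootstrap
  effect-stability scores;
- a synthetic study generator with a known lagged linear response kernel
  and confounded treatment assignment, so every causal claim can be
  checked against analytic ground truth.

## The model

Per prediction time t the network composes

1. **temporal encoding** — causal 1-D convolutions over each node's
   τ-step window: Z_i^t = φ_temp(E_i^{t−τ:t}) ∈ ℝ^d;
2. **graph diffusion** — a degree-K polynomial filter in the graph
   Laplacian L = D − A of the Gaussian-kernel adjacency
   A_ij = exp(−‖x_i−x_j‖²/2σ²)·1[‖x_i−x_j‖<δ]:
   Z̃_t = Σ_{k=0}^K α_k L^k Z_t;
3. **temporal attention** — per node, softmax(QKᵀ/√d)V over the time axis;
4. **contextual integration** — U_t = LayerNorm(Attn_t + ReLU(W_c C(t)+b_c))
   modulated by a policy gate ζ_t = σ(W_p P(t)+b_p), Ũ_t = U_t ⊙ ζ_t;
5. **prediction head** — a residual two-layer MLP with linear readout.

Training minimizes L = Σ_{x,t} ‖Ĥ−H‖²/(π+ε) + R_epi + μ·Tr(ĤᵀLĤ), where
R_epi penalizes exposure-response gradients whose sign contradicts prior
directions ρ_j ∈ {−1,0,+1}. Counterfactual responses H_x^{(e)}(t) under a
hypothetical trajectory e are computed either through the known synthetic
kernel (exact) or by substituting e into a node's exposure window and
re-running the trained network; differences of two such responses are
causal effects, and ‖∂Ĥ/∂E_j‖-type gradient norms weighted by ρ_j give a
per-location vulnerability map.

Everything differentiable runs on a small reverse-mode autodiff engine
over numpy (`geoexposure.autodiff`), validated against finite differences
in the test suite.

## Worked example

```python
import numpy as np
import geoexposure as gx
from geoexposure import baselines, cam, synthetic

# a confounded study with known truth: 200 nodes, 60 steps, effect 2.0
study = synthetic.simulate_study(synthetic.SimulationConfig(seed=0))

for est in (baselines.naive_estimate(study.causal),
            baselines.iptw_estimate(study.causal),
            baselines.psm_estimate(study.causal)):
    print(f"{est.method:5s} ({est.estimand}): estimate {est.estimate:.3f}, "
          f"avg SMD after adjustment {np.mean(est.smd_after):.3f}")

kernel = study.truth.kernel()
scenarios = [cam.ExposureScenario(np.full((4, 2), lv), label=f"exposure={lv}")
             for lv in (0.0, 0.5, 1.0)]
mat = cam.counterfactual_matrix(scenarios, kernel)
best = cam.select_scenario(mat, target=[1.0])
print("responses:", np.round(mat.values.ravel(), 3),
      "-> nearest the benchmark 1.0:", mat.labels[best])
```

prints

```
naive (ATE): estimate 2.520, avg SMD after adjustment 0.219
IPTW  (ATE): estimate 2.040, avg SMD after adjustment 0.015
PSM   (ATT): estimate 2.144, avg SMD after adjustment 0.060
responses: [0.   1.25 2.5 ] -> nearest the benchmark 1.0: exposure=0.5
```

The generator's confounding (susceptible nodes are likelier to be treated,
and susceptibility raises the outcome) biases the unadjusted estimate by
about +0.5 against the true effect of 2.0; weighting on the fitted
propensities removes almost all of it and balances the covariates (average
SMD 0.22 → 0.015). The counterfactual matrix evaluates three constant
exposure trajectories through the true kernel and picks the scenario whose
response is closest to the health benchmark.

A command-line surface wraps the same pipeline:

```bash
geoexposure simulate --seed 7 --out study/
geoexposure fit --nodes-file study/nodes.csv --exposure-file study/exposure.csv \
    --outcome-file study/outcomes.csv --context-file study/context.csv --out fit/
geoexposure compare-causal --causal-file study/causal.csv --out report/
```

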