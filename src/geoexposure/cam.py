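"""Causal-aware adaptive mapping: propensity weighting, epidemiological and
spatial regularizers, policy gating, counterfactual simulation and the
composite training objective.

The causal layer treats exposure assignment as confounded by observed
covariates: a logistic propensity model reweights the observational squared
error (inverse-propensity weighting), a monotonicity regularizer penalizes
exposure-response gradients whose sign contradicts epidemiological priors,
and a graph-Laplacian penalty keeps predictions spatially coherent.
Counterfactual health responses under hypothetical exposure trajectories
are computed either through the literal discrete-sum response kernel (exact
for the synthetic ground truth) or by substituting the trajectory into a
node's exposure window and re-running the trained network — both behind one
interface.

Treatment in v1 is binary (an exposure variable dichotomized or an explicit
indicator); continuous generalized propensities are unsupported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, Adam
from . import model as gx_model
from .model import ModelState, ContextSeries, forward, attribution_scores

__all__ = [
    "PropensityModel",
    "EpidemiologicalPriors",
    "ExposureScenario",
    "CounterfactualMatrix",
    "VulnerabilityMap",
    "LossConfig",
    "OptimizerConfig",
    "TrainingData",
    "TrainResult",
    "LinearLagKernel",
    "ModelScenarioAdapter",
    "propensity_score",
    "fit_propensity",
    "ipw_loss",
    "epi_regularizer",
    "policy_gate",
    "apply_gate",
    "counterfactual_response",
    "causal_effect",
    "counterfactual_matrix",
    "select_scenario",
    "causal_gradients",
    "vulnerability_map",
    "laplacian_penalty",
    "total_loss",
    "train",
]

_PROB_LO = np.nextafter(0.0, 1.0)
_PROB_HI = np.nextafter(1.0, 0.0)


# ----------------------------------------------------------------- containers
@dataclass
class PropensityModel:
    """Logistic treatment model: P(T=1|Z) = sigmoid(w.Z + intercept)."""

    weights: np.ndarray
    intercept: float = 0.0
    stabilizer: float = 1e-3
    ridged: bool = False  # True when the ridge fallback was used

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.stabilizer <= 0:
            raise ValueError("stabilizer must be positive")


@dataclass
class EpidemiologicalPriors:
    """Expected monotonic direction per exposure variable.

    directions[j] in {-1, 0, +1}; 0 means no prior for that variable and
    contributes nothing.  `strength` is the regularizer weight lambda.
    """

    directions: np.ndarray
    strength: float = 0.0

    def __post_init__(self):
        self.directions = np.atleast_1d(np.asarray(self.directions, dtype=int))
        if not np.all(np.isin(self.directions, (-1, 0, 1))):
            raise ValueError("prior directions must be -1, 0 or +1")
        if self.strength < 0:
            raise ValueError("prior strength must be nonnegative")


@dataclass
class ExposureScenario:
    """A hypothetical exposure trajectory over a tau-step window.

    `trajectory` is (tau, p) with row 0 the earliest step of the window.
    """

    trajectory: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.trajectory = np.atleast_2d(np.asarray(self.trajectory, dtype=float))
        if not np.all(np.isfinite(self.trajectory)):
            raise ValueError("scenario trajectory must be finite")


@dataclass
class CounterfactualMatrix:
    """Counterfactual responses, one (q,) column per scenario."""

    values: np.ndarray   # (q, K)
    labels: list = dc_field(default_factory=list)


@dataclass
class VulnerabilityMap:
    """Prior-weighted gradient map: V(x_i, t) = sum_j gamma_{i,j}^t rho_j."""

    values: np.ndarray   # (node, time)
    time_indices: np.ndarray | None = None


@dataclass
class LossConfig:
    """Weights of the composite objective.

    lambda_epi scales the monotonicity regularizer, mu_lap the Laplacian
    smoothness penalty, epsilon stabilizes the inverse-propensity weights;
    `clip` bounds propensities before weighting (positivity guard; set to
    None for the literal unclipped weighting).  kappa is the tanh
    temperature of the train-mode sign surrogate.
    """

    lambda_epi: float = 0.0
    mu_lap: float = 0.0
    epsilon: float = 1e-3
    use_weighting: bool = True
    use_epi: bool = True
    use_lap: bool = True
    kappa: float = 0.1
    clip: tuple | None = (0.01, 0.99)

    def __post_init__(self):
        if self.lambda_epi < 0 or self.mu_lap < 0 or self.epsilon < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class OptimizerConfig:
    epochs: int = 200
    lr: float = 1e-3


@dataclass
class TrainingData:
    """Everything the descent loop consumes.

    `outcomes` must be aligned to the model's prediction times (time index
    tau-1 onward); `propensities` is one value per node (or per node-time),
    None meaning unweighted.
    """

    exposure: object
    outcomes: object
    graph: object
    context: ContextSeries | None = None
    propensities: np.ndarray | None = None
    priors: EpidemiologicalPriors | None = None


@dataclass
class TrainResult:
    model: ModelState
    loss_trace: np.ndarray
    components: dict


# ------------------------------------------------------------------ propensity
def propensity_score(confounder_vector, model: PropensityModel) -> np.ndarray:
    """Logistic propensity, strictly inside (0, 1)."""
    z = np.asarray(confounder_vector, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite confounder values")
    logit = z @ model.weights + model.intercept
    score = 1.0 / (1.0 + np.exp(-logit))
    return np.clip(score, _PROB_LO, _PROB_HI)


def fit_propensity(dataset, stabilizer: float = 1e-3) -> PropensityModel:
    """Maximum-likelihood logistic regression of treatment on confounders.

    Deterministic given the data.  Perfect separation or a singular design
    triggers a warning and a ridge-penalized fallback (penalty 1e-4).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    t = np.asarray(dataset.treatment, dtype=float)
    Z = np.atleast_2d(np.asarray(dataset.confounders, dtype=float))
    if t.min() == t.max():
        raise ValueError("both treatment arms must be nonempty")
    if min((t == 0).sum(), (t == 1).sum()) < 2:
        raise ValueError("need at least 2 units per treatment arm")
    X = sm.add_constant(Z, has_constant="add")
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1]
    try:
        if rank_deficient:
            raise np.linalg.LinAlgError("rank-deficient design (unidentifiable)")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(t, X).fit(disp=0)
        params = res.params
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 50:
            raise PerfectSeparationError("implausible logistic coefficients")
        return PropensityModel(weights=params[1:], intercept=float(params[0]),
                               stabilizer=stabilizer)
    except Exception:
        warnings.warn(
            "logistic MLE failed (separation or singular design); "
            "falling back to ridge-penalized fit",
            RuntimeWarning,
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0 / 1e-4, solver="lbfgs", max_iter=1000)
        clf.fit(Z, t.astype(int))
        return PropensityModel(weights=clf.coef_[0],
                               intercept=float(clf.intercept_[0]),
                               stabilizer=stabilizer, ridged=True)


def ipw_loss(predictions, observed, propensities, epsilon: float,
             clip: tuple | None = None):
    """Inverse-propensity-weighted squared-error sum.

    sum over samples of ||H_hat - H||^2 / (pi + epsilon).  Works on plain
    arrays or on an autodiff Tensor of predictions (training path).  `clip`
    optionally bounds the propensities first (positivity guard).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    pi = np.asarray(propensities, dtype=float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("propensities must lie in (0, 1]")
    if clip is not None:
        pi = np.clip(pi, clip[0], clip[1])

    def _weights(sq_shape):
        w = 1.0 / (pi + epsilon)
        if w.ndim == 1 and len(sq_shape) == 2 and w.shape[0] == sq_shape[0]:
            w = w[:, None]  # per-node weights broadcast over time
        return np.broadcast_to(w, sq_shape)

    if isinstance(predictions, Tensor):
        obs = np.asarray(observed, dtype=float)
        err = predictions - obs
        sq = (err * err).sum(axis=-1) if err.ndim > 1 else err * err
        return (sq * _weights(sq.shape)).sum()
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations must align")
    sq = ((pred - obs) ** 2)
    if sq.ndim > 1:
        sq = sq.sum(axis=-1)
    return float((sq * _weights(sq.shape)).sum())


# --------------------------------------------------------------- regularizers
def _shift_sensitivities(model: ModelState, exposure, context, graph,
                         variable: int, step: float, as_tensor: bool):
    """Central-difference sensitivity of predictions to a uniform shift of
    one exposure variable (the cumulative exposure-response direction)."""
    E = np.array(gx_model._as_exposure_array(exposure), dtype=float)
    up, dn = E.copy(), E.copy()
    up[:, :, variable] += step
    dn[:, :, variable] -= step
    if as_tensor:
        pu = forward(up, context, graph, model, return_tensor=True)
        pd = forward(dn, context, graph, model, return_tensor=True)
        return (pu - pd) * (1.0 / (2.0 * step))
    pu = forward(up, context, graph, model)
    pd = forward(dn, context, graph, model)
    return (pu - pd) / (2.0 * step)


def epi_regularizer(model: ModelState, exposure_field, priors: EpidemiologicalPriors,
                    mode: str, *, context=None, graph=None, kappa: float = 0.1,
                    fd_step: float = 1e-3, strength: float | None = None):
    """Monotonicity regularizer against the prior exposure-response signs.

    For each exposure variable j with a nonzero prior rho_j, the model's
    sensitivity g_j = dH_hat/dE_j (cumulative over the lag window, by
    central differences) is compared to the prior: the penalty is the mean
    over nodes, times and outcomes of (s(g_j) - sign(rho_j))^2, summed over
    j and scaled by the prior strength.  `mode='eval'` uses the exact sign;
    `mode='train'` uses the differentiable surrogate tanh(g/kappa) and
    returns a Tensor.
    """
    if mode not in ("eval", "train"):
        raise ValueError(f"unknown mode {mode!r} (use 'eval' or 'train')")
    lam = priors.strength if strength is None else strength
    active = [j for j, rho in enumerate(priors.directions) if rho != 0]
    if not active or lam == 0:
        return Tensor(0.0) if mode == "train" else 0.0
    if mode == "eval":
        total = 0.0
        for j in active:
            g = _shift_sensitivities(model, exposure_field, context, graph,
                                     j, fd_step, as_tensor=False)
            total += float(np.mean((np.sign(g) - np.sign(priors.directions[j])) ** 2))
        return lam * total
    total = Tensor(0.0)
    for j in active:
        g = _shift_sensitivities(model, exposure_field, context, graph,
                                 j, fd_step, as_tensor=True)
        s = ad.tanh(g * (1.0 / kappa))
        dev = s - float(np.sign(priors.directions[j]))
        total = total + (dev * dev).mean()
    return total * lam


def laplacian_penalty(predictions_slice, laplacian, mu: float):
    """Spatial roughness penalty mu * Tr(H' L H).

    Accepts a single (N, q) slice or an (N, T', q) cube (averaged over
    time slices).  Zero exactly on node-constant predictions; nonnegative
    whenever L is positive semidefinite.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    L = np.asarray(laplacian, dtype=float)
    H = predictions_slice
    if isinstance(H, Tensor):
        if H.ndim == 2:
            return (H * (ad.tensor(L) @ H)).sum() * mu
        N, T, q = H.shape
        flat = H.swapaxes(0, 1).reshape(T, N, q)
        Lh = ad.tensor(L) @ flat
        return (flat * Lh).sum() * (mu / T)
    H = np.asarray(H, dtype=float)
    if H.ndim == 2:
        if H.shape[0] != L.shape[0]:
            raise ValueError("prediction node axis does not match laplacian")
        return mu * float(np.einsum("nq,nm,mq->", H, L, H))
    vals = np.einsum("ntq,nm,mtq->t", H, L, H)
    return mu * float(vals.mean())


# -------------------------------------------------------------- policy gating
def policy_gate(policy_vector, model: ModelState) -> np.ndarray:
    """Sigmoid modulation gate zeta = sigmoid(Wp P(t) + bp), in (0,1)^d."""
    out = gx_model._policy_gate_tensor(policy_vector, model).data
    return np.clip(out, _PROB_LO, _PROB_HI)


def apply_gate(fused_slice, gate):
    """Elementwise modulation of the fused latent, broadcast across nodes."""
    if isinstance(fused_slice, Tensor) or isinstance(gate, Tensor):
        return ad.tensor(fused_slice) * ad.tensor(gate)
    U = np.asarray(fused_slice, dtype=float)
    z = np.asarray(gate, dtype=float)
    if z.shape[-1] != U.shape[-1]:
        raise ValueError("gate length must match the latent dimension")
    return U * z


# ------------------------------------------------------------ counterfactuals
@dataclass
class LinearLagKernel:
    """Literal discrete-sum response kernel with linear lagged structure.

    response(e) = sum_s w(lag of s) beta' e[s] + gamma_s' S + mean_s
    gamma_c' C(s), with trajectory row 0 the earliest window step.  Lag
    weights are used as given (the synthetic generator normalizes its own).
    """

    beta: np.ndarray
    lag_weights: np.ndarray
    gamma_s: np.ndarray | None = None
    gamma_c: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.lag_weights = np.atleast_1d(np.asarray(self.lag_weights, dtype=float))

    def response(self, trajectory, susceptibility=None, context_window=None) -> np.ndarray:
        e = np.atleast_2d(np.asarray(trajectory, dtype=float))
        tau = e.shape[0]
        if tau != self.lag_weights.shape[0]:
            raise ValueError(
                f"scenario window {tau} != kernel lag window {self.lag_weights.shape[0]}"
            )
        w = self.lag_weights[::-1]
        out = np.einsum("s,sp,pq->q", w, e, self.beta)
        if self.gamma_s is not None and susceptibility is not None:
            out = out + np.asarray(susceptibility, dtype=float) @ self.gamma_s
        if self.gamma_c is not None and context_window is not None:
            C = np.atleast_2d(np.asarray(context_window, dtype=float))
            out = out + C.mean(axis=0) @ self.gamma_c
        return out


class ModelScenarioAdapter:
    """Counterfactual responses through a trained network.

    The scenario trajectory is substituted into one node's exposure window
    ending at the anchor time and the forward pass re-run; the response is
    that node's prediction at the anchor time.
    """

    def __init__(self, model: ModelState, graph, exposure_field, context,
                 node_index: int, time_index: int):
        self.model = model
        self.graph = graph
        self.exposure = np.array(gx_model._as_exposure_array(exposure_field),
                                 dtype=float)
        self.context = context
        self.node_index = int(node_index)
        self.time_index = int(time_index)
        tau = model.config.tau
        if not (tau - 1 <= self.time_index < self.exposure.shape[1]):
            raise ValueError("anchor time has no complete lookback window")

    def response(self, trajectory, susceptibility=None, context_window=None) -> np.ndarray:
        tau = self.model.config.tau
        e = np.atleast_2d(np.asarray(trajectory, dtype=float))
        if e.shape != (tau, self.model.config.n_exposures):
            raise ValueError(
                f"trajectory shape {e.shape} != (tau, p) "
                f"({tau}, {self.model.config.n_exposures})"
            )
        E = self.exposure.copy()
        t = self.time_index
        E[self.node_index, t - tau + 1 : t + 1, :] = e
        pred = forward(E, self.context, self.graph, self.model)
        return pred[self.node_index, t - (tau - 1), :]


def counterfactual_response(scenario, response_kernel, susceptibility=None,
                            context=None) -> np.ndarray:
    """Counterfactual health response under a hypothetical trajectory.

    `response_kernel` is either an object with a `.response(trajectory,
    susceptibility, context_window)` method (ground-truth kernel or trained
    model adapter) or a plain callable G(e_s, s, S, C_s), in which case the
    literal discrete sum over the window (unit step) is taken.
    """
    traj = np.atleast_2d(np.asarray(
        getattr(scenario, "trajectory", scenario), dtype=float))
    if hasattr(response_kernel, "response"):
        return np.atleast_1d(response_kernel.response(traj, susceptibility, context))
    out = None
    for s in range(traj.shape[0]):
        c_s = None if context is None else np.asarray(context)[s]
        term = np.atleast_1d(np.asarray(
            response_kernel(traj[s], s, susceptibility, c_s), dtype=float))
        out = term if out is None else out + term
    return out


def causal_effect(scenario1, scenario2, kernel, susceptibility=None,
                  context=None) -> np.ndarray:
    """Expected health change of scenario 1 relative to scenario 2."""
    t1 = np.atleast_2d(np.asarray(getattr(scenario1, "trajectory", scenario1)))
    t2 = np.atleast_2d(np.asarray(getattr(scenario2, "trajectory", scenario2)))
    if t1.shape != t2.shape:
        raise ValueError("scenarios must share the window shape")
    r1 = counterfactual_response(scenario1, kernel, susceptibility, context)
    r2 = counterfactual_response(scenario2, kernel, susceptibility, context)
    return r1 - r2


def counterfactual_matrix(scenarios, kernel, susceptibility=None,
                          context=None) -> CounterfactualMatrix:
    """One response column per scenario, shape (q, K)."""
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("at least one scenario required")
    shapes = {np.atleast_2d(np.asarray(
        getattr(s, "trajectory", s))).shape for s in scenarios}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent scenario windows: {sorted(shapes)}")
    cols = [counterfactual_response(s, kernel, susceptibility, context)
            for s in scenarios]
    labels = [getattr(s, "label", f"scenario_{k}") or f"scenario_{k}"
              for k, s in enumerate(scenarios)]
    return CounterfactualMatrix(values=np.column_stack(cols), labels=labels)


def select_scenario(matrix: CounterfactualMatrix, target) -> int:
    """Index (0-based) of the scenario whose response is nearest the target
    benchmark in Euclidean norm; ties broken by the lowest index."""
    vals = np.atleast_2d(matrix.values)
    if vals.size == 0 or vals.shape[1] == 0:
        raise ValueError("empty counterfactual matrix")
    target = np.atleast_1d(np.asarray(target, dtype=float))
    if target.shape[0] != vals.shape[0]:
        raise ValueError("target must be a q-vector")
    dists = np.linalg.norm(vals - target[:, None], axis=0)
    return int(np.argmin(dists))  # argmin takes the first minimum


# ----------------------------------------------------- attribution / mapping
def causal_gradients(model: ModelState, exposure_field, context, graph,
                     time_indices=None) -> np.ndarray:
    """Per-variable gradient-norm saliency gamma_{i,j}^t, shaped
    (node, exposure-variable, time)."""
    amap = attribution_scores(model, exposure_field, context, graph,
                              time_indices)
    return amap.per_variable


def vulnerability_map(gradients, priors: EpidemiologicalPriors,
                      time_indices=None) -> VulnerabilityMap:
    """Prior-weighted saliency: V(x_i, t) = sum_j gamma_{i,j}^t rho_j."""
    g = np.asarray(gradients, dtype=float)
    rho = priors.directions.astype(float)
    if g.ndim != 3 or g.shape[1] != rho.shape[0]:
        raise ValueError(
            f"gradients must be (node, variable, time) with {rho.shape[0]} variables"
        )
    return VulnerabilityMap(values=np.einsum("jvt,v->jt", g, rho),
                            time_indices=time_indices)


# -------------------------------------------------------------------- training
def total_loss(predictions, observed, propensities, model: ModelState,
               priors: EpidemiologicalPriors | None, graph, loss_config: LossConfig,
               *, exposure_field=None, context=None):
    """Composite objective: weighted error + monotonicity + smoothness.

    Returns (total, components).  When `predictions` is an autodiff Tensor
    the total is a Tensor (training path, tanh sign surrogate); otherwise
    plain floats with the exact eval-mode sign.
    """
    is_tensor = isinstance(predictions, Tensor)
    comps = {}
    zero = Tensor(0.0) if is_tensor else 0.0
    if loss_config.use_weighting:
        pi = propensities
        if pi is None:
            pi = np.ones(np.asarray(
                predictions.data if is_tensor else predictions).shape[0])
        weighted = ipw_loss(predictions, observed, pi, loss_config.epsilon,
                            clip=loss_config.clip)
    else:
        weighted = zero
    comps["weighted"] = float(weighted.data) if is_tensor else float(weighted)
    if loss_config.use_epi and priors is not None and loss_config.lambda_epi > 0:
        epi = epi_regularizer(model, exposure_field, priors,
                              "train" if is_tensor else "eval",
                              context=context, graph=graph,
                              kappa=loss_config.kappa,
                              strength=loss_config.lambda_epi)
    else:
        epi = zero
    comps["epi"] = float(epi.data) if isinstance(epi, Tensor) else float(epi)
    if loss_config.use_lap and loss_config.mu_lap > 0 and graph is not None:
        lap = laplacian_penalty(predictions, graph.laplacian, loss_config.mu_lap)
    else:
        lap = zero
    comps["laplacian"] = float(lap.data) if isinstance(lap, Tensor) else float(lap)
    total = weighted + epi + lap if is_tensor else (
        comps["weighted"] + comps["epi"] + comps["laplacian"])
    comps["total"] = float(total.data) if is_tensor else float(total)
    return total, comps


def train(model: ModelState, dataset: TrainingData, loss_config: LossConfig,
          optimizer_config: OptimizerConfig | None = None,
          seed: int | None = None) -> TrainResult:
    """Full-batch descent on the composite objective with adaptive moments.

    The loop is deterministic given the initialized model and data (the
    seed is recorded for provenance; all stochasticity lives in the model
    initialization and the data simulation).  Non-finite losses abort with
    a diagnostic.
    """
    opt_cfg = optimizer_config or OptimizerConfig()
    observed = dataset.outcomes.values if hasattr(dataset.outcomes, "values") \
        else np.asarray(dataset.outcomes, dtype=float)
    optimizer = Adam(model.params, lr=opt_cfg.lr)
    trace = []
    comp_trace = {"weighted": [], "epi": [], "laplacian": []}
    for epoch in range(opt_cfg.epochs):
        optimizer.zero_grad()
        pred = forward(dataset.exposure, dataset.context, dataset.graph,
                       model, return_tensor=True)
        loss, comps = total_loss(pred, observed, dataset.propensities, model,
                                 dataset.priors, dataset.graph, loss_config,
                                 exposure_field=dataset.exposure,
                                 context=dataset.context)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={val} "
                f"(components: {comps})"
            )
        trace.append(val)
        for k in comp_trace:
            comp_trace[k].append(comps[k])
        loss.backward()
        optimizer.step()
    return TrainResult(model=model, loss_trace=np.asarray(trace),
                       components={k: np.asarray(v) for k, v in comp_trace.items()})
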