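"""Spatiotemporal exposure-response network.

The predictive architecture maps a cube of exposure histories on a spatial
graph to health-outcome predictions.  Per prediction time t it composes:

1. a temporal encoder: two causal 1-D convolutions (kernel width 3,
   dilations 1 and 2, ReLU between) over the tau-step lookback window of
   each node, read out at the window's last step, giving a d-dim latent;
2. graph diffusion: a degree-K polynomial filter in the graph Laplacian,
   sum_k alpha_k L^k Z_t, with trainable coefficients alpha_k, mixing
   latents across nodes (K-hop spatial dependencies);
3. temporal self-attention: single-head scaled dot-product attention over
   the time axis of each node's diffused latent series;
4. adaptive contextual integration: a ReLU-embedded context vector is
   broadcast over nodes, added, layer-normalized, and modulated elementwise
   by a sigmoid policy gate;
5. a prediction head: one residual block (two dense layers of width d,
   ReLU) plus a linear readout to the q outcome variables.

Stages 2-4 can be disabled independently (ablation flags); a disabled stage
is an identity pass-through.  Everything is differentiable through the
:mod:`geoexposure.autodiff` tape, which is what the attribution maps and
the causal-aware training objective rely on.

Windows shorter than the convolution stack's receptive field are handled by
causal zero-padding inside the window, so any lookback tau >= 1 is valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .spatial import SpatialGraph, SpatioTemporalField

__all__ = [
    "ModelConfig",
    "ModelState",
    "ContextSeries",
    "AttributionMap",
    "init_model",
    "temporal_encode",
    "graph_diffuse",
    "temporal_attention",
    "context_embed",
    "contextual_fuse",
    "predict_health",
    "forward",
    "attribution_scores",
    "exposure_jacobian_blocks",
    "save_model",
    "load_model",
]

_CONV_WIDTH = 3
_CONV_DILATIONS = (1, 2)


# ----------------------------------------------------------------- containers
@dataclass
class ModelConfig:
    """Hyperparameters and ablation switches.

    d: latent width; diffusion_depth: polynomial filter degree K;
    tau: lookback window in steps; n_exposures/n_outcomes: p and q;
    context_dim / policy_dim: widths of the context and policy series
    (0 disables the corresponding input); use_gpl / use_tam / use_aci
    toggle graph diffusion, temporal attention, and contextual
    integration (context fusion + policy gate).  scale_laplacian
    rescales L by its largest eigenvalue before filtering (off by
    default; the filter then acts on the raw combinatorial Laplacian).
    """

    d: int = 8
    diffusion_depth: int = 2
    tau: int = 4
    n_exposures: int = 1
    n_outcomes: int = 1
    context_dim: int = 0
    policy_dim: int = 0
    use_gpl: bool = True
    use_tam: bool = True
    use_aci: bool = True
    scale_laplacian: bool = False
    layer_norm_eps: float = 1e-5


@dataclass
class ModelState:
    """Learnable parameters plus configuration and the init seed."""

    config: ModelConfig
    params: dict = dc_field(default_factory=dict)
    seed: int = 17


@dataclass
class ContextSeries:
    """External context (seasonality, socioeconomics) and policy series.

    `values` is (time, context_dim); `policy` is (time, policy_dim).
    Either may be empty (second axis of width 0).
    """

    values: np.ndarray
    policy: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.policy is not None:
            self.policy = np.atleast_2d(np.asarray(self.policy, dtype=float))
            if self.policy.shape[0] != self.values.shape[0]:
                raise ValueError("context and policy series must share the time axis")


@dataclass
class AttributionMap:
    """Gradient-norm relevance scores, (node, time); entries are norms >= 0."""

    scores: np.ndarray
    time_indices: np.ndarray
    per_variable: np.ndarray | None = None  # (node, exposure-variable, time)


# -------------------------------------------------------------- initialization
def _uniform(rng, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def init_model(config: ModelConfig, seed: int = 17) -> ModelState:
    """Seeded uniform fan-in initialization of every parameter tensor."""
    rng = np.random.default_rng(seed)
    d, p, q = config.d, config.n_exposures, config.n_outcomes
    K = config.diffusion_depth
    params: dict[str, Tensor] = {}

    def par(name, arr):
        params[name] = Tensor(arr, requires_grad=True)

    par("conv1_W", _uniform(rng, _CONV_WIDTH * p, (_CONV_WIDTH, p, d)))
    par("conv1_b", np.zeros(d))
    par("conv2_W", _uniform(rng, _CONV_WIDTH * d, (_CONV_WIDTH, d, d)))
    par("conv2_b", np.zeros(d))
    # alpha_0 = 1, rest 0: the filter starts as the identity
    alpha = np.zeros(K + 1)
    alpha[0] = 1.0
    par("alpha", alpha)
    par("Wq", _uniform(rng, d, (d, d)))
    par("Wk", _uniform(rng, d, (d, d)))
    par("Wv", _uniform(rng, d, (d, d)))
    if config.context_dim > 0:
        par("Wc", _uniform(rng, config.context_dim, (config.context_dim, d)))
        par("bc", np.zeros(d))
    if config.policy_dim > 0:
        par("Wp", _uniform(rng, config.policy_dim, (config.policy_dim, d)))
        par("bp", np.zeros(d))
    par("head1_W", _uniform(rng, d, (d, d)))
    par("head1_b", np.zeros(d))
    par("head2_W", _uniform(rng, d, (d, d)))
    par("head2_b", np.zeros(d))
    par("out_W", _uniform(rng, d, (d, q)))
    par("out_b", np.zeros(q))
    return ModelState(config=config, params=params, seed=seed)


# ------------------------------------------------------------------ components
def _causal_conv_full(x: Tensor, W: Tensor, b: Tensor, dilation: int) -> Tensor:
    """Causal 1-D convolution over axis 1 of (batch, time, channel).

    Output at step s uses inputs at s, s-dilation, s-2*dilation; steps
    before the series contribute zero (left padding inside the window).
    """
    T = x.shape[1]
    out = x @ W[0] + b
    for k in range(1, _CONV_WIDTH):
        shift = k * dilation
        if shift >= T:
            break
        shifted = ad.pad_axis(x, axis=1, left=shift)[:, :T, :]
        out = out + shifted @ W[k]
    return out


def _causal_conv_last(x: Tensor, W: Tensor, b: Tensor, dilation: int) -> Tensor:
    """Last-step output of the causal convolution: a (batch, channel) slice."""
    T = x.shape[1]
    out = x[:, T - 1, :] @ W[0] + b
    for k in range(1, _CONV_WIDTH):
        idx = T - 1 - k * dilation
        if idx < 0:
            break
        out = out + x[:, idx, :] @ W[k]
    return out


def temporal_encode(history, model: ModelState) -> Tensor:
    """Encode a (node, tau, p) exposure window into a (node, d) latent slice.

    Deterministic given parameters; the stack is conv(dil 1) -> ReLU ->
    conv(dil 2), read out at the window's final step.
    """
    x = ad.tensor(history)
    if x.ndim != 3:
        raise ValueError("history must be (node, tau_steps, exposure-variable)")
    cfg = model.config
    if x.shape[1] != cfg.tau:
        raise ValueError(f"window length {x.shape[1]} != model tau {cfg.tau}")
    if x.shape[2] != cfg.n_exposures:
        raise ValueError("exposure-variable axis does not match model config")
    p = model.params
    h = ad.relu(_causal_conv_full(x, p["conv1_W"], p["conv1_b"], _CONV_DILATIONS[0]))
    return _causal_conv_last(h, p["conv2_W"], p["conv2_b"], _CONV_DILATIONS[1])


def graph_diffuse(latent_slice, laplacian, diffusion_coeffs) -> Tensor:
    """Polynomial graph filter sum_k alpha_k L^k Z by iterated products.

    `latent_slice` is (N, d) or (N, T', d); the Laplacian contracts the
    node axis.  Matrix powers are never formed explicitly — only the
    running product L(L(...Z)).
    """
    Z = ad.tensor(latent_slice)
    L = ad.tensor(laplacian)
    alpha = ad.tensor(diffusion_coeffs)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("laplacian must be square")
    if Z.shape[0] != L.shape[0]:
        raise ValueError(
            f"latent node axis {Z.shape[0]} does not match laplacian {L.shape[0]}"
        )
    orig_shape = Z.shape
    flat = Z if Z.ndim == 2 else Z.reshape(orig_shape[0], -1)
    acc = alpha[0] * flat
    cur = flat
    for k in range(1, alpha.shape[0]):
        cur = L @ cur
        acc = acc + alpha[k] * cur
    return acc if Z.ndim == 2 else acc.reshape(orig_shape)


def temporal_attention(diffused_series, model: ModelState) -> Tensor:
    """Single-head scaled dot-product attention over the time axis, per node."""
    Z = ad.tensor(diffused_series)
    if Z.ndim != 3:
        raise ValueError("series must be (node, time, d)")
    d = model.config.d
    if d == 0:
        raise ValueError("latent dimension must be positive")
    p = model.params
    Q = Z @ p["Wq"]
    K = Z @ p["Wk"]
    V = Z @ p["Wv"]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
    weights = ad.softmax(scores, axis=-1)
    return weights @ V


def attention_weights(diffused_series, model: ModelState) -> np.ndarray:
    """The (node, time, time) softmax attention matrix (rows sum to 1)."""
    Z = ad.tensor(diffused_series)
    p = model.params
    Q, K = Z @ p["Wq"], Z @ p["Wk"]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(model.config.d))
    return ad.softmax(scores, axis=-1).data


def context_embed(context_vector, model: ModelState) -> Tensor:
    """ReLU feedforward embedding of a context vector (or (time, dim) series)."""
    c = ad.tensor(context_vector)
    p = model.params
    if "Wc" not in p:
        raise ValueError("model was built without a context pathway (context_dim=0)")
    if c.shape[-1] != p["Wc"].shape[0]:
        raise ValueError(
            f"context dimension {c.shape[-1]} != expected {p['Wc'].shape[0]}"
        )
    squeeze = c.ndim == 1
    if squeeze:
        c = c.reshape(1, -1)
    out = ad.relu(c @ p["Wc"] + p["bc"])
    return out.reshape(-1) if squeeze else out


def contextual_fuse(attended_slice, context_embedding,
                    eps: float = 1e-5) -> Tensor:
    """Broadcast the context embedding over nodes, add, and layer-normalize.

    Normalization is over the latent axis per (node, time) with no
    learnable affine; requires d >= 2 (the per-row variance is otherwise
    degenerate).
    """
    U = ad.tensor(attended_slice)
    C = ad.tensor(context_embedding)
    if U.shape[-1] < 2:
        raise ValueError("layer normalization requires latent dimension >= 2")
    if U.ndim == 3 and C.ndim == 2:
        C = C.reshape(1, C.shape[0], C.shape[1])
    return ad.layer_norm(U + C, eps=eps)


def _policy_gate_tensor(policy_vector, model: ModelState) -> Tensor:
    P = ad.tensor(policy_vector)
    p = model.params
    if "Wp" not in p:
        raise ValueError("model was built without a policy pathway (policy_dim=0)")
    if P.shape[-1] != p["Wp"].shape[0]:
        raise ValueError(
            f"policy dimension {P.shape[-1]} != expected {p['Wp'].shape[0]}"
        )
    squeeze = P.ndim == 1
    if squeeze:
        P = P.reshape(1, -1)
    out = ad.sigmoid(P @ p["Wp"] + p["bp"])
    return out.reshape(-1) if squeeze else out


def predict_health(fused_slice, model: ModelState) -> Tensor:
    """Residual MLP head: two dense layers of width d, ReLU, skip connection,
    then a linear map to the q outcome variables."""
    U = ad.tensor(fused_slice)
    p = model.params
    h = ad.relu(U @ p["head1_W"] + p["head1_b"])
    h = ad.relu(h @ p["head2_W"] + p["head2_b"])
    block = U + h
    return block @ p["out_W"] + p["out_b"]


# --------------------------------------------------------------- forward pass
def _as_exposure_array(exposure) -> np.ndarray:
    if isinstance(exposure, SpatioTemporalField):
        return exposure.values
    return np.asarray(exposure, dtype=float)


def _effective_laplacian(graph: SpatialGraph, config: ModelConfig) -> np.ndarray:
    L = graph.laplacian
    if config.scale_laplacian:
        lam = np.max(np.abs(np.linalg.eigvalsh(L)))
        if lam > 0:
            L = L / lam
    return L


def forward(exposure_field, context: ContextSeries | None, graph: SpatialGraph | None,
            model: ModelState, *, return_tensor: bool = False,
            exposure_tensor: Tensor | None = None):
    """Run the full pipeline over every time index with a complete window.

    Returns predictions shaped (N, T - tau + 1, q); prediction index t'
    corresponds to original time index t' + tau - 1.  Disabled stages are
    identity pass-throughs.  Pass `return_tensor=True` (training,
    attribution) to keep the autodiff graph; `exposure_tensor` overrides
    the exposure input with an existing graph node.
    """
    cfg = model.config
    if exposure_tensor is not None:
        E = exposure_tensor
    else:
        E = ad.tensor(_as_exposure_array(exposure_field))
    if E.ndim != 3:
        raise ValueError("exposure must be (node, time, variable)")
    N, T, p = E.shape
    if p != cfg.n_exposures:
        raise ValueError(f"exposure variables {p} != model config {cfg.n_exposures}")
    if T < cfg.tau:
        raise ValueError(f"series length {T} shorter than lookback tau={cfg.tau}")
    Tprime = T - cfg.tau + 1

    # all lookback windows at once: (N, T', tau, p) -> (N*T', tau, p)
    win_idx = np.arange(Tprime)[:, None] + np.arange(cfg.tau)[None, :]
    windows = E[:, win_idx, :].reshape(N * Tprime, cfg.tau, p)
    Z = temporal_encode(windows, model).reshape(N, Tprime, cfg.d)

    if cfg.use_gpl:
        if graph is None:
            raise ValueError("graph required when the diffusion stage is enabled")
        L = _effective_laplacian(graph, cfg)
        Z = graph_diffuse(Z, L, model.params["alpha"])

    if cfg.use_tam:
        Z = temporal_attention(Z, model)

    if cfg.use_aci:
        if context is None:
            raise ValueError("context required when contextual integration is enabled")
        if cfg.context_dim > 0:
            cvals = context.values[cfg.tau - 1 :]
            if cvals.shape[0] != Tprime:
                raise ValueError("context series does not cover the prediction times")
            Z = contextual_fuse(Z, context_embed(cvals, model),
                                eps=cfg.layer_norm_eps)
        if cfg.policy_dim > 0:
            if context.policy is None:
                raise ValueError("policy series required (policy_dim > 0)")
            pvals = context.policy[cfg.tau - 1 :]
            if pvals.shape[0] != Tprime:
                raise ValueError("policy series does not cover the prediction times")
            zeta = _policy_gate_tensor(pvals, model)
            Z = Z * zeta.reshape(1, Tprime, cfg.d)

    out = predict_health(Z, model)
    return out if return_tensor else out.data


# -------------------------------------------------------------- interpretation
def exposure_jacobian_blocks(model: ModelState, exposure_field, context,
                             graph, time_indices=None,
                             nodes=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-node own-window Jacobian blocks of the predictions.

    For each selected prediction time t and node i, the block
    d H_hat_t(i, :) / d E(i, t-tau+1 : t, :) of shape (q, tau, p) is
    extracted by one reverse-mode sweep per (node, time, outcome) —
    cross-node dependence through diffusion and attention makes the
    node-diagonal blocks irreducible to fewer sweeps.  Returns
    (blocks, time_indices) with blocks shaped (n_nodes, n_times, q, tau, p)
    indexed on prediction times.
    """
    E_np = _as_exposure_array(exposure_field)
    cfg = model.config
    N, T, p = E_np.shape
    Tprime = T - cfg.tau + 1
    if time_indices is None:
        time_indices = np.arange(Tprime)
    time_indices = np.atleast_1d(np.asarray(time_indices, dtype=int))
    node_sel = np.arange(N) if nodes is None else np.atleast_1d(np.asarray(nodes))
    q = cfg.n_outcomes
    blocks = np.zeros((len(node_sel), len(time_indices), q, cfg.tau, p))
    # one forward graph, many reverse sweeps (grads cleared between sweeps)
    E_t = Tensor(E_np, requires_grad=True)
    pred = forward(None, context, graph, model,
                   return_tensor=True, exposure_tensor=E_t)
    graph_nodes = _collect_graph(pred)
    for ti, tp in enumerate(time_indices):
        for k in range(q):
            for ni, i in enumerate(node_sel):
                for node in graph_nodes:
                    node.grad = None
                seed = np.zeros_like(pred.data)
                seed[int(i), int(tp), k] = 1.0
                pred.backward(seed)
                blocks[ni, ti, k] = E_t.grad[int(i), tp : tp + cfg.tau, :]
    return blocks, time_indices


def _collect_graph(root: Tensor) -> list[Tensor]:
    seen: set[int] = set()
    out: list[Tensor] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        out.append(node)
        stack.extend(node._parents)
    return out


def attribution_scores(model: ModelState, exposure_field, context,
                       graph, time_indices=None) -> AttributionMap:
    """Relevance attribution: Euclidean norm of each node's own-window
    prediction Jacobian (over outcomes, lags and exposure variables).

    Also fills the per-exposure-variable scores used by the vulnerability
    map.  All scores are nonnegative by construction.
    """
    blocks, tsel = exposure_jacobian_blocks(model, exposure_field, context,
                                            graph, time_indices)
    n, t = blocks.shape[:2]
    scores = np.sqrt((blocks**2).sum(axis=(2, 3, 4)))
    per_var = np.sqrt((blocks**2).sum(axis=(2, 3)))  # (node, time, p)
    return AttributionMap(scores=scores, time_indices=tsel,
                          per_variable=np.moveaxis(per_var, 2, 1))


# ----------------------------------------------------------------- checkpoints
def save_model(model: ModelState, path) -> None:
    """Write a checkpoint: config/seed header plus full-precision arrays."""
    doc = {
        "format": "geoexposure-checkpoint-v1",
        "config": asdict(model.config),
        "seed": model.seed,
        "params": {
            k: {"shape": list(v.data.shape), "data": v.data.ravel().tolist()}
            for k, v in model.params.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ModelState:
    """Load a checkpoint, validating every parameter shape against config."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "geoexposure-checkpoint-v1":
        raise ValueError("not a recognized checkpoint file")
    config = ModelConfig(**doc["config"])
    reference = init_model(config, seed=doc["seed"])
    params = {}
    for k, spec in doc["params"].items():
        arr = np.asarray(spec["data"], dtype=float).reshape(spec["shape"])
        if k not in reference.params:
            raise ValueError(f"unexpected parameter {k!r} in checkpoint")
        if arr.shape != reference.params[k].data.shape:
            raise ValueError(
                f"parameter {k!r} shape {arr.shape} inconsistent with config"
            )
        params[k] = Tensor(arr, requires_grad=True)
    missing = set(reference.params) - set(params)
    if missing:
        raise ValueError(f"checkpoint missing parameters: {sorted(missing)}")
    return ModelState(config=config, params=params, seed=doc["seed"])
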