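"""Classical causal baselines and comparison metrics.

Given a unit table of (binary treatment, confounders, outcome), this module
provides the unadjusted difference of means, inverse-probability-of-
treatment weighting (IPTW, ATE estimand) and 1:1 propensity-score matching
(PSM, ATT estimand), together with the diagnostics used to compare them:
standardized mean differences for covariate balance, mean squared error
for predictive accuracy, and a bootstrap effect-stability score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cam import fit_propensity, propensity_score, PropensityModel

__all__ = [
    "CausalDataset",
    "EffectEstimate",
    "naive_estimate",
    "iptw_estimate",
    "psm_estimate",
    "standardized_mean_difference",
    "mse",
    "effect_stability",
    "compare_methods",
    "read_causal_csv",
    "write_causal_csv",
]

_CLIP = (0.01, 0.99)


@dataclass
class CausalDataset:
    """One row per unit: binary treatment, confounder vector, outcome."""

    unit_ids: list
    treatment: np.ndarray
    confounders: np.ndarray
    outcome: np.ndarray

    def __post_init__(self):
        self.treatment = np.asarray(self.treatment, dtype=int)
        self.confounders = np.atleast_2d(np.asarray(self.confounders, dtype=float))
        self.outcome = np.asarray(self.outcome, dtype=float)
        n = len(self.treatment)
        if self.confounders.shape[0] != n or self.outcome.shape[0] != n:
            raise ValueError("treatment, confounders and outcome must align")
        if not np.all(np.isin(self.treatment, (0, 1))):
            raise ValueError("treatment must be binary 0/1")
        if not (np.all(np.isfinite(self.confounders))
                and np.all(np.isfinite(self.outcome))):
            raise ValueError("missing or non-finite entries are not allowed")

    @property
    def n_units(self) -> int:
        return len(self.treatment)

    def subset(self, idx) -> "CausalDataset":
        idx = np.asarray(idx)
        return CausalDataset(
            unit_ids=[self.unit_ids[i] for i in idx],
            treatment=self.treatment[idx],
            confounders=self.confounders[idx],
            outcome=self.outcome[idx],
        )


@dataclass
class EffectEstimate:
    estimate: float
    n_used: int
    method: str
    estimand: str
    smd_before: np.ndarray | None = None
    smd_after: np.ndarray | None = None
    extras: dict = dc_field(default_factory=dict)


def _check_arms(ds: CausalDataset) -> None:
    if (ds.treatment == 1).sum() == 0 or (ds.treatment == 0).sum() == 0:
        raise ValueError("both treatment arms must be nonempty")


# ------------------------------------------------------------------ estimators
def naive_estimate(dataset: CausalDataset) -> EffectEstimate:
    """Unadjusted difference of arm means (the bias-comparison control)."""
    _check_arms(dataset)
    t = dataset.treatment.astype(bool)
    est = dataset.outcome[t].mean() - dataset.outcome[~t].mean()
    smd, _ = standardized_mean_difference(dataset)
    return EffectEstimate(estimate=float(est), n_used=dataset.n_units,
                          method="naive", estimand="ATE", smd_before=smd,
                          smd_after=smd)


def iptw_estimate(dataset: CausalDataset,
                  propensity_model: PropensityModel | None = None) -> EffectEstimate:
    """Self-normalized Horvitz-Thompson weighted difference of means (ATE).

    Treated units are weighted 1/pi, controls 1/(1-pi), with propensities
    clipped to [0.01, 0.99] as a positivity guard.  Self-normalization
    makes the estimate invariant to a common rescaling of the weights.
    """
    _check_arms(dataset)
    pm = propensity_model or fit_propensity(dataset)
    pi = np.clip(propensity_score(dataset.confounders, pm), *_CLIP)
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("degenerate propensities after clipping")
    t = dataset.treatment.astype(bool)
    w = np.where(t, 1.0 / pi, 1.0 / (1.0 - pi))
    y = dataset.outcome
    mean_t = np.sum(w[t] * y[t]) / np.sum(w[t])
    mean_c = np.sum(w[~t] * y[~t]) / np.sum(w[~t])
    smd_before, _ = standardized_mean_difference(dataset)
    smd_after, _ = standardized_mean_difference(dataset, weights=w)
    return EffectEstimate(estimate=float(mean_t - mean_c), n_used=dataset.n_units,
                          method="IPTW", estimand="ATE",
                          smd_before=smd_before, smd_after=smd_after,
                          extras={"weights": w, "propensities": pi})


def psm_estimate(dataset: CausalDataset, caliper: float | None = None,
                 propensity_model: PropensityModel | None = None) -> EffectEstimate:
    """1:1 nearest-neighbour matching on the propensity logit (ATT).

    Greedy matching without replacement, treated units processed in
    descending propensity order; the caliper defaults to 0.2 standard
    deviations of the logit.  Unmatched treated units are dropped and
    counted; zero matches is an error.
    """
    _check_arms(dataset)
    pm = propensity_model or fit_propensity(dataset)
    pi = np.clip(propensity_score(dataset.confounders, pm), *_CLIP)
    logit = np.log(pi / (1.0 - pi))
    if caliper is None:
        sd = logit.std(ddof=1) if len(logit) > 1 else 0.0
        caliper = 0.2 * sd
    t_idx = np.where(dataset.treatment == 1)[0]
    c_idx = np.where(dataset.treatment == 0)[0]
    order = t_idx[np.argsort(-pi[t_idx], kind="stable")]
    available = np.ones(len(c_idx), dtype=bool)
    pairs = []
    for i in order:
        if not available.any():
            break
        dists = np.abs(logit[c_idx] - logit[i])
        dists[~available] = np.inf
        j = int(np.argmin(dists))
        if dists[j] <= caliper:
            pairs.append((i, c_idx[j]))
            available[j] = False
    if not pairs:
        raise ValueError("no matches found within the caliper")
    ti = np.array([p[0] for p in pairs])
    ci = np.array([p[1] for p in pairs])
    est = float(np.mean(dataset.outcome[ti] - dataset.outcome[ci]))
    matched = dataset.subset(np.concatenate([ti, ci]))
    smd_before, _ = standardized_mean_difference(dataset)
    smd_after, _ = standardized_mean_difference(matched)
    return EffectEstimate(
        estimate=est, n_used=2 * len(pairs), method="PSM", estimand="ATT",
        smd_before=smd_before, smd_after=smd_after,
        extras={"n_treated_unmatched": int(len(t_idx) - len(pairs)),
                "caliper": float(caliper)},
    )


# -------------------------------------------------------------------- metrics
def _weighted_moments(x, w):
    wsum = w.sum()
    mean = np.sum(w * x) / wsum
    var = np.sum(w * (x - mean) ** 2) / wsum
    return mean, var


def standardized_mean_difference(dataset: CausalDataset,
                                 weights: np.ndarray | None = None):
    """Per-covariate |mean_T - mean_C| / sqrt((var_T + var_C) / 2).

    Unweighted variances use the n-1 denominator; with weights, weighted
    means and (population-style) weighted variances are used.  A covariate
    with zero pooled variance is reported as SMD 0 with a warning.
    Returns (per-covariate vector, average).
    """
    t = dataset.treatment.astype(bool)
    Z = dataset.confounders
    k = Z.shape[1]
    out = np.zeros(k)
    for j in range(k):
        zt, zc = Z[t, j], Z[~t, j]
        if weights is None:
            mt, mc = zt.mean(), zc.mean()
            vt = zt.var(ddof=1) if len(zt) > 1 else 0.0
            vc = zc.var(ddof=1) if len(zc) > 1 else 0.0
        else:
            w = np.asarray(weights, dtype=float)
            mt, vt = _weighted_moments(zt, w[t])
            mc, vc = _weighted_moments(zc, w[~t])
        pooled = (vt + vc) / 2.0
        if pooled <= 0:
            warnings.warn(
                f"covariate {j} has zero pooled variance; SMD reported as 0",
                RuntimeWarning, stacklevel=2)
            out[j] = 0.0
        else:
            out[j] = abs(mt - mc) / np.sqrt(pooled)
    return out, float(out.mean())


def mse(predictions, truth) -> float:
    """Mean squared error over aligned arrays."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != t.shape:
        raise ValueError("predictions and truth must align")
    return float(np.mean((p - t) ** 2))


def effect_stability(estimator, dataset: CausalDataset, B: int,
                     seed: int) -> float:
    """Bootstrap consistency of an effect estimator, in [0, 1].

    B per-arm stratified resamples with replacement; stability is
    clip(1 - sd / (|mean| + 1e-12), 0, 1).  Failing resamples are skipped
    and counted; more than 20% failures is an error.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    t_idx = np.where(dataset.treatment == 1)[0]
    c_idx = np.where(dataset.treatment == 0)[0]
    estimates, failures = [], 0
    for _ in range(B):
        idx = np.concatenate([
            rng.choice(t_idx, size=len(t_idx), replace=True),
            rng.choice(c_idx, size=len(c_idx), replace=True),
        ])
        try:
            res = estimator(dataset.subset(idx))
            estimates.append(res.estimate if isinstance(res, EffectEstimate)
                             else float(res))
        except Exception:
            failures += 1
    if failures > 0.2 * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap resamples failed; estimator too fragile")
    est = np.asarray(estimates)
    sd = est.std(ddof=1)
    return float(np.clip(1.0 - sd / (abs(est.mean()) + 1e-12), 0.0, 1.0))


def compare_methods(dataset: CausalDataset, B: int = 100, seed: int = 0,
                    predictions=None, truth=None) -> dict:
    """Side-by-side report of naive, IPTW and PSM on one dataset.

    Returns {method: {estimate, estimand, avg_smd, stability[, mse]}};
    prediction MSE is included only when model predictions and reference
    values are supplied (the balance/stability metrics do not need them).
    """
    methods = {
        "naive": naive_estimate,
        "IPTW": iptw_estimate,
        "PSM": psm_estimate,
    }
    report = {}
    for name, fn in methods.items():
        est = fn(dataset)
        smd_vec = est.smd_after if est.smd_after is not None else est.smd_before
        entry = {
            "estimate": est.estimate,
            "estimand": est.estimand,
            "avg_smd": float(np.mean(smd_vec)),
            "stability": effect_stability(fn, dataset, B=B, seed=seed),
        }
        if predictions is not None and truth is not None:
            entry["mse"] = mse(predictions, truth)
        report[name] = entry
    return report


# ------------------------------------------------------------------------- IO
def read_causal_csv(path) -> CausalDataset:
    """Read `unit_id,treatment,outcome,z1..zk` delimited text."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"unit_id", "treatment", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"causal table missing columns: {sorted(missing)}")
    zcols = [c for c in df.columns if c not in required]
    if not zcols:
        raise ValueError("causal table has no confounder columns")
    return CausalDataset(
        unit_ids=df["unit_id"].tolist(),
        treatment=df["treatment"].to_numpy(),
        confounders=df[zcols].to_numpy(dtype=float),
        outcome=df["outcome"].to_numpy(dtype=float),
    )


def write_causal_csv(dataset: CausalDataset, path) -> None:
    cols = {"unit_id": dataset.unit_ids, "treatment": dataset.treatment,
            "outcome": dataset.outcome}
    for j in range(dataset.confounders.shape[1]):
        cols[f"z{j+1}"] = dataset.confounders[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
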