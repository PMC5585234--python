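"""Single-hidden-layer neural-network transfer functions with median ensembling.

The network is the classic nnet-style regressor: one hidden layer of logistic
units, a linear output, squared-error loss (optionally with weight decay),
trained by quasi-Newton minimization (L-BFGS-B) from small random initial
weights.  Because the loss surface is multimodal, a single fit is an
unreliable estimator; the transfer function is therefore an *ensemble*: many
replicates differing only in their (seeded) weight initialization, aggregated
per cell by the median, with the inter-replicate IQR as a stability
diagnostic.

A hard cap on the total number of weights — (n_inputs + 1) * n_hidden +
n_hidden + 1 — guards against over-parameterized configurations; training
refuses to start if the architecture exceeds it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "AnnConfig",
    "AnnReplicate",
    "AnnEnsemble",
    "WeightCapError",
    "weight_count",
    "train_ann",
    "train_ensemble",
    "predict_ensemble",
    "internal_validation",
]


class WeightCapError(ValueError):
    """Architecture exceeds the configured weight budget."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(f"network needs {count} weights, cap is {cap}")


def weight_count(n_inputs: int, n_hidden: int) -> int:
    """Total weights of a single-hidden-layer net incl. biases."""
    return (n_inputs + 1) * n_hidden + n_hidden + 1


@dataclass(frozen=True)
class AnnConfig:
    n_hidden: int = 5
    max_iterations: int = 100_000
    max_weights: int = 1000
    n_replicates: int = 1000
    base_seed: int = 0
    weight_decay: float = 0.0
    gradient_tol: float = 1e-6
    ftol: float = 1e-15
    init_scale: float = 0.5
    max_failed_fraction: float = 0.2

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")


@dataclass
class AnnReplicate:
    weights: np.ndarray
    converged: bool
    sse: float
    n_iter: int


def _unpack(w: np.ndarray, n_in: int, h: int):
    i = (n_in + 1) * h
    W1 = w[:i].reshape(n_in + 1, h)
    W2 = w[i:].reshape(h + 1, 1)
    return W1, W2


def _loss_grad(w, Xb, y, n_in, h, decay):
    W1, W2 = _unpack(w, n_in, h)
    a = Xb @ W1
    z = expit(a)
    zb = np.column_stack([np.ones(len(z)), z])
    out = (zb @ W2).ravel()
    err = out - y
    f = 0.5 * err @ err + 0.5 * decay * (w @ w)

    gW2 = zb.T @ err[:, None]
    dz = err[:, None] * W2[1:, 0][None, :] * z * (1 - z)
    gW1 = Xb.T @ dz
    g = np.concatenate([gW1.ravel(), gW2.ravel()]) + decay * w
    return f, g


def train_ann(
    calibration: pd.DataFrame | np.ndarray,
    env: pd.Series | np.ndarray,
    config: AnnConfig,
    replicate_index: int = 0,
) -> AnnReplicate:
    """Train one replicate, deterministic in (base_seed, replicate_index).

    Inputs and target are standardized internally from the calibration data;
    the returned weights act on standardized quantities (the ensemble stores
    the constants and back-transforms).
    """
    X = np.asarray(calibration, dtype=float)
    y = np.asarray(env, dtype=float)
    n, n_in = X.shape
    if n < 2:
        raise ValueError("need at least 2 calibration cells")
    nw = weight_count(n_in, config.n_hidden)
    if nw > config.max_weights:
        raise WeightCapError(nw, config.max_weights)

    xm, xs = X.mean(axis=0), X.std(axis=0)
    xs = np.where(xs == 0, 1.0, xs)
    ym, ys = y.mean(), y.std()
    ys = ys if ys > 0 else 1.0
    Xs = (X - xm) / xs
    ysn = (y - ym) / ys
    Xb = np.column_stack([np.ones(n), Xs])

    rng = np.random.default_rng([int(config.base_seed), int(replicate_index)])
    w0 = rng.uniform(-config.init_scale, config.init_scale, nw)

    res = minimize(
        _loss_grad,
        w0,
        args=(Xb, ysn, n_in, config.n_hidden, config.weight_decay),
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "gtol": config.gradient_tol,
            "ftol": config.ftol,
        },
    )
    # status 1 = iteration cap reached: a normal stopping rule here (the cap
    # is part of the training protocol), not an optimizer failure
    usable = bool(res.success) or res.status == 1
    return AnnReplicate(
        weights=res.x,
        converged=usable,
        sse=float(res.fun),
        n_iter=int(res.nit),
    )


@dataclass
class AnnEnsemble:
    """A bag of trained replicates sharing architecture and standardization."""

    config: AnnConfig
    taxa: list
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    replicates: list = field(default_factory=list)
    n_failed: int = 0

    def _forward(self, w: np.ndarray, Xs: np.ndarray) -> np.ndarray:
        W1, W2 = _unpack(w, len(self.taxa), self.config.n_hidden)
        Xb = np.column_stack([np.ones(len(Xs)), Xs])
        z = expit(Xb @ W1)
        zb = np.column_stack([np.ones(len(z)), z])
        return (zb @ W2).ravel() * self.y_std + self.y_mean

    def predict_all(self, assemblages: pd.DataFrame) -> np.ndarray:
        """Replicates x cells prediction matrix (columns aligned, zero-filled)."""
        aligned = assemblages.reindex(columns=self.taxa, fill_value=0.0)
        Xs = (aligned.to_numpy(dtype=float) - self.x_mean) / self.x_std
        return np.vstack([self._forward(r.weights, Xs) for r in self.replicates])

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "config": self.config.__dict__,
            "taxa": list(self.taxa),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "n_failed": self.n_failed,
            "replicates": [
                {
                    "weights": r.weights.tolist(),
                    "converged": r.converged,
                    "sse": r.sse,
                    "n_iter": r.n_iter,
                }
                for r in self.replicates
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AnnEnsemble":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=AnnConfig(**d["config"]),
            taxa=d["taxa"],
            x_mean=np.asarray(d["x_mean"]),
            x_std=np.asarray(d["x_std"]),
            y_mean=d["y_mean"],
            y_std=d["y_std"],
            n_failed=d["n_failed"],
            replicates=[
                AnnReplicate(
                    weights=np.asarray(r["weights"]),
                    converged=r["converged"],
                    sse=r["sse"],
                    n_iter=r["n_iter"],
                )
                for r in d["replicates"]
            ],
        )


def train_ensemble(
    calibration: pd.DataFrame, env: pd.Series | np.ndarray, config: AnnConfig
) -> AnnEnsemble:
    """Train ``config.n_replicates`` seeded replicates and keep the converged ones.

    Non-converged replicates are dropped with a logged count; the run fails
    outright if more than ``max_failed_fraction`` of them fail.
    """
    X = calibration.to_numpy(dtype=float)
    y = np.asarray(env, dtype=float)
    xm, xs = X.mean(axis=0), X.std(axis=0)
    xs = np.where(xs == 0, 1.0, xs)
    ys = y.std()
    ens = AnnEnsemble(
        config=config,
        taxa=list(calibration.columns),
        x_mean=xm,
        x_std=xs,
        y_mean=float(y.mean()),
        y_std=float(ys if ys > 0 else 1.0),
    )
    kept, failed = [], 0
    for r in range(config.n_replicates):
        rep = train_ann(calibration, y, config, replicate_index=r)
        if rep.converged:
            kept.append(rep)
        else:
            failed += 1
    if failed:
        logger.info("train_ensemble: dropped %d / %d non-converged replicates",
                    failed, config.n_replicates)
    if failed > config.max_failed_fraction * config.n_replicates:
        raise RuntimeError(
            f"{failed}/{config.n_replicates} replicates failed to converge"
        )
    if not kept:
        raise RuntimeError("no replicate converged")
    ens.replicates = kept
    ens.n_failed = failed
    return ens


def predict_ensemble(
    ensemble: AnnEnsemble, assemblages: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell median prediction across replicates, with IQR spread."""
    if not ensemble.replicates:
        raise RuntimeError("ensemble holds no converged replicates")
    P = ensemble.predict_all(assemblages)
    q25, med, q75 = np.percentile(P, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {"prediction": med, "iqr": q75 - q25}, index=assemblages.index
    )


def internal_validation(
    calibration: pd.DataFrame,
    env: pd.Series,
    config: AnnConfig,
    latitudes: pd.Series | None = None,
) -> pd.DataFrame:
    """Resubstitution check: train on the calibration set, predict it back.

    Returns a per-cell table of observed, predicted (ensemble median) and
    signed deviation (observed - predicted), with latitude attached when
    provided for profile summaries.
    """
    ens = train_ensemble(calibration, env, config)
    pred = predict_ensemble(ens, calibration)
    out = pd.DataFrame(
        {
            "observed": np.asarray(env, dtype=float),
            "predicted": pred["prediction"].to_numpy(),
        },
        index=calibration.index,
    )
    out["deviation"] = out["observed"] - out["predicted"]
    if latitudes is not None:
        out["lat"] = np.asarray(latitudes, dtype=float)
    return out
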