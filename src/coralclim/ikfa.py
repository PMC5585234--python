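"""Imbrie-Kipp factor-analysis transfer functions, from first principles.

The classic micropaleontological recipe for turning assemblage composition
into an environmental estimate:

1. **Q-mode scaling** — each sample (cell) vector of taxon proportions is
   scaled to unit Euclidean length, so samples are compared by composition
   shape, not by richness or sampling intensity.
2. **Rank-k decomposition** — a truncated SVD of the scaled matrix W gives
   sample loadings F (n x k) and taxon scores A (p x k) with W ~= F A'.
   Factors are end-member assemblages.
3. **Varimax rotation** — an orthogonal rotation of the factors maximizing
   the variance of squared loadings, for sparse, interpretable end members.
   Rotation never changes the fitted environment values (the regression
   absorbs any orthogonal rotation); it fixes a reproducible, interpretable
   basis.
4. **Regression** — least squares of the environmental variable(s) on the
   rotated sample loadings (optionally with squared and cross terms).
5. **Projection** — a fossil sample is unit-scaled, projected onto the taxon
   scores to estimate its loadings, and pushed through the regression.  The
   *communality* (squared norm of the projected part of the unit row) says
   how much of the fossil composition the modern factor space explains; low
   communality flags no-analog assemblages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IkfaModel", "fit_ikfa", "predict_ikfa", "varimax", "varimax_criterion"]


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax simplicity: sum over factors of the variance of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float((L2**2).mean(axis=0).sum() - (L2.mean(axis=0) ** 2).sum())


def varimax(
    loadings: np.ndarray, tol: float = 1e-12, max_sweeps: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser varimax rotation (raw, no row normalization).

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation`` and
    ``rotation`` orthogonal, so row communalities are preserved exactly.
    k = 1 returns the input with an identity rotation.  Non-convergence within
    ``max_sweeps`` emits a warning and returns the best iterate.
    """
    L = np.asarray(loadings, dtype=float)
    n, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)

    R = np.eye(k)
    d_old = 0.0
    converged = False
    for _ in range(max_sweeps):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / n)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d = s.sum()
        if d_old > 0 and d <= d_old * (1 + tol):
            converged = True
            break
        d_old = d
    if not converged:
        warnings.warn("varimax did not converge; returning best iterate")
    return L @ R, R


@dataclass
class IkfaModel:
    """A fitted Imbrie-Kipp factor-analysis transfer function."""

    taxa: list
    taxon_scores: np.ndarray          # p x k, rotated, orthonormal columns
    rotation: np.ndarray              # k x k orthogonal
    coefficients: dict                # env var -> coefficient vector
    k: int
    quadratic: bool = False
    row_norm: str = "unit_length"     # or "none"
    communality_threshold: float = 0.5
    calibration_stats: dict = field(default_factory=dict)

    @property
    def env_vars(self) -> list:
        return list(self.coefficients)

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "taxa": list(self.taxa),
            "taxon_scores": self.taxon_scores.tolist(),
            "rotation": self.rotation.tolist(),
            "coefficients": {k: v.tolist() for k, v in self.coefficients.items()},
            "k": self.k,
            "quadratic": self.quadratic,
            "row_norm": self.row_norm,
            "communality_threshold": self.communality_threshold,
            "calibration_stats": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.calibration_stats.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "IkfaModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            taxa=d["taxa"],
            taxon_scores=np.asarray(d["taxon_scores"]),
            rotation=np.asarray(d["rotation"]),
            coefficients={k: np.asarray(v) for k, v in d["coefficients"].items()},
            k=d["k"],
            quadratic=d["quadratic"],
            row_norm=d["row_norm"],
            communality_threshold=d["communality_threshold"],
            calibration_stats=d.get("calibration_stats", {}),
        )


def _unit_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return X / safe[:, None], norms


def _design(F: np.ndarray, quadratic: bool) -> np.ndarray:
    cols = [np.ones(len(F)), *F.T]
    if quadratic:
        k = F.shape[1]
        for i in range(k):
            for j in range(i, k):
                cols.append(F[:, i] * F[:, j])
    return np.column_stack(cols)


def fit_ikfa(
    calibration: pd.DataFrame,
    env: pd.DataFrame | pd.Series,
    k: int = 5,
    quadratic: bool = False,
    row_norm: str = "unit_length",
    communality_threshold: float = 0.5,
) -> IkfaModel:
    """Fit the transfer function on a calibration set.

    Parameters
    ----------
    calibration
        Cells x taxa proportions (rows sum to 1), taxon names as columns.
    env
        Per-cell environmental values (Series, or DataFrame for several
        variables, e.g. mean SST and seasonal range), aligned with
        ``calibration`` rows.
    k
        Number of retained factors; must not exceed the matrix rank.
    """
    X = calibration.to_numpy(dtype=float)
    n, p = X.shape
    if k < 1 or k > min(n, p):
        raise ValueError(f"k={k} outside [1, min(n_samples, n_taxa)={min(n, p)}]")
    if n < k + 2:
        # regression is saturated (no residual degrees of freedom); legal for
        # reconstruction studies but useless as a calibrated transfer function
        warnings.warn("fewer than k+2 calibration cells: regression saturated")
    env_df = env.to_frame() if isinstance(env, pd.Series) else env

    W = _unit_rows(X)[0] if row_norm == "unit_length" else X
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    if s[k - 1] <= s[0] * 1e-12:
        raise ValueError(f"k={k} exceeds the effective rank of the matrix")
    F = U[:, :k] * s[:k]
    A = Vt[:k].T

    Frot, R = varimax(F)
    Arot = A @ R

    # reproducible basis: positive dominant taxon score, then order factors
    # by explained variance
    signs = np.sign(Arot[np.argmax(np.abs(Arot), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    Frot = Frot * signs
    Arot = Arot * signs
    R = R * signs
    order = np.argsort(-(Frot**2).sum(axis=0), kind="stable")
    Frot, Arot, R = Frot[:, order], Arot[:, order], R[:, order]

    D = _design(Frot, quadratic)
    coefs, fitted, residuals, rmse = {}, {}, {}, {}
    for var in env_df.columns:
        y = env_df[var].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        coefs[var] = beta
        yhat = D @ beta
        fitted[var] = yhat
        residuals[var] = y - yhat
        rmse[var] = float(np.sqrt(np.mean((y - yhat) ** 2)))

    return IkfaModel(
        taxa=list(calibration.columns),
        taxon_scores=Arot,
        rotation=R,
        coefficients=coefs,
        k=k,
        quadratic=quadratic,
        row_norm=row_norm,
        communality_threshold=communality_threshold,
        calibration_stats={
            "rmse": rmse,
            "fitted": {v: fitted[v].tolist() for v in fitted},
            "residuals": {v: residuals[v].tolist() for v in residuals},
            "loadings": Frot,
        },
    )


def predict_ikfa(
    model: IkfaModel,
    fossil: pd.DataFrame,
    communality_threshold: float | None = None,
) -> pd.DataFrame:
    """Project fossil assemblages through a fitted model.

    Fossil columns are aligned to the model's taxa (calibration taxa absent
    from a fossil cell enter as structural zeros; fossil-only taxa are
    ignored).  All-zero fossil rows yield missing predictions.

    Returns a DataFrame indexed like ``fossil`` with one ``pred_<var>``
    column per environmental variable plus ``communality`` and
    ``no_analog`` (communality below the threshold).
    """
    thr = (
        model.communality_threshold
        if communality_threshold is None
        else communality_threshold
    )
    aligned = fossil.reindex(columns=model.taxa, fill_value=0.0)
    X = aligned.to_numpy(dtype=float)
    if model.row_norm == "unit_length":
        W, norms = _unit_rows(X)
    else:
        W, norms = X, np.linalg.norm(X, axis=1)
    empty = norms == 0

    F = W @ model.taxon_scores              # projection: scores are orthonormal
    comm = (F**2).sum(axis=1)
    if model.row_norm == "unit_length":
        comm = np.where(empty, np.nan, comm)
    else:
        denom = np.where(norms == 0, np.nan, norms**2)
        comm = (F**2).sum(axis=1) / denom

    D = _design(F, model.quadratic)
    out = pd.DataFrame(index=fossil.index)
    for var, beta in model.coefficients.items():
        pred = D @ beta
        pred[empty] = np.nan
        out[f"pred_{var}"] = pred
    out["communality"] = comm
    out["no_analog"] = ~(comm >= thr)  # NaN communality also flags
    return out
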