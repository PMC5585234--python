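"""Anomaly profiles, latitudinal summaries and cross-proxy statistics.

Reconstructed-minus-modern anomalies per fossil cell are summarized along
latitude three ways: a LOESS curve (tricube-weighted local polynomial
regression), 5-degree band means (the unit at which sparse proxy
compilations can be compared), and range-restricted means/medians.  Band
series from different sources (model variants, proxy compilations) are
compared with Spearman rank correlations (exact small-sample p-values by
enumeration), one-way ANOVA, and pairwise Wilcoxon signed-rank tests on
band-matched pairs.

The sensitivity experiment degrades the calibration data (species-pool and
cell subsampling) and measures how internal error and the reconstructed
anomaly profile respond.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ann import AnnConfig, internal_validation, predict_ensemble, train_ensemble
from .ikfa import fit_ikfa, predict_ikfa

logger = logging.getLogger(__name__)

DEFAULT_LAT_RANGE = (-32.0, 33.0)  # the latitudinal band reef corals occupy


# ---------------------------------------------------------------------------
# anomalies
# ---------------------------------------------------------------------------

def compute_anomalies(
    predictions: pd.DataFrame,
    modern_env: pd.DataFrame,
    variable: str = "mean_sst",
    method: str = "ann",
    prediction_col: str | None = None,
) -> pd.DataFrame:
    """Reconstructed-minus-modern anomaly per fossil cell.

    ``predictions`` is indexed by cell id with the reconstructed values;
    ``modern_env`` (from ``ClimatologyField.env_table``) provides the modern
    observed reference and cell-center latitude.  Cells without a modern
    reference are dropped and logged.
    """
    col = prediction_col or (
        "prediction" if "prediction" in predictions.columns else f"pred_{variable}"
    )
    shared = predictions.index.intersection(modern_env.index)
    if len(shared) == 0:
        raise ValueError("no fossil cell has a modern reference")
    missing = predictions.index.difference(modern_env.index)
    if len(missing):
        logger.info("compute_anomalies: %d cells lack a modern reference", len(missing))
    pred = predictions.loc[shared, col].astype(float)
    modern = modern_env.loc[shared, variable].astype(float)
    out = pd.DataFrame(
        {
            "lat": modern_env.loc[shared, "lat"].astype(float),
            "predicted": pred,
            "modern": modern,
            "anomaly": pred - modern,
        },
        index=shared,
    )
    out["variable"] = variable
    out["method"] = method
    return out.dropna(subset=["anomaly"])


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def loess_profile(
    lat,
    values,
    span: float = 0.8,
    degree: int = 2,
    grid=None,
) -> pd.DataFrame:
    """LOESS: tricube-weighted local polynomial regression along latitude.

    ``span`` is the fraction of points in each local window (nearest
    neighbors of the query).  Windows too small for the polynomial degree are
    widened to the minimum viable size.  The curve is evaluated at ``grid``
    (default: 1-degree steps across the data range).
    """
    x = np.asarray(lat, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if n < degree + 2:
        raise ValueError("need at least degree+2 points")
    q = int(np.ceil(span * n))
    if q < degree + 2:
        q = degree + 2
        logger.info("loess_profile: widened window to %d points", q)
    q = min(q, n)

    if grid is None:
        grid = np.arange(np.floor(x.min()), np.ceil(x.max()) + 1.0, 1.0)
    grid = np.asarray(grid, dtype=float)

    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        deg = degree
        while True:
            # weighted polynomial LS in (x - x0); intercept = fitted value
            D = np.vander(x[idx] - x0, deg + 1, increasing=True)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(D * sw[:, None], y[idx] * sw, rcond=None)
            val = beta[0]
            if np.isfinite(val) or deg == 0:
                break
            deg -= 1
        out[i] = val
    return pd.DataFrame({"lat": grid, "value": out})


# ---------------------------------------------------------------------------
# band means
# ---------------------------------------------------------------------------

def band_means(
    profile: pd.DataFrame,
    width: float = 5.0,
    value_col: str = "anomaly",
    lat_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of the value per ``width``-degree latitudinal band.

    Bands are [k*width, (k+1)*width) tiles anchored at 0 degrees, labelled by
    their center.  Empty bands inside ``lat_range`` are reported as missing.
    """
    lat = profile["lat"].astype(float)
    vals = profile[value_col].astype(float)
    if lat_range is not None:
        keep = (lat >= lat_range[0]) & (lat <= lat_range[1])
        lat, vals = lat[keep], vals[keep]
    band_lo = np.floor(lat / width) * width
    df = pd.DataFrame({"band_lo": band_lo, "value": vals})
    g = df.groupby("band_lo")["value"]
    out = pd.DataFrame({"mean": g.mean(), "n": g.size()})
    if lat_range is not None:
        full = np.arange(
            np.floor(lat_range[0] / width) * width,
            np.floor(lat_range[1] / width) * width + width / 2,
            width,
        )
        out = out.reindex(full)
        out["n"] = out["n"].fillna(0).astype(int)
    out.index = out.index + width / 2.0
    out.index.name = "band_center"
    return out


# ---------------------------------------------------------------------------
# rank statistics with exact small-n nulls
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """All attainable Spearman rho under the permutation null (n! values).

    Tie-free ranks, so rho = 1 - 6 sum(d^2) / (n (n^2 - 1)) holds exactly.
    """
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    base = np.arange(1, n + 1, dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def spearman_test(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value for small samples.

    For n <= ``exact_max_n`` and tie-free data, the two-sided p-value comes
    from full enumeration of rank permutations; otherwise scipy's
    t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return (np.nan, np.nan)
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not ties and np.isfinite(rho):
        null = _exact_spearman_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(res.pvalue)


def wilcoxon_test(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p on matched pairs.

    Identical series (all differences zero) return p = 1.  scipy picks the
    exact null for small tie-free samples.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) == 0 or np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(d, zero_method="wilcox", method="auto").pvalue)


def spearman_matrix(series: pd.DataFrame, min_shared: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise complete-case Spearman correlations among band series.

    ``series``: index = band center, one column per source.  Pairs sharing
    fewer than ``min_shared`` bands come back NaN.  Returns (rho, p) frames.
    """
    cols = list(series.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a in cols:
        rho.loc[a, a] = 1.0
        pval.loc[a, a] = 0.0
        for b in cols:
            if b <= a:
                continue
            pair = series[[a, b]].dropna()
            if len(pair) < min_shared:
                continue
            r, p = spearman_test(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def format_correlation_table(rho: pd.DataFrame, pval: pd.DataFrame) -> pd.DataFrame:
    """One matrix, correlation coefficients lower-left, p-values upper-right."""
    cols = list(rho.columns)
    out = pd.DataFrame("", index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i > j:
                v = rho.loc[a, b]
                out.loc[a, b] = "" if pd.isna(v) else f"{v:.2f}"
            elif i < j:
                v = pval.loc[a, b]
                out.loc[a, b] = "" if pd.isna(v) else f"{v:.3g}"
    return out


def compare_means(
    series: pd.DataFrame, lat_range: tuple[float, float] = DEFAULT_LAT_RANGE
) -> dict:
    """One-way ANOVA across sources plus pairwise Wilcoxon on matched bands.

    ``series``: band-center-indexed frame, one column per source.  Returns
    the ANOVA p, a pairwise signed-rank p table, and per-source means and
    medians over the latitude range.
    """
    inside = series[(series.index >= lat_range[0]) & (series.index <= lat_range[1])]
    groups = [inside[c].dropna().to_numpy() for c in inside.columns]
    if all(len(g) >= 2 for g in groups):
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:
            anova_p = 1.0
        else:
            anova_p = float(sps.f_oneway(*groups).pvalue)
    else:
        anova_p = np.nan
    cols = list(inside.columns)
    wp = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a in cols:
        for b in cols:
            if b <= a:
                continue
            pair = inside[[a, b]].dropna()
            if len(pair) < 2:
                continue
            p = wilcoxon_test(pair[a], pair[b])
            wp.loc[a, b] = wp.loc[b, a] = p
    return {
        "anova_p": anova_p,
        "wilcoxon_p": wp,
        "means": inside.mean(),
        "medians": inside.median(),
    }


# ---------------------------------------------------------------------------
# cross-validation and sensitivity
# ---------------------------------------------------------------------------

def cross_validation(
    calibration: pd.DataFrame,
    env: pd.Series,
    method: str = "ann",
    mode: str = "leave_one_out",
    ann_config: AnnConfig | None = None,
    k: int = 4,
    latitudes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell signed deviations (observed - predicted) for either method.

    ``resubstitution`` trains once on everything and predicts it back (the
    optimistic, apparent error); ``leave_one_out`` refits with each cell held
    out in turn.
    """
    env = pd.Series(np.asarray(env, dtype=float), index=calibration.index)
    if method not in ("ann", "ikfa"):
        raise ValueError("method must be 'ann' or 'ikfa'")
    if mode not in ("resubstitution", "leave_one_out"):
        raise ValueError("unknown validation mode")

    def _fit_predict(train_X, train_y, test_X):
        if method == "ann":
            ens = train_ensemble(train_X, train_y, ann_config or AnnConfig())
            return predict_ensemble(ens, test_X)["prediction"]
        model = fit_ikfa(train_X, train_y.rename("env"), k=k)
        return predict_ikfa(model, test_X)["pred_env"]

    if mode == "resubstitution":
        pred = _fit_predict(calibration, env, calibration)
    else:
        preds = []
        for cell in calibration.index:
            train_X = calibration.drop(index=[cell])
            test_X = calibration.loc[[cell]]
            # drop taxa that vanish from the training fold
            occupied = train_X.columns[(train_X > 0).any(axis=0)]
            train_fold = train_X[occupied]
            rowsum = train_fold.sum(axis=1)
            train_fold = train_fold.div(rowsum.where(rowsum > 0, 1.0), axis=0)
            preds.append(_fit_predict(train_fold, env.drop(index=[cell]), test_X))
        pred = pd.concat(preds)

    out = pd.DataFrame({"observed": env, "predicted": pred.reindex(env.index)})
    out["deviation"] = out["observed"] - out["predicted"]
    if latitudes is not None:
        out["lat"] = np.asarray(latitudes, dtype=float)
    return out


def sensitivity_experiment(
    calibration: pd.DataFrame,
    env: pd.Series,
    fossil: pd.DataFrame,
    modern_env: pd.DataFrame,
    species_fractions=(1.0, 0.5, 0.25, 0.1),
    cell_fractions=(1.0,),
    n_reps: int = 3,
    base_seed: int = 0,
    ann_config: AnnConfig | None = None,
    k: int = 4,
    variable: str = "mean_sst",
) -> pd.DataFrame:
    """Degrade the calibration data and measure how the reconstruction moves.

    For every (species_fraction, cell_fraction) pair and replicate draw, the
    species pool and calibration cells are subsampled without replacement,
    both transfer models are refit, and two responses are recorded per
    method: the internal (resubstitution) RMSE, and the mean absolute change
    of the fossil anomaly profile relative to the full-data run.  The
    (1.0, 1.0) pair is the reference and shows zero shift by construction.
    """
    env = pd.Series(np.asarray(env, dtype=float), index=calibration.index)
    cfg = ann_config or AnnConfig(n_replicates=20)
    rng = np.random.default_rng(base_seed)

    def _run(X, y, foss):
        out = {}
        ens = train_ensemble(X, y, cfg)
        resub_ann = predict_ensemble(ens, X)["prediction"]
        out["ann_rmse"] = float(np.sqrt(np.mean((y - resub_ann) ** 2)))
        out["ann_profile"] = compute_anomalies(
            predict_ensemble(ens, foss), modern_env, variable=variable, method="ann"
        )["anomaly"]
        kk = min(k, max(1, min(X.shape) - 2), int(np.linalg.matrix_rank(X.to_numpy())))
        model = fit_ikfa(X, y.rename(variable), k=kk)
        resub_fa = predict_ikfa(model, X)[f"pred_{variable}"]
        out["ikfa_rmse"] = float(np.sqrt(np.mean((y - resub_fa) ** 2)))
        out["ikfa_profile"] = compute_anomalies(
            predict_ikfa(model, foss), modern_env, variable=variable, method="ikfa"
        )["anomaly"]
        return out

    full = _run(calibration, env, fossil)
    taxa = list(calibration.columns)
    cells = list(calibration.index)
    rows = []
    for sf in species_fractions:
        if not (0 < sf <= 1):
            raise ValueError("fractions must be in (0, 1]")
        for cf in cell_fractions:
            for rep in range(n_reps):
                if sf == 1.0 and cf == 1.0 and rep > 0:
                    continue
                n_sp = max(2, int(round(sf * len(taxa))))
                n_cell = max(k + 2, int(round(cf * len(cells))))
                sub_taxa = sorted(
                    rng.choice(taxa, size=n_sp, replace=False).tolist()
                ) if n_sp < len(taxa) else taxa
                sub_cells = sorted(
                    rng.choice(len(cells), size=n_cell, replace=False).tolist()
                ) if n_cell < len(cells) else range(len(cells))
                X = calibration.iloc[list(sub_cells)][sub_taxa]
                foss = fossil[fossil.columns.intersection(sub_taxa)]
                if len(sub_taxa) < len(taxa):  # renormalize the reduced pool
                    rowsum = X.sum(axis=1)
                    keep = rowsum > 0
                    X = X.loc[keep].div(rowsum[keep], axis=0)
                    frowsum = foss.sum(axis=1)
                    foss = foss.loc[frowsum > 0].div(frowsum[frowsum > 0], axis=0)
                y = env.loc[X.index]
                res = _run(X, y, foss)
                row = {"species_fraction": sf, "cell_fraction": cf, "rep": rep,
                       "n_species": len(sub_taxa), "n_cells": len(X)}
                for m in ("ann", "ikfa"):
                    row[f"{m}_rmse"] = res[f"{m}_rmse"]
                    shared = full[f"{m}_profile"].index.intersection(
                        res[f"{m}_profile"].index
                    )
                    row[f"{m}_anomaly_shift"] = float(
                        (res[f"{m}_profile"].loc[shared]
                         - full[f"{m}_profile"].loc[shared]).abs().mean()
                    )
                rows.append(row)
    return pd.DataFrame(rows)
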