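"""End-to-end drivers: synthetic world -> calibration -> reconstruction.

:class:`WorldConfig` captures every generator knob plus the seed, so a full
run is reproducible from one small config (serializable to/from TOML).
:func:`build_world` produces the modern and fossil data products with the
standard filters applied; :func:`reconstruct` trains both transfer-function
branches on the modern calibration set and turns fossil predictions into
anomaly profiles against the observed modern field.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, replace
from typing import NamedTuple

import pandas as pd

from . import assemblage as asb
from .ann import AnnConfig, predict_ensemble, train_ensemble
from .climatology import ClimatologyField, pair_cells
from .evaluate import compute_anomalies
from .ikfa import fit_ikfa, predict_ikfa
from .synthetic_world import (
    AnomalySpec,
    SstFieldParams,
    apply_anomaly,
    make_species_pool,
    make_sst_field,
    sample_occurrences,
)


@dataclass(frozen=True)
class WorldConfig:
    """The study conditions of a synthetic-world run.

    Defaults define the standard validation world: a 1-degree reef band from
    32 S to 33 N (about 130 ocean cells at two longitudes), 30 species in 10
    genera with niches spanning the thermal gradient, modern sampling at 50
    visits per cell, and a sparser fossil scenario (half the cells, effort
    15) on a field carrying the U-shaped anomaly: 1 degC cooler inner
    tropics, 2 degC warmer subtropics, with a reduced northern-hemisphere
    seasonal range.
    """

    seed: int = 42
    lat_extent: tuple[float, float] = (-32.0, 33.0)
    n_lon: int = 2
    field_params: SstFieldParams = field(default_factory=SstFieldParams)
    n_species: int = 30
    n_genera: int = 10
    optimum_range: tuple[float, float] = (19.5, 28.5)
    frac_increasing: float = 0.2
    modern_effort: int = 50
    fossil_effort: int = 15
    fossil_cell_fraction: float = 0.5
    anomaly: AnomalySpec = field(
        default_factory=lambda: AnomalySpec(
            equatorial_offset=-1.0,
            subtropical_offset=2.0,
            stv_offset_north=-1.0,
            stv_offset_south=0.0,
        )
    )
    max_depth: float = 60.0
    min_genera: int = 2
    rank: str = "species"

    @classmethod
    def from_toml(cls, path) -> "WorldConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "field_params" in raw:
            raw["field_params"] = SstFieldParams(**raw["field_params"])
        if "anomaly" in raw:
            raw["anomaly"] = AnomalySpec(**raw["anomaly"])
        for key in ("lat_extent", "optimum_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


class World(NamedTuple):
    """Everything one run of the generator and gridding steps produces."""

    config: WorldConfig
    field: ClimatologyField          # modern observed climatology
    fossil_field: ClimatologyField   # anomaly-shifted truth
    pool: list
    modern_records: pd.DataFrame
    fossil_records: pd.DataFrame
    calibration: pd.DataFrame        # harmonized modern proportions
    env: pd.DataFrame                # per-cell lat/lon/mean_sst/stv (modern)
    fossil_matrix: pd.DataFrame      # harmonized fossil proportions
    modern_env: pd.DataFrame         # modern reference at all ocean cells


def build_world(config: WorldConfig | None = None) -> World:
    """Generate, filter, grid and harmonize one synthetic-world scenario."""
    cfg = config or WorldConfig()
    fld = make_sst_field(cfg.lat_extent, cfg.n_lon, cfg.field_params, seed=cfg.seed)
    fossil_fld = apply_anomaly(fld, cfg.anomaly)
    pool = make_species_pool(
        n_species=cfg.n_species,
        n_genera=cfg.n_genera,
        optimum_range=cfg.optimum_range,
        frac_increasing=cfg.frac_increasing,
        seed=cfg.seed,
    )
    modern = sample_occurrences(
        pool, fld, effort=cfg.modern_effort, epoch="modern", seed=cfg.seed
    )
    fossil = sample_occurrences(
        pool,
        fossil_fld,
        effort=cfg.fossil_effort,
        epoch="LIG",
        seed=cfg.seed + 1,
        cell_fraction=cfg.fossil_cell_fraction,
    )

    modern_f = asb.filter_records(modern, max_depth=cfg.max_depth)
    fossil_f = asb.filter_records(fossil, max_depth=cfg.max_depth)
    m_mat = asb.apply_cell_filters(
        asb.build_matrix(modern_f, rank=cfg.rank), min_genera=cfg.min_genera
    )
    f_mat = asb.apply_cell_filters(
        asb.build_matrix(fossil_f, rank=cfg.rank), min_genera=cfg.min_genera
    )
    m_mat, f_mat = asb.harmonize_taxa(m_mat, f_mat, min_genera=cfg.min_genera)

    calib, env = pair_cells(m_mat, fld)
    modern_env = fld.env_table()
    return World(
        config=cfg,
        field=fld,
        fossil_field=fossil_fld,
        pool=pool,
        modern_records=modern,
        fossil_records=fossil,
        calibration=calib,
        env=env,
        fossil_matrix=f_mat.props,
        modern_env=modern_env,
    )


class Reconstruction(NamedTuple):
    anomalies: pd.DataFrame          # long: lat, predicted, modern, anomaly, method
    ann_ensemble: object
    ikfa_model: object
    fossil_predictions: pd.DataFrame


def reconstruct(
    world: World,
    variable: str = "mean_sst",
    ann_config: AnnConfig | None = None,
    k: int = 4,
) -> Reconstruction:
    """Train both transfer-function branches and reconstruct fossil anomalies.

    The anomaly baseline is the observed modern climatology at each fossil
    cell (the less circular choice; a model-vs-model baseline is a separate
    analysis, not the default).
    """
    cfg = ann_config or AnnConfig(n_replicates=100, base_seed=world.config.seed)
    y = world.env[variable]

    ens = train_ensemble(world.calibration, y, cfg)
    ann_pred = predict_ensemble(ens, world.fossil_matrix)
    fa_model = fit_ikfa(world.calibration, y.rename(variable), k=k)
    fa_pred = predict_ikfa(fa_model, world.fossil_matrix)

    ann_prof = compute_anomalies(
        ann_pred, world.modern_env, variable=variable, method="ann"
    )
    fa_prof = compute_anomalies(
        fa_pred, world.modern_env, variable=variable, method="ikfa"
    )
    both = pd.concat([ann_prof, fa_prof])
    preds = pd.DataFrame(
        {"ann": ann_pred["prediction"], "ikfa": fa_pred[f"pred_{variable}"]}
    )
    return Reconstruction(
        anomalies=both, ann_ensemble=ens, ikfa_model=fa_model,
        fossil_predictions=preds,
    )


def true_anomaly(world: World, lat) -> pd.Series:
    """The imposed mean-SST anomaly at given latitudes (the ground truth)."""
    import numpy as np

    return pd.Series(world.config.anomaly.mean_shift(np.asarray(lat)), index=None)


def with_seed(config: WorldConfig, seed: int) -> WorldConfig:
    return replace(config, seed=seed)
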