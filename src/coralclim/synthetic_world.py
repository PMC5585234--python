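"""A toy reef planet with known thermal niches and a known imposed anomaly.

This module generates everything the transfer-function pipeline consumes, with
ground truth attached: a latitudinally graded monthly SST field, a pool of
species with unimodal (Gaussian) or monotonically increasing occupancy
responses to mean SST, occurrence tables sampled with finite effort, and a
"fossil" scenario built by shifting the field with a piecewise-linear
latitudinal anomaly (cooler inner tropics, warmer subtropics — the U-shaped
pattern the reconstruction is asked to recover).

Everything is seeded and deterministic: the same seed reproduces the same
field, pool and occurrence table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .climatology import MONTHS, ClimatologyField

__all__ = [
    "SpeciesNiche",
    "AnomalySpec",
    "SstFieldParams",
    "make_sst_field",
    "make_species_pool",
    "sample_occurrences",
    "apply_anomaly",
    "occupancy_probability",
]

SEA_FLOOR_SST = -2.0  # degC; below the freezing point of seawater


@dataclass(frozen=True)
class SpeciesNiche:
    """One species' occupancy response to mean SST.

    ``gaussian`` niches peak at ``optimum`` with SD ``tolerance``;
    ``increasing`` niches are logistic in SST (half-saturation at ``optimum``,
    scale ``tolerance``), standing in for the minority of taxa whose occupancy
    rises with temperature.
    """

    taxon_id: str
    genus_id: str
    optimum: float
    tolerance: float
    peak_occupancy: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not (0 < self.peak_occupancy <= 1):
            raise ValueError("peak_occupancy must be in (0, 1]")
        if self.shape not in ("gaussian", "increasing"):
            raise ValueError(f"unknown niche shape {self.shape!r}")


@dataclass(frozen=True)
class AnomalySpec:
    """Piecewise-linear latitudinal mean-SST shift plus seasonal-range shifts.

    The mean shift equals ``equatorial_offset`` for |lat| <= inner_lat,
    ``subtropical_offset`` for |lat| >= outer_lat, and interpolates linearly
    in between — continuous in latitude and symmetric across hemispheres.
    ``stv_offset_north``/``stv_offset_south`` additively shift the seasonal
    range per hemisphere (applied by rescaling the monthly deviations).
    """

    equatorial_offset: float
    subtropical_offset: float
    inner_lat: float = 15.0
    outer_lat: float = 25.0
    stv_offset_north: float = 0.0
    stv_offset_south: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_lat < self.outer_lat):
            raise ValueError("need 0 < inner_lat < outer_lat")

    def mean_shift(self, lat) -> np.ndarray:
        """Mean-SST offset (degC) at latitude(s) ``lat``."""
        a = np.abs(np.asarray(lat, dtype=float))
        frac = np.clip((a - self.inner_lat) / (self.outer_lat - self.inner_lat), 0, 1)
        return self.equatorial_offset + frac * (
            self.subtropical_offset - self.equatorial_offset
        )

    def stv_shift(self, lat) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        return np.where(lat >= 0, self.stv_offset_north, self.stv_offset_south)


@dataclass(frozen=True)
class SstFieldParams:
    """Base climate of the toy planet.

    mean SST(lat) = equator_mean - pole_gradient * |lat|; the seasonal
    amplitude (= annual range) grows linearly from the equator:
    amp(lat) = seasonal_amp_equator + seasonal_amp_slope * |lat|.
    """

    equator_mean: float = 28.0
    pole_gradient: float = 0.25
    seasonal_amp_equator: float = 1.0
    seasonal_amp_slope: float = 1.0 / 6.0

    def mean_sst(self, lat) -> np.ndarray:
        return self.equator_mean - self.pole_gradient * np.abs(
            np.asarray(lat, dtype=float)
        )

    def seasonal_amp(self, lat) -> np.ndarray:
        return self.seasonal_amp_equator + self.seasonal_amp_slope * np.abs(
            np.asarray(lat, dtype=float)
        )


def make_sst_field(
    lat_extent: tuple[float, float] | float,
    n_lon: int,
    base_params: SstFieldParams | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> ClimatologyField:
    """Build the modern 1-degree monthly SST climatology.

    The monthly curve is sinusoidal, sampled at the twelve month indices with
    the warm peak in month 8 in the northern hemisphere and month 2 in the
    southern (a 6-month phase flip), so the annual range of the sampled curve
    equals the prescribed amplitude exactly.  ``noise_sd`` optionally adds a
    seeded per-cell perturbation to the mean (default off: ground truth stays
    closed-form).
    """
    p = base_params or SstFieldParams()
    if np.isscalar(lat_extent):
        lat_extent = (-float(lat_extent), float(lat_extent))
    lo, hi = lat_extent
    if lo < -40 or hi > 40 or lo >= hi:
        raise ValueError("lat_extent must lie within [-40, 40]")
    if n_lon < 1:
        raise ValueError("n_lon must be >= 1")
    if p.seasonal_amp_equator < 0 or p.seasonal_amp(max(abs(lo), abs(hi))) < 0:
        raise ValueError("seasonal amplitude must be non-negative")

    lat_idx = np.arange(int(np.floor(lo)), int(np.ceil(hi)))
    lat = lat_idx + 0.5
    lon = np.arange(n_lon) + 0.5

    mean = p.equator_mean - p.pole_gradient * np.abs(lat)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mean = mean[:, None] + rng.normal(0.0, noise_sd, (lat.size, lon.size))
    else:
        mean = np.repeat(mean[:, None], lon.size, axis=1)

    amp = p.seasonal_amp(lat)
    peak_month = np.where(lat >= 0, 8, 2)
    phase = np.cos(2 * np.pi * (MONTHS[None, :] - peak_month[:, None]) / 12.0)
    monthly = mean[:, :, None] + (amp[:, None] / 2.0)[:, :, None] * phase[:, None, :]

    arr = xr.DataArray(
        monthly,
        dims=("lat", "lon", "month"),
        coords={"lat": lat, "lon": lon, "month": MONTHS},
        name="sst",
    )
    return ClimatologyField(arr)


def make_species_pool(
    n_species: int = 30,
    n_genera: int = 10,
    optimum_range: tuple[float, float] = (19.5, 28.5),
    frac_increasing: float = 0.2,
    seed: int = 0,
    tolerance_range: tuple[float, float] = (1.5, 3.5),
    peak_range: tuple[float, float] = (0.3, 0.9),
) -> list[SpeciesNiche]:
    """Draw a seeded species pool with niches spanning ``optimum_range``.

    Optima are evenly spaced across the range (so the pool covers the whole
    thermal gradient regardless of seed); tolerances and peak occupancies are
    uniform draws.  ``round(frac_increasing * n_species)`` species get the
    monotonically increasing (logistic) shape.  Every genus receives at least
    one species.
    """
    if n_genera > n_species:
        raise ValueError("n_genera must be <= n_species")
    if not (0 <= frac_increasing < 0.5):
        raise ValueError("frac_increasing must be in [0, 0.5)")
    lo, hi = optimum_range
    if not lo < hi:
        raise ValueError("empty optimum_range")

    rng = np.random.default_rng(seed)
    optima = np.linspace(lo, hi, n_species)
    tolerances = rng.uniform(*tolerance_range, n_species)
    peaks = rng.uniform(*peak_range, n_species)

    n_inc = int(round(frac_increasing * n_species))
    inc_idx = set(rng.choice(n_species, size=n_inc, replace=False).tolist())

    # every genus gets one species up front; the rest are assigned at random
    genus_of = np.empty(n_species, dtype=int)
    genus_of[:n_genera] = np.arange(n_genera)
    genus_of[n_genera:] = rng.integers(0, n_genera, n_species - n_genera)
    rng.shuffle(genus_of)

    pool = []
    for i in range(n_species):
        pool.append(
            SpeciesNiche(
                taxon_id=f"sp{i + 1:03d}",
                genus_id=f"gen{genus_of[i] + 1:02d}",
                optimum=float(optima[i]),
                tolerance=float(tolerances[i]),
                peak_occupancy=float(peaks[i]),
                shape="increasing" if i in inc_idx else "gaussian",
            )
        )
    return pool


def occupancy_probability(niche: SpeciesNiche, sst) -> np.ndarray:
    """Per-visit detection probability of a species at mean SST ``sst``."""
    sst = np.asarray(sst, dtype=float)
    if niche.shape == "gaussian":
        return niche.peak_occupancy * np.exp(
            -((sst - niche.optimum) ** 2) / (2.0 * niche.tolerance**2)
        )
    return niche.peak_occupancy / (1.0 + np.exp(-(sst - niche.optimum) / niche.tolerance))


def sample_occurrences(
    pool: list[SpeciesNiche],
    field: ClimatologyField,
    effort: int,
    epoch: str,
    seed: int = 0,
    cell_fraction: float = 1.0,
    deep_fraction: float = 0.0,
    azoox_fraction: float = 0.0,
) -> pd.DataFrame:
    """Sample an occurrence table from niches over the field's cells.

    Per cell and species, the number of detections is Binomial(effort, p)
    with p given by :func:`occupancy_probability` at the cell's mean SST.
    Rows carry the cell-center coordinates, a depth drawn uniformly in
    (0, 60] m, the epoch label, and a zooxanthellate flag.

    ``cell_fraction`` subsamples the occupied cells (fossil scenarios are
    sparser than modern ones); ``deep_fraction`` / ``azoox_fraction`` inject
    contamination (depth > 60 m, azooxanthellate records) so the record
    filters have something to remove.
    """
    if effort < 1:
        raise ValueError("effort must be >= 1")
    rng = np.random.default_rng(seed)

    env = field.env_table().reset_index()
    if cell_fraction < 1.0:
        n_keep = max(1, int(round(cell_fraction * len(env))))
        keep = np.sort(rng.choice(len(env), size=n_keep, replace=False))
        env = env.iloc[keep]

    sst = env["mean_sst"].to_numpy()
    frames = []
    for niche in pool:
        p = occupancy_probability(niche, sst)
        counts = rng.binomial(effort, p)
        idx = np.repeat(np.arange(len(env)), counts)
        if idx.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "taxon": niche.taxon_id,
                    "genus": niche.genus_id,
                    "rank": "species",
                    "lat": env["lat"].to_numpy()[idx],
                    "lon": env["lon"].to_numpy()[idx],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "taxon", "genus", "rank", "lat", "lon",
                "depth_m", "epoch", "zooxanthellate",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    n = len(out)
    # uniform(0, 60]: shallow reef habitat that passes the depth filter
    depth = 60.0 * (1.0 - rng.random(n))
    if deep_fraction > 0:
        deep = rng.random(n) < deep_fraction
        depth[deep] = rng.uniform(60.0, 120.0, deep.sum()) + 1e-9
    out["depth_m"] = depth
    out["epoch"] = epoch
    zoox = np.ones(n, dtype=bool)
    if azoox_fraction > 0:
        zoox &= rng.random(n) >= azoox_fraction
    out["zooxanthellate"] = zoox
    return out


def apply_anomaly(field: ClimatologyField, spec: AnomalySpec) -> ClimatologyField:
    """Shift a field's mean SST and seasonal range by an :class:`AnomalySpec`.

    The monthly curve is reconstructed so that its annual mean equals the
    shifted mean and its range equals the shifted range: deviations from the
    cell mean are rescaled by (new amplitude / old amplitude) and the shifted
    mean is added back.  Identity spec returns the field unchanged bit for bit.
    """
    if (
        spec.equatorial_offset == 0
        and spec.subtropical_offset == 0
        and spec.stv_offset_north == 0
        and spec.stv_offset_south == 0
    ):
        return ClimatologyField(field.monthly.copy())

    lat = field.lat
    shift = spec.mean_shift(lat)
    stv_shift = spec.stv_shift(lat)

    mean = field.mean_sst  # (lat, lon)
    dev = field.monthly - mean
    old_amp = field.stv
    new_amp = old_amp + xr.DataArray(stv_shift, dims="lat", coords={"lat": lat})
    if (new_amp < 0).any():
        raise ValueError("stv offsets drive the seasonal range negative")
    zero = old_amp == 0
    if bool((zero & (new_amp != old_amp)).any()):
        raise ValueError("cannot impose a seasonal range on a seasonless cell")
    scale = xr.where(zero, 1.0, new_amp / xr.where(zero, 1.0, old_amp))

    new_mean = mean + xr.DataArray(shift, dims="lat", coords={"lat": lat})
    monthly = new_mean + dev * scale
    if float(monthly.min()) < SEA_FLOOR_SST:
        raise ValueError("anomaly drives SST below -2 degC (non-physical)")
    return ClimatologyField(monthly.transpose("lat", "lon", "month"))
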