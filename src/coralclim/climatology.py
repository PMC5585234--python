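"""Monthly SST climatologies: per-cell mean SST and seasonal temperature variability.

The central container is :class:`ClimatologyField`, a 1-degree gridded
12-month sea-surface temperature climatology.  Two per-cell scalars are
derived from it and drive everything downstream:

* ``mean_sst`` — arithmetic mean of the twelve climatological months (degC);
* ``stv``     — seasonal temperature variability, the absolute annual range
  (warmest minus coldest climatological month, degC).

Multi-year monthly series (e.g. a Hadley-style product) are collapsed to a
climatology with :func:`monthly_climatology` / :func:`climatology_from_series`,
optionally excluding years.  Cells with any missing climatological month are
treated as missing (land or insufficient coverage) and dropped when paired
with assemblage data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

MONTHS = np.arange(1, 13)


@dataclass
class ClimatologyField:
    """A 1-degree gridded 12-month SST climatology.

    Parameters
    ----------
    monthly
        DataArray with dims ``(lat, lon, month)``; ``lat``/``lon`` coordinates
        are cell centers (integer + 0.5), ``month`` is 1..12, values in degC.
        NaN months mark missing cells (land).
    """

    monthly: xr.DataArray

    def __post_init__(self) -> None:
        if tuple(self.monthly.dims) != ("lat", "lon", "month"):
            self.monthly = self.monthly.transpose("lat", "lon", "month")
        if len(self.monthly.month) != 12:
            raise ValueError("climatology needs exactly 12 months")

    # -- derived scalars ---------------------------------------------------
    @property
    def mean_sst(self) -> xr.DataArray:
        return self.monthly.mean("month")

    @property
    def stv(self) -> xr.DataArray:
        """Absolute annual range: warmest minus coldest climatological month."""
        return self.monthly.max("month") - self.monthly.min("month")

    @property
    def lat(self) -> np.ndarray:
        return np.asarray(self.monthly.lat.values)

    @property
    def lon(self) -> np.ndarray:
        return np.asarray(self.monthly.lon.values)

    def env_table(self) -> pd.DataFrame:
        """Per-cell mean SST and STV indexed by (lat_index, lon_index).

        Cells with any missing month are excluded.  The index uses the
        lower-left (floor) corner convention shared with the assemblage grid.
        """
        mean = self.mean_sst.to_pandas().stack()
        rng = self.stv.to_pandas().stack()
        df = pd.DataFrame({"mean_sst": mean, "stv": rng}).reset_index()
        df["lat_index"] = np.floor(df["lat"]).astype(int)
        df["lon_index"] = np.floor(df["lon"]).astype(int)
        df = df.dropna(subset=["mean_sst", "stv"])
        return df.set_index(["lat_index", "lon_index"]).sort_index()[
            ["lat", "lon", "mean_sst", "stv"]
        ]

    # -- serialization -----------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        df = self.monthly.rename("sst").to_dataframe().reset_index()
        return df[["lat", "lon", "month", "sst"]]

    def to_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def to_netcdf(self, path) -> None:
        # scipy engine -> NETCDF3; no netCDF4 dependency
        self.monthly.rename("sst").to_netcdf(path, engine="scipy")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "ClimatologyField":
        arr = (
            df.set_index(["lat", "lon", "month"])["sst"]
            .to_xarray()
            .transpose("lat", "lon", "month")
        )
        return cls(arr)

    @classmethod
    def from_long_csv(cls, path) -> "ClimatologyField":
        return cls.from_long_frame(pd.read_csv(path))

    @classmethod
    def from_netcdf(cls, path) -> "ClimatologyField":
        ds = xr.open_dataset(path, engine="scipy")
        return cls(ds["sst"].load())


def monthly_climatology(
    series: pd.DataFrame, exclude_years: Iterable[int] = ()
) -> np.ndarray:
    """Collapse a multi-year monthly series to a 12-value climatology.

    ``series`` holds one cell's record with columns ``year``, ``month``,
    ``sst``.  Month *m* of the climatology is the mean over included years of
    that calendar month's values; a calendar month with no data after the year
    exclusion comes back as NaN.
    """
    excl = set(int(y) for y in exclude_years)
    kept = series[~series["year"].astype(int).isin(excl)]
    by_month = kept.groupby("month")["sst"].mean()
    out = np.full(12, np.nan)
    for m, v in by_month.items():
        out[int(m) - 1] = v
    return out


def climatology_from_series(
    df: pd.DataFrame, exclude_years: Iterable[int] = ()
) -> ClimatologyField:
    """Gridded version of :func:`monthly_climatology`.

    ``df`` is long-format with columns ``lat, lon, year, month, sst`` (cell
    centers).  Cells missing any calendar month are left NaN for that month.
    """
    excl = set(int(y) for y in exclude_years)
    kept = df[~df["year"].astype(int).isin(excl)]
    clim = (
        kept.groupby(["lat", "lon", "month"])["sst"]
        .mean()
        .to_xarray()
        .reindex(month=MONTHS)
        .transpose("lat", "lon", "month")
    )
    return ClimatologyField(clim)


def derive_mean_and_stv(climatology: np.ndarray) -> tuple[float, float]:
    """Mean SST and seasonal range (max - min) from a 12-month climatology.

    Any missing month poisons both outputs (returned as NaN).
    """
    c = np.asarray(climatology, dtype=float)
    if c.shape != (12,):
        raise ValueError("expected 12 monthly values")
    if np.isnan(c).any():
        return (np.nan, np.nan)
    return (float(c.mean()), float(c.max() - c.min()))


def pair_cells(matrix, field: ClimatologyField) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join an assemblage matrix with per-cell SST summaries.

    Inner join on the (lat_index, lon_index) cell id; assemblage cells with no
    SST (land / missing months) are dropped and logged.

    Returns
    -------
    (props, env)
        ``props``: proportions for the retained cells (rows sum to 1);
        ``env``: matching rows with ``lat, lon, mean_sst, stv``.
    """
    env = field.env_table()
    shared = matrix.props.index.intersection(env.index)
    if len(shared) == 0:
        raise ValueError("no assemblage cell has SST coverage")
    dropped = matrix.props.index.difference(env.index)
    if len(dropped):
        logger.info(
            "pair_cells: dropped %d assemblage cells without SST: %s",
            len(dropped),
            list(dropped),
        )
    shared = shared.sort_values()
    return matrix.props.loc[shared], env.loc[shared]
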