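"""Occurrence records -> filtered proportional assemblage matrices.

Records are one-row-per-observation tables (taxon, genus, rank, lat, lon,
depth_m, epoch, zooxanthellate).  The pipeline is:

1. :func:`filter_records` — keep shallow (depth <= 60 m), zooxanthellate
   records; counts of everything dropped are logged by reason.
2. :func:`build_matrix` — bin records into 1-degree cells (floor semantics)
   and compute per-cell proportional composition at species or genus rank.
3. :func:`apply_cell_filters` — drop cells occupied by fewer than
   ``min_genera`` genera (taxonomic-focus bias guard).
4. :func:`harmonize_taxa` — restrict modern and fossil matrices to their
   shared taxon pool and renormalize, so both transfer-model branches see the
   same columns.

Proportions are count-based (each record counts once); a presence/absence
mode is available for robustness checks.  Matrix rows always sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "taxon", "genus", "rank", "lat", "lon", "depth_m", "epoch", "zooxanthellate",
]


@dataclass
class AssemblageMatrix:
    """Cells x taxa proportional-composition matrix.

    ``props`` is indexed by (lat_index, lon_index) — the floor corner of each
    1-degree cell — with alphabetically ordered taxon columns; every row sums
    to 1.  ``genus_map`` maps each taxon column to its genus (identity at
    genus rank), which the cell filters need.
    """

    props: pd.DataFrame
    rank: str
    epoch: str
    genus_map: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.props.columns)

    @property
    def cells(self) -> pd.MultiIndex:
        return self.props.index

    def validate(self, atol: float = 1e-12) -> None:
        v = self.props.to_numpy()
        if v.size == 0:
            return
        if (v < -atol).any() or (v > 1 + atol).any():
            raise ValueError("proportions outside [0, 1]")
        rows = v.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("rows do not sum to 1")

    def genus_richness(self) -> pd.Series:
        """Number of distinct genera occupying each cell."""
        genera = pd.Index([self.genus_map.get(t, t) for t in self.props.columns])
        present = self.props.to_numpy() > 0
        out = []
        for row in present:
            out.append(genera[row].nunique())
        return pd.Series(out, index=self.props.index, name="n_genera")

    # -- serialization -----------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        df = self.props.reset_index()
        df.insert(2, "epoch", self.epoch)
        return df

    def to_csv(self, path) -> None:
        self.to_wide_frame().to_csv(path, index=False)

    @classmethod
    def from_wide_frame(cls, df: pd.DataFrame, rank: str, genus_map=None):
        epoch = df["epoch"].iloc[0] if len(df) else "modern"
        props = df.drop(columns=["epoch"]).set_index(["lat_index", "lon_index"])
        return cls(props=props, rank=rank, epoch=epoch, genus_map=dict(genus_map or {}))


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


def assign_cell(lat, lon) -> tuple:
    """Map coordinates to their 1-degree cell id (floor semantics).

    The cell spans [lat_index, lat_index+1) x [lon_index, lon_index+1); a
    coordinate on the lower/left boundary belongs to that cell.  Longitudes
    are wrapped to [-180, 180) first.
    """
    lat = np.asarray(lat, dtype=float)
    if ((lat < -90) | (lat >= 90)).any():
        raise ValueError("latitude outside [-90, 90)")
    lon = normalize_lon(lon)
    lat_idx = np.floor(lat).astype(int)
    lon_idx = np.floor(lon).astype(int)
    if lat_idx.ndim == 0:
        return (int(lat_idx), int(lon_idx))
    return (lat_idx, lon_idx)


def filter_records(
    records: pd.DataFrame,
    max_depth: float = 60.0,
    require_zoox: bool = True,
    drop_missing_depth: bool = False,
) -> pd.DataFrame:
    """Apply the depth and symbiosis filters.

    Depth boundary is inclusive (a 60.0 m record survives a 60 m cutoff).
    Records with missing depth are retained by default with a logged warning
    (depth fields in occurrence databases are sparse); set
    ``drop_missing_depth=True`` to discard them instead.
    """
    depth = records["depth_m"]
    missing = depth.isna()
    too_deep = depth > max_depth  # NaN compares False: missing handled apart
    azoox = ~records["zooxanthellate"].astype(bool) if require_zoox else pd.Series(
        False, index=records.index
    )

    drop = too_deep | azoox
    if drop_missing_depth:
        drop = drop | missing
    elif missing.any():
        logger.warning("retaining %d records with missing depth", int(missing.sum()))

    logger.info(
        "filter_records: dropped %d too deep (> %g m), %d azooxanthellate, "
        "%d missing depth; %d retained",
        int(too_deep.sum()),
        max_depth,
        int(azoox.sum()),
        int((missing & drop).sum()) if drop_missing_depth else 0,
        int((~drop).sum()),
    )
    return records.loc[~drop].copy()


def build_matrix(records: pd.DataFrame, rank: str = "species",
                 presence_absence: bool = False) -> AssemblageMatrix:
    """Grid records into 1-degree cells and compute proportional composition.

    p[cell, taxon] = (records of taxon in cell) / (records in cell).  With
    ``presence_absence=True`` each taxon counts at most once per cell before
    normalizing.  Taxa are ordered alphabetically and cells by
    (lat_index, lon_index), so the matrix is invariant to input record order.
    """
    if rank not in ("species", "genus"):
        raise ValueError("rank must be 'species' or 'genus'")
    taxon_col = "taxon" if rank == "species" else "genus"

    df = records.copy()
    lat_idx, lon_idx = assign_cell(df["lat"].to_numpy(), df["lon"].to_numpy())
    df["lat_index"] = lat_idx
    df["lon_index"] = lon_idx

    counts = (
        df.groupby(["lat_index", "lon_index", taxon_col], sort=True)
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=1)
    )
    if presence_absence:
        counts = (counts > 0).astype(float)
    props = counts.div(counts.sum(axis=1), axis=0)

    if rank == "species":
        genus_map = df.drop_duplicates("taxon").set_index("taxon")["genus"].to_dict()
    else:
        genus_map = {g: g for g in props.columns}
    epoch = df["epoch"].iloc[0] if len(df) else "modern"
    return AssemblageMatrix(props=props, rank=rank, epoch=epoch, genus_map=genus_map)


def apply_cell_filters(matrix: AssemblageMatrix, min_genera: int = 2) -> AssemblageMatrix:
    """Drop cells occupied by fewer than ``min_genera`` distinct genera.

    Taxon columns left with no occupied cell are removed too; that cannot
    change row sums, so no renormalization happens here.  Raises if every
    cell is filtered away.
    """
    rich = matrix.genus_richness()
    keep = rich[rich >= min_genera].index
    if len(keep) == 0:
        raise ValueError(f"all cells have < {min_genera} genera")
    dropped = len(matrix.props) - len(keep)
    if dropped:
        logger.info("apply_cell_filters: dropped %d of %d cells", dropped,
                    len(matrix.props))
    props = matrix.props.loc[keep]
    props = props.loc[:, (props > 0).any(axis=0)]
    return AssemblageMatrix(
        props=props, rank=matrix.rank, epoch=matrix.epoch,
        genus_map={t: g for t, g in matrix.genus_map.items() if t in props.columns},
    )


def harmonize_taxa(
    modern: AssemblageMatrix,
    fossil: AssemblageMatrix,
    min_genera: int = 2,
) -> tuple[AssemblageMatrix, AssemblageMatrix]:
    """Restrict both matrices to the shared taxon pool and renormalize.

    Mirrors calibrating on extant taxa that also have a fossil record: both
    matrices keep only the taxon intersection (identical column order), rows
    are rescaled to sum 1, emptied cells dropped, and the min-genera cell
    filter re-applied.
    """
    if modern.rank != fossil.rank:
        raise ValueError("matrices must share taxonomic rank")
    shared = sorted(set(modern.taxa) & set(fossil.taxa))
    if not shared:
        raise ValueError("modern and fossil matrices share no taxa")

    out = []
    for m in (modern, fossil):
        props = m.props[shared]
        rowsum = props.sum(axis=1)
        props = props.loc[rowsum > 0].div(rowsum[rowsum > 0], axis=0)
        restricted = AssemblageMatrix(
            props=props, rank=m.rank, epoch=m.epoch,
            genus_map={t: g for t, g in m.genus_map.items() if t in shared},
        )
        filtered = apply_cell_filters(restricted, min_genera=min_genera)
        # keep identical column order across the pair, even for taxa that end
        # up unoccupied on one side (they are structural zeros downstream)
        filtered.props = filtered.props.reindex(columns=shared, fill_value=0.0)
        filtered.genus_map = dict(restricted.genus_map)
        out.append(filtered)
    return out[0], out[1]
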