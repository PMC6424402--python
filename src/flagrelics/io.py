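"""Readers and writers for the pipeline's tabular and volumetric formats.

Point tables are TSV/CSV files with the header
``pole_id, structure_id, label, x_nm, y_nm``; density maps are MRC2014
volumes (read and written through gemmi).  Lengths are nm everywhere inside
the package; the MRC boundary stores Angstrom and is converted exactly once
on read/write.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .maps import DensityMap
from .spatial import ALLOWED_LABELS, PolePattern

POINT_TABLE_COLUMNS = ["pole_id", "structure_id", "label", "x_nm", "y_nm"]


class PointTableFormatError(ValueError):
    """Malformed point table (missing column, bad label, bad number)."""


class MapFormatError(ValueError):
    """Malformed or unreadable MRC file."""


def read_point_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a point table; rows keep file order.

    *dialect* is ``"tsv"`` or ``"csv"``; when omitted it is taken from the
    file suffix (default tsv).  Raises :class:`PointTableFormatError` naming
    the missing column, the offending label, or the row of a non-numeric
    coordinate.
    """
    path = Path(path)
    sep = _separator(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in POINT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PointTableFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {POINT_TABLE_COLUMNS}"
        )
    df = df[POINT_TABLE_COLUMNS].copy()
    bad = ~df["label"].isin(ALLOWED_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PointTableFormatError(
            f"{path}: row {row + 1}: label {df['label'].iloc[row]!r} not in "
            f"allowed labels {list(ALLOWED_LABELS)}"
        )
    for col in ("x_nm", "y_nm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        nonnum = vals.isna().to_numpy()
        if nonnum.any():
            row = int(np.flatnonzero(nonnum)[0])
            raise PointTableFormatError(
                f"{path}: row {row + 1}: non-numeric {col} value "
                f"{df[col].iloc[row]!r}"
            )
        if not np.all(np.isfinite(vals.to_numpy())):
            row = int(np.flatnonzero(~np.isfinite(vals.to_numpy()))[0])
            raise PointTableFormatError(
                f"{path}: row {row + 1}: non-finite {col} value"
            )
        df[col] = vals.astype(float)
    return df


def write_point_table(
    df: pd.DataFrame, path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    sep = _separator(path, dialect)
    missing = [c for c in POINT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PointTableFormatError(f"cannot write table missing columns {missing}")
    df[POINT_TABLE_COLUMNS].to_csv(path, sep=sep, index=False)


def _separator(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")


def patterns_from_table(
    df: pd.DataFrame, cring_diameter_nm: float = 45.0
) -> list[PolePattern]:
    """Group a point table into one :class:`PolePattern` per pole id."""
    out = []
    for pole_id, grp in df.groupby("pole_id", sort=False):
        out.append(
            PolePattern(
                pole_id=str(pole_id),
                xy=grp[["x_nm", "y_nm"]].to_numpy(dtype=float),
                labels=grp["label"].to_numpy(dtype=object),
                cring_diameter_nm=cring_diameter_nm,
            )
        )
    return out


def table_from_patterns(patterns: Iterable[PolePattern]) -> pd.DataFrame:
    rows = []
    for p in patterns:
        for i in range(p.n_points):
            rows.append(
                {
                    "pole_id": p.pole_id,
                    "structure_id": f"{p.pole_id}_s{i:03d}",
                    "label": p.labels[i],
                    "x_nm": float(p.xy[i, 0]),
                    "y_nm": float(p.xy[i, 1]),
                }
            )
    return pd.DataFrame(rows, columns=POINT_TABLE_COLUMNS)


# --------------------------------------------------------------------------
# Density maps (MRC2014 via gemmi)


def read_density_map(path: str | Path) -> DensityMap:
    """Read an MRC2014 map; voxel size converted Angstrom -> nm.

    Anisotropic voxels trigger a warning and the mean spacing is used; the
    symmetry operations require genuinely cubic voxels, so resample
    anisotropic maps before using them there.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"{path}: cannot read MRC map: {exc}") from exc
    spacing_ang = np.array(ccp4.grid.spacing, dtype=float)
    if spacing_ang.min() <= 0:
        raise MapFormatError(f"{path}: non-positive voxel size in header")
    if not np.allclose(spacing_ang, spacing_ang[0], rtol=1e-4):
        warnings.warn(
            f"{path}: anisotropic voxels {spacing_ang} A; using the mean — "
            "resample before any rotational-symmetry operation",
            stacklevel=2,
        )
    data = np.array(ccp4.grid, copy=True)
    return DensityMap(data=data, voxel_size_nm=float(spacing_ang.mean()) / 10.0)


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Write MRC2014 with recomputed header statistics (nm -> Angstrom)."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.data, dtype=np.float32))
    ang = dmap.voxel_size_nm * 10.0
    nz, ny, nx = dmap.shape
    # gemmi.FloatGrid(np_array) uses the array's (nx, ny, nz) ordering of
    # its own accessors; the unit cell must match the grid dimensions
    grid.set_unit_cell(
        gemmi.UnitCell(grid.nu * ang, grid.nv * ang, grid.nw * ang, 90, 90, 90)
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def map_header_stats(path: str | Path) -> dict[str, float]:
    """Header dmin/dmax/dmean/rms of an MRC file (words 20-22 and 55)."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    return {
        "dmin": float(ccp4.header_float(20)),
        "dmax": float(ccp4.header_float(21)),
        "dmean": float(ccp4.header_float(22)),
        "rms": float(ccp4.header_float(55)),
    }


# --------------------------------------------------------------------------
# Other tabular formats


def write_population_table(timepoints, path: str | Path) -> None:
    """Population TSV: t_h, od600, cfu_per_ml, counts (comma list)."""
    rows = [
        {
            "t_h": tp.t_h,
            "od600": tp.od600,
            "cfu_per_ml": tp.cfu_per_ml,
            "counts": ",".join(str(int(c)) for c in tp.counts),
        }
        for tp in timepoints
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_population_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["counts"] = df["counts"].apply(
        lambda s: np.array([int(x) for x in str(s).split(",")])
    )
    return df


def write_tracks_table(tracks, path: str | Path) -> None:
    """Track TSV: track_id, t_s, x_um, y_um (one row per sample)."""
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t_s, tr.x_um, tr.y_um):
            rows.append(
                {"track_id": tr.track_id, "t_s": t, "x_um": x, "y_um": y}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tracks_table(path: str | Path):
    from .simulate import SwimTrack

    df = pd.read_csv(path, sep="\t")
    out = []
    for tid, grp in df.groupby("track_id", sort=False):
        out.append(
            SwimTrack(
                track_id=str(tid),
                t_s=grp["t_s"].to_numpy(float),
                x_um=grp["x_um"].to_numpy(float),
                y_um=grp["y_um"].to_numpy(float),
            )
        )
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
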