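"""Reading, writing and filtering of labeled volumes and per-cell tables.

A *labeled volume* is a 3D integer grid in which each voxel carries the ID of
the cell it belongs to (0, or any configured background label, marks the
exterior or cell walls).  A *cell table* is the long-format per-cell attribute
table exported by 3D morphometry software: one row per cell with its sample,
developmental stage, tissue annotation and volume in µm³.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, SchemaError

__all__ = [
    "LabeledVolume",
    "TableSchema",
    "DEFAULT_STAGE_ORDER",
    "read_labeled_volume",
    "write_labeled_volume",
    "read_cell_table",
    "filter_small_cells",
    "restrict_to_tissue",
]

#: Ovule developmental stages in chronological order.
DEFAULT_STAGE_ORDER: tuple[str, ...] = (
    "1-I", "1-II",
    "2-I", "2-II", "2-III", "2-IV", "2-V",
    "3-I", "3-II", "3-III", "3-IV", "3-V", "3-VI",
)

#: Default HDF5 dataset name holding the label grid.
HDF5_DATASET = "labels"

#: Cells below this volume (µm³) are segmentation artifacts; see
#: :func:`filter_small_cells`.  The boundary value itself is retained.
SMALL_CELL_THRESHOLD = 30.0


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D cell-resolution segmentation.

    Parameters
    ----------
    labels
        3D array of non-negative integers; one cell ID per voxel.
    spacing
        Physical voxel size ``(dz, dy, dx)`` in µm.
    background
        Label values that mark exterior / non-cell voxels.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background: frozenset[int] = frozenset({0})

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"label array must be integer, got dtype={arr.dtype}")
        if arr.size and arr.min() < 0:
            raise ValueError("label array contains negative values")
        object.__setattr__(self, "labels", arr)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "background", frozenset(int(b) for b in self.background))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        """Sorted array of distinct non-background labels."""
        out = np.unique(self.labels)
        mask = ~np.isin(out, list(self.background))
        return out[mask]

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels().size)

    def border_labels(self) -> frozenset[int]:
        """Cells whose voxels touch any face of the volume."""
        a = self.labels
        faces = np.concatenate([
            a[0].ravel(), a[-1].ravel(),
            a[:, 0].ravel(), a[:, -1].ravel(),
            a[:, :, 0].ravel(), a[:, :, -1].ravel(),
        ])
        return frozenset(int(x) for x in np.unique(faces)) - self.background

    def interior_labels(self) -> frozenset[int]:
        """Cells that do not touch the volume boundary."""
        return frozenset(int(x) for x in self.cell_labels()) - self.border_labels()

    def with_labels(self, labels: np.ndarray) -> "LabeledVolume":
        return dataclasses.replace(self, labels=labels)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tiff", "hdf5"):
            raise ValueError(f"unknown volume format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer volume format from suffix {suffix!r}")


def read_labeled_volume(
    path: str | Path,
    format: str | None = None,
    spacing: tuple[float, float, float] | None = None,
    background: Iterable[int] = (0,),
    dataset: str = HDF5_DATASET,
) -> LabeledVolume:
    """Read a labeled segmentation volume from TIFF or HDF5.

    2D TIFF pages are promoted to single-slice 3D grids; any other
    dimensionality is an error.  For HDF5, ``spacing`` stored as a dataset
    attribute is used when the argument is omitted.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    stored_spacing = None
    if fmt == "tiff":
        arr = np.asarray(tifffile.imread(path))
    else:
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise FormatError(f"dataset {dataset!r} not found in {path}")
            ds = f[dataset]
            arr = ds[()]
            if "spacing" in ds.attrs:
                stored_spacing = tuple(float(s) for s in ds.attrs["spacing"])
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: voxel data is {arr.dtype}, expected integers")
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={arr.ndim}")
    if spacing is None:
        spacing = stored_spacing or (1.0, 1.0, 1.0)
    return LabeledVolume(arr, spacing=spacing, background=frozenset(background))


def write_labeled_volume(
    vol: LabeledVolume,
    path: str | Path,
    format: str | None = None,
    dataset: str = HDF5_DATASET,
) -> Path:
    """Write a labeled volume; round-trips bit-exactly with the reader."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        tifffile.imwrite(path, vol.labels)
    else:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=vol.labels, compression="gzip")
            ds.attrs["spacing"] = np.asarray(vol.spacing, dtype=float)
            ds.attrs["background"] = np.asarray(sorted(vol.background), dtype=np.int64)
    return path


@dataclass(frozen=True)
class TableSchema:
    """Mapping from CSV column headers to the canonical cell-table fields.

    Attribute exports name their columns inconsistently across tools and
    versions, so the mapping is configurable; the defaults follow the common
    label / tissue / volume convention.
    """

    sample_id: str = "sample"
    cohort: str | None = "cohort"
    stage: str = "stage"
    cell_id: str = "label"
    tissue_id: str = "tissue"
    volume: str = "volume"
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "TableSchema":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        kw = dict(mapping)
        if "stage_order" in kw:
            kw["stage_order"] = tuple(str(s) for s in kw["stage_order"])  # type: ignore[arg-type]
        return cls(**kw)  # type: ignore[arg-type]


#: Canonical columns of a cell table, in output order.
CELL_TABLE_COLUMNS = ("sample_id", "cohort", "stage", "cell_id", "tissue_id", "volume")


def read_cell_table(path: str | Path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a long-format per-cell attribute CSV into canonical form.

    Returns a DataFrame with columns ``sample_id, cohort, stage, cell_id,
    tissue_id, volume``; ``stage`` is an ordered categorical over the
    schema's stage list.
    """
    schema = schema or TableSchema()
    raw = pd.read_csv(path)
    mapping = {
        "sample_id": schema.sample_id,
        "stage": schema.stage,
        "cell_id": schema.cell_id,
        "tissue_id": schema.tissue_id,
        "volume": schema.volume,
    }
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    df = pd.DataFrame({dst: raw[src] for dst, src in mapping.items()})
    if schema.cohort is not None and schema.cohort in raw.columns:
        df["cohort"] = raw[schema.cohort].astype(str)
    else:
        df["cohort"] = ""
    return _validate_cell_table(df, schema.stage_order, origin=str(path))


def _validate_cell_table(
    df: pd.DataFrame, stage_order: tuple[str, ...], origin: str = "cell table"
) -> pd.DataFrame:
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["stage"] = df["stage"].astype(str)
    unknown = sorted(set(df["stage"]) - set(stage_order))
    if unknown:
        raise ValueError(
            f"{origin}: stage value(s) {unknown} not in declared stage order {list(stage_order)}"
        )
    df["stage"] = pd.Categorical(df["stage"], categories=stage_order, ordered=True)
    try:
        df["volume"] = pd.to_numeric(df["volume"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{origin}: non-numeric volume values") from exc
    if (df["volume"] <= 0).any():
        bad = df.loc[df["volume"] <= 0].head(3)
        raise ValueError(f"{origin}: non-positive cell volumes, e.g.\n{bad}")
    df["cell_id"] = df["cell_id"].astype(np.int64)
    if (df["cell_id"] <= 0).any():
        raise ValueError(f"{origin}: cell IDs must be positive integers")
    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        pair = df.loc[dup, ["sample_id", "cell_id"]].iloc[0]
        raise ValueError(
            f"{origin}: duplicate (sample_id, cell_id) pair "
            f"({pair['sample_id']!r}, {pair['cell_id']})"
        )
    return df[list(CELL_TABLE_COLUMNS)]


def filter_small_cells(table: pd.DataFrame, threshold: float = SMALL_CELL_THRESHOLD) -> pd.DataFrame:
    """Drop segmentation-artifact cells with volume strictly below ``threshold`` µm³.

    Cells exactly at the threshold are retained.  Row order is preserved.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return table.loc[table["volume"] >= threshold].copy()


def restrict_to_tissue(
    vol: LabeledVolume, table: pd.DataFrame, tissues: Iterable
) -> LabeledVolume:
    """Remap voxels of cells outside the selected tissue(s) to background.

    ``tissues`` is a set of tissue IDs as they appear in the cell table.
    Retained cell labels are unchanged, so downstream complexes are built on
    exactly the cells annotated with the selected tissues.
    """
    tissues = set(tissues)
    if not tissues:
        raise ValueError("empty tissue selection")
    present = set(table["tissue_id"])
    if not (tissues & present):
        raise ValueError(
            f"none of the selected tissues {sorted(map(str, tissues))} occur in the table"
        )
    keep = table.loc[table["tissue_id"].isin(tissues), "cell_id"].to_numpy()
    bg_value = min(vol.background)
    mask = np.isin(vol.labels, keep) | np.isin(vol.labels, list(vol.background))
    new = np.where(mask, vol.labels, bg_value)
    return vol.with_labels(new.astype(vol.labels.dtype))
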