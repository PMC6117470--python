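"""File formats: calibrated image stacks, punctum tables, atlases, matrices.

All tabular artifacts are delimited text with a ``#``-prefixed provenance
header; images and label masks are TIFF.  Every reader/writer pair is a
round-trip identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import Provenance

__all__ = [
    "ImageStack",
    "RegionAtlas",
    "read_image_stack",
    "write_image_stack",
    "read_punctum_table",
    "write_punctum_table",
    "read_atlas",
    "write_atlas",
    "read_matrix",
    "write_matrix",
    "MANDATORY_COLUMNS",
]

#: Columns a punctum table must provide.  Coordinates are physical (nm).
MANDATORY_COLUMNS = ("channel", "x_nm", "y_nm")

#: Full measurement column set written by the measurement stage.
MEASUREMENT_COLUMNS = (
    "intensity",      # mean gray value per punctum, AU
    "size_um2",       # segmented area, um^2
    "skewness",       # standardized 3rd moment of within-mask intensities
    "kurtosis",       # standardized 4th moment (Fisher) of intensities
    "circularity",    # 4*pi*A/P^2, in (0, 1]
    "aspect_ratio",   # major/minor axis of the intensity-weighted ellipse
)

LABEL_COLUMNS = ("type", "subtype", "pair_id")


@dataclass
class ImageStack:
    """A 2D image or 3D stack with physical calibration.

    ``data`` is (z, y, x) or (y, x); ``pixel_size_nm`` is (y, x).
    """

    data: np.ndarray
    pixel_size_nm: tuple[float, float] | None = None
    z_step_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("image must be 2D or a 3D stack")

    @property
    def calibrated(self) -> bool:
        return self.pixel_size_nm is not None

    def require_calibration(self) -> tuple[float, float]:
        if self.pixel_size_nm is None:
            raise ValueError(
                "operation requires physical calibration but the stack has "
                "no pixel size; pass calibration explicitly"
            )
        return self.pixel_size_nm

    def max_project(self) -> "ImageStack":
        """Maximum-intensity projection along z (identity for 2D)."""
        if self.data.ndim == 2:
            return self
        return ImageStack(self.data.max(axis=0), self.pixel_size_nm, self.z_step_nm)

    def pixel_to_nm(self, yx: np.ndarray) -> np.ndarray:
        """Convert continuous (y, x) pixel coordinates to nm at pixel centers."""
        py, px = self.require_calibration()
        yx = np.atleast_2d(np.asarray(yx, dtype=float))
        return yx * np.array([py, px])


def read_image_stack(
    path: str | Path,
    pixel_size_nm: tuple[float, float] | None = None,
    z_step_nm: float | None = None,
) -> ImageStack:
    """Read a 2D/3D integer TIFF, preserving sample values losslessly."""
    data = tifffile.imread(str(path))
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: expected integer samples, got {data.dtype}")
    return ImageStack(data, pixel_size_nm=pixel_size_nm, z_step_nm=z_step_nm)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.data)


def _write_table(df: pd.DataFrame, path: str | Path, provenance: Provenance | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance is not None:
            for line in provenance.header_lines():
                fh.write(line + "\n")
        df.to_csv(fh, index=False)


def _read_header(path: Path) -> list[str]:
    lines = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            lines.append(line)
    return lines


def write_punctum_table(
    puncta: pd.DataFrame, path: str | Path, provenance: Provenance | None = None
) -> None:
    """Write one row per punctum as CSV.  Coordinates are in nm (header states
    units); type/subtype labels are kept as integers."""
    missing = [c for c in MANDATORY_COLUMNS if c not in puncta.columns]
    if missing:
        raise ValueError(f"punctum table missing mandatory columns: {missing}")
    df = puncta.copy()
    for col in ("type", "subtype", "pair_id", "channel", "id"):
        if col in df.columns and not df[col].isna().any():
            df[col] = df[col].astype(np.int64)
    _write_table(df, path, provenance)


def read_punctum_table(path: str | Path) -> pd.DataFrame:
    """Read a punctum table, validating mandatory columns.

    Unknown columns are preserved with a warning; missing mandatory columns
    raise.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    known = set(MANDATORY_COLUMNS) | set(MEASUREMENT_COLUMNS) | set(LABEL_COLUMNS) | {
        "id", "z_nm", "x_px", "y_px", "score", "coloc", "region", "genotype",
    }
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: unknown columns preserved: {unknown}", stacklevel=2)
    return df


@dataclass
class RegionAtlas:
    """Integer label raster plus the subregion -> overarching-area hierarchy.

    ``labels`` is a 2D array where 0 is unannotated background and positive
    integers are subregion ids.  ``hierarchy`` maps each region id to a row
    with at least ``name`` and ``parent`` (the overarching area name).
    """

    labels: np.ndarray
    hierarchy: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["region", "name", "parent"]))
    pixel_size_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be a 2D integer raster")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def region_area_px(self, region: int) -> int:
        return int((self.labels == region).sum())

    def parent_of(self, region: int) -> str:
        row = self.hierarchy[self.hierarchy["region"] == region]
        if row.empty:
            raise KeyError(f"region {region} not in hierarchy")
        return str(row["parent"].iloc[0])


def write_atlas(atlas: RegionAtlas, mask_path: str | Path, hierarchy_path: str | Path,
                provenance: Provenance | None = None) -> None:
    tifffile.imwrite(str(mask_path), atlas.labels.astype(np.uint16))
    _write_table(atlas.hierarchy, hierarchy_path, provenance)


def read_atlas(mask_path: str | Path, hierarchy_path: str | Path,
               pixel_size_nm: tuple[float, float] | None = None) -> RegionAtlas:
    labels = tifffile.imread(str(mask_path)).astype(np.int64)
    hierarchy = pd.read_csv(hierarchy_path, comment="#")
    return RegionAtlas(labels, hierarchy, pixel_size_nm)


def write_matrix(matrix: np.ndarray, ids: list, path: str | Path,
                 provenance: Provenance | None = None) -> None:
    """Write a labeled square matrix (similarity, distance) as CSV."""
    df = pd.DataFrame(np.asarray(matrix), index=ids, columns=ids)
    path = Path(path)
    with open(path, "w") as fh:
        if provenance is not None:
            for line in provenance.header_lines():
                fh.write(line + "\n")
        df.to_csv(fh, index=True, index_label="region")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, comment="#", index_col=0)
    ids = list(df.index)
    return df.to_numpy(dtype=float), ids


def read_provenance(path: str | Path) -> Provenance | None:
    return Provenance.from_header_lines(_read_header(Path(path)))


def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
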