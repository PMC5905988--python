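"""Image and table input/output.

Coordinates in all files are 0-based with x = column, y = row and the
origin at the top-left pixel center; sub-pixel reals are allowed.

The annotation CSV carries observer-style edge markings, one row per
profile: segment_id, point_index, center_x, center_y, edge1_x, edge1_y,
edge2_x, edge2_y. The measurement CSV carries one row per measured
profile: center coordinates, model id, the fitted parameter vector,
goodness-of-fit fields and the estimated (and, when matched, ground-truth)
width.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_annotations",
    "write_annotations",
    "read_measurements",
    "write_measurements",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = (
    "segment_id",
    "point_index",
    "center_x",
    "center_y",
    "edge1_x",
    "edge1_y",
    "edge2_x",
    "edge2_y",
)


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an (H, W, 3) float array in [0, 1]."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise OSError(f"{path}: expected a 2D grayscale or RGB image")
    return _to_unit_float(arr[:, :, :3])


def write_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary vessel mask; grayscale files are binarized at half
    their value range."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise OSError(f"{path}: mask must be a 2D image")
    if arr.dtype == bool:
        return arr
    return _to_unit_float(arr) > 0.5


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an edge-annotation table; unknown extra columns are preserved.

    Raises ValueError on missing columns, duplicate (segment_id,
    point_index) keys, or rows whose two edge points coincide (zero width).
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    if df.duplicated(subset=["segment_id", "point_index"]).any():
        raise ValueError(f"{path}: duplicate (segment_id, point_index) rows")
    widths = np.hypot(df.edge1_x - df.edge2_x, df.edge1_y - df.edge2_y)
    if (widths <= 0).any():
        bad = df.index[widths <= 0].tolist()
        raise ValueError(f"{path}: zero-width rows (edge1 == edge2) at {bad}")
    return df


def write_annotations(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def annotation_widths(table: pd.DataFrame) -> np.ndarray:
    """Ground-truth width per row: Euclidean edge-to-edge distance (px)."""
    return np.hypot(
        table.edge1_x - table.edge2_x, table.edge1_y - table.edge2_y
    ).to_numpy()


def write_measurements(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
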