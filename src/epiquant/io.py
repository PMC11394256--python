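"""Raster I/O and the per-sample batch report.

Images are plain ``numpy`` arrays: an RGB image is an ``H x W x 3`` uint8
array (row-major, origin top-left), a mask is an ``H x W`` boolean array
aligned to its source image.  Lossy inputs (JPEG) are accepted, but every
artifact this package writes (masks, overlays) is PNG so that a save/load
round trip is bit-exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Column order of the batch report CSV.
REPORT_COLUMNS = [
    "image_id",
    "marker",
    "rotation_deg",
    "tissue_px",
    "ap_percent",
    "is_positive",
    "k_clusters",
    "dab_percent",
]


def load_rgb_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file and return an ``H x W x 3`` uint8 array.

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped.  Raises ``IOError`` for unreadable files and ``ValueError`` for
    zero-size images.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {os.fspath(path)!r}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(
            f"unsupported image layout {arr.shape} in {os.fspath(path)!r}"
        )
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(arr)


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write an RGB or grayscale uint8 image as PNG."""
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG with values {0, 255}."""
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a {0, 255} PNG mask back into a boolean array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


@dataclass
class SampleResult:
    """Per-image record emitted by the pipeline.

    ``dab_percent`` is the percentage of the tissue area occupied by the
    segmented DAB-positive region; samples gated out as negative report
    ``dab_percent = 0`` and ``k_clusters = 0``.
    """

    image_id: str
    rotation_deg: float = 0.0
    tissue_px: int = 0
    ap_percent: float = float("nan")
    is_positive: bool = False
    k_clusters: int = 0
    dab_percent: float = 0.0
    marker: str = ""
    low_contrast: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (np.isnan(self.dab_percent) or 0.0 <= self.dab_percent <= 100.0):
            raise ValueError(f"dab_percent out of [0, 100]: {self.dab_percent}")
        if not self.is_positive:
            self.dab_percent = 0.0
            self.k_clusters = 0


def write_report(results: list[SampleResult], path: str | os.PathLike) -> None:
    """Write the batch report CSV (header + one row per sample).

    UTF-8, comma-separated, '.' decimal; columns exactly ``REPORT_COLUMNS``.
    """
    rows = [
        {
            "image_id": r.image_id,
            "marker": r.marker,
            "rotation_deg": r.rotation_deg,
            "tissue_px": r.tissue_px,
            "ap_percent": r.ap_percent,
            "is_positive": r.is_positive,
            "k_clusters": r.k_clusters,
            "dab_percent": r.dab_percent,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_report(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a report CSV written by :func:`write_report`."""
    return pd.read_csv(path)
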