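"""Tissue-vs-background masking from the hematoxylin grayscale channel.

Stained tissue absorbs light, so it is darker than the near-white slide
background: Otsu's threshold on the hematoxylin rendering separates the two
populations, and a fixed morphology sequence (opening, closing, hole
filling with a disk structuring element, then largest-component selection,
then the same morphology once more) cleans specks, artifacts and interior
holes, leaving a single solid tissue region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk


@dataclass(frozen=True)
class MorphologyParams:
    """Structuring-element and cleanup options for the tissue mask."""

    se_shape: str = "disk"
    se_radius: int = 15
    fill_holes: bool = True
    min_tissue_fraction: float = 0.005

    def __post_init__(self) -> None:
        if self.se_shape != "disk":
            raise ValueError("only disk structuring elements are supported")
        if self.se_radius < 1:
            raise ValueError("se_radius must be >= 1")


def otsu_threshold(gray: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold on the 256-bin histogram.

    Returns an integer ``t``; tissue (foreground) is the dark class
    ``gray <= t``.  Raises ``ValueError`` for a constant image.
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        gray = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    if np.unique(gray).size < 2:
        raise ValueError("degenerate histogram: image has a single intensity")
    return int(threshold_otsu(gray))


def _clean(mask: np.ndarray, footprint: np.ndarray, fill: bool) -> np.ndarray:
    mask = ndi.binary_opening(mask, structure=footprint)
    mask = ndi.binary_closing(mask, structure=footprint)
    if fill:
        mask = ndi.binary_fill_holes(mask)
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def make_tissue_mask(
    hema_gray: np.ndarray, params: MorphologyParams = MorphologyParams()
) -> np.ndarray:
    """Build the tissue mask from the hematoxylin grayscale rendering.

    Sequence: Otsu binarization (dark = tissue), opening/closing/hole
    filling with a disk SE, largest-component selection, then the same
    morphology pass once more (re-selecting the largest component if the
    second pass splits the region).  Raises ``ValueError`` when no tissue
    is found or the mask is smaller than ``min_tissue_fraction`` of the
    frame.
    """
    gray = np.asarray(hema_gray)
    t = otsu_threshold(gray)
    binary = gray <= t
    if not binary.any():
        raise ValueError("no tissue detected: empty foreground after thresholding")
    fp = disk(params.se_radius)
    mask = _clean(binary, fp, params.fill_holes)
    mask = largest_component(mask)
    mask = _clean(mask, fp, params.fill_holes)
    mask = largest_component(mask)
    if mask.sum() < params.min_tissue_fraction * mask.size:
        raise ValueError(
            "no tissue detected: foreground below "
            f"{params.min_tissue_fraction:.3%} of the frame"
        )
    return mask
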