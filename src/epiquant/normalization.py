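"""Reinhard color transfer in the l-alpha-beta opponent color space.

Color variation between slides (section thickness, stain timing, camera
settings) is removed by matching the per-channel mean and standard deviation
of each image to a reference in Ruderman's decorrelated l-alpha-beta space:
RGB -> LMS cone response -> log10 -> opponent axes.  After mapping back to
RGB the result is stretched to the full intensity range (one global
min/max, the ``mat2gray`` convention) before 8-bit re-quantization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

# Ruderman et al. RGB -> LMS and its inverse, plus the log-LMS -> l-alpha-beta
# decorrelating rotation, as used in Reinhard's color transfer.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
# Inverses are computed from the forward constants (the independently
# rounded published inverses would leave a ~2-level round-trip error).
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOGLMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)

#: Intensities are clamped to at least this before the log (one 8-bit step).
LOG_EPS = 1.0 / 255.0

#: Channel spread below this (l-alpha-beta units) counts as degenerate; any
#: non-constant 8-bit image has a spread orders of magnitude larger.
DEGENERATE_STD = 1e-8


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and population std in l-alpha-beta space."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float).reshape(3))
        object.__setattr__(self, "std", np.asarray(self.std, float).reshape(3))
        if np.any(self.std < 0):
            raise ValueError("std components must be >= 0")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean flags for channels with (numerically) zero spread."""
        return self.std <= DEGENERATE_STD


def rgb_to_lab_opponent(image: np.ndarray) -> np.ndarray:
    """Map an RGB image to l-alpha-beta planes (H x W x 3, float).

    Zero intensities are offset to ``LOG_EPS`` so the log is finite.
    """
    rgb = np.asarray(image, float) / 255.0
    rgb = np.maximum(rgb, LOG_EPS)
    lms = rgb @ _RGB2LMS.T
    lms = np.maximum(lms, 1e-12)
    return np.log10(lms) @ _LOGLMS2LAB.T


def lab_opponent_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab_opponent`; returns float RGB in [0, 1]."""
    loglms = np.asarray(lab, float) @ _LAB2LOGLMS.T
    lms = np.power(10.0, loglms)
    rgb = lms @ _LMS2RGB.T
    return np.clip(rgb, 0.0, 1.0)


def compute_channel_stats(lab: np.ndarray) -> ChannelStats:
    """Per-channel mean and population standard deviation over all pixels."""
    lab = np.asarray(lab, float)
    if lab.size == 0:
        raise ValueError("empty image")
    flat = lab.reshape(-1, 3)
    stats = ChannelStats(mean=flat.mean(axis=0), std=flat.std(axis=0, ddof=0))
    if np.any(stats.degenerate):
        logger.warning("degenerate (zero-std) l-alpha-beta channel(s): %s",
                       np.nonzero(stats.degenerate)[0].tolist())
    return stats


def minmax_stretch(rgb01: np.ndarray) -> np.ndarray:
    """Global min-max stretch of a float RGB image to [0, 1].

    One minimum and maximum over all channels jointly (the ``mat2gray``
    convention on an RGB array), so channel ratios -- and therefore the
    stain balance seen by downstream deconvolution -- are preserved up to
    a single affine gain.  A zero-range image is returned unchanged.
    """
    out = np.asarray(rgb01, float).copy()
    lo = out.min()
    hi = out.max()
    if hi - lo > 1e-9:  # below one float step of an 8-bit level: no spread
        out = (out - lo) / (hi - lo)
    return out


def reinhard_normalize(
    source: np.ndarray,
    ref: ChannelStats,
    *,
    stretch: bool = True,
) -> np.ndarray:
    """Transfer the reference color statistics onto ``source``.

    Each l-alpha-beta channel is mapped ``x -> (x - mu_src) * (sigma_ref /
    sigma_src) + mu_ref``; a channel whose source spread is zero is shifted
    only (scale 1).  The result is converted back to RGB, optionally
    stretched channel-wise to the full range, and re-quantized to uint8.
    """
    if np.any(np.asarray(ref.std) <= 0):
        raise ValueError("reference stds must be > 0")
    lab = rgb_to_lab_opponent(source)
    src = compute_channel_stats(lab)
    scale = np.ones(3)
    ok = ~src.degenerate
    scale[ok] = ref.std[ok] / src.std[ok]
    if not ok.all():
        logger.warning("source channel(s) %s have zero spread; shifting only",
                       np.nonzero(~ok)[0].tolist())
    mapped = (lab - src.mean) * scale + ref.mean
    rgb = lab_opponent_to_rgb(mapped)
    if stretch:
        rgb = minmax_stretch(rgb)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
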