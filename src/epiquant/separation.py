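"""Ruifrok-Johnston color deconvolution for H-DAB stained images.

Stains mix additively in optical density (Beer-Lambert), so a pixel's OD
vector is ``c_H * V_H + c_D * V_D + c_R * V_R`` where ``V_s`` are unit
absorbance ("stain") vectors.  Inverting the stain matrix yields per-pixel
concentration planes for hematoxylin, DAB and a residual channel.

The default H-DAB vectors are the published constants of the ImageJ
"Colour Deconvolution 2" plugin, which in side-by-side comparisons gives the
cleanest DAB channel for this material; they can be overridden through the
``stains.*`` configuration keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Hematoxylin absorbance vector (R, G, B), ImageJ Colour Deconvolution 2 H-DAB.
HDAB_HEMATOXYLIN = np.array([0.6500286, 0.704031, 0.2860126])
#: DAB absorbance vector (R, G, B), ImageJ Colour Deconvolution 2 H-DAB.
HDAB_DAB = np.array([0.26814753, 0.57031375, 0.77642715])


@dataclass(frozen=True)
class StainMatrix:
    """3x3 matrix whose rows are unit stain OD vectors (H, DAB, residual)."""

    matrix: np.ndarray
    inverse: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float).reshape(3, 3)
        norms = np.linalg.norm(m, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("stain matrix rows must be unit vectors")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "inverse", np.linalg.inv(m))

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def dab(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def residual(self) -> np.ndarray:
        return self.matrix[2]


def build_stain_matrix(
    h_vec: np.ndarray = HDAB_HEMATOXYLIN, dab_vec: np.ndarray = HDAB_DAB
) -> StainMatrix:
    """Normalize the two stain vectors and complete with their cross product.

    Raises ``ValueError`` if the inputs are zero or collinear.
    """
    h = np.asarray(h_vec, float).reshape(3)
    d = np.asarray(dab_vec, float).reshape(3)
    hn = np.linalg.norm(h)
    dn = np.linalg.norm(d)
    if hn == 0 or dn == 0:
        raise ValueError("stain vectors must be nonzero")
    h = h / hn
    d = d / dn
    r = np.cross(h, d)
    rn = np.linalg.norm(r)
    if rn < 1e-9:
        raise ValueError("stain vectors are collinear; matrix would be singular")
    return StainMatrix(np.stack([h, d, r / rn]))


def rgb_to_od(image: np.ndarray, background: float = 255.0) -> np.ndarray:
    """Convert intensities to optical density.

    ``OD_c = -log10((I_c + 1) / (background + 1))`` per channel; the +1
    offsets avoid log(0) and make the map exactly invertible on uint8 data.
    """
    if background <= 0:
        raise ValueError("background intensity must be > 0")
    img = np.asarray(image, float)
    return -np.log10((img + 1.0) / (background + 1.0))


def od_to_rgb(od: np.ndarray, background: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (returns float intensities, unrounded)."""
    return (background + 1.0) * np.power(10.0, -np.asarray(od, float)) - 1.0


@dataclass
class StainConcentrationMaps:
    """Per-pixel stain concentrations and single-stain renderings.

    ``raw`` keeps the unclipped concentrations for diagnostics; the named
    planes are clipped at zero.  ``dab_gray``/``hema_gray`` are 8-bit-scale
    transmittance renderings of one stain (darker = more stain); ``dab_rgb``
    and ``hema_rgb`` re-project one stain through its absorbance vector.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    raw: np.ndarray
    dab_gray: np.ndarray
    hema_gray: np.ndarray
    dab_rgb: np.ndarray
    hema_rgb: np.ndarray


def _single_stain_rgb(conc: np.ndarray, stain_vec: np.ndarray) -> np.ndarray:
    od = conc[..., None] * stain_vec[None, None, :]
    return np.clip(np.round(255.0 * np.power(10.0, -od)), 0, 255).astype(np.uint8)


def _single_stain_gray(conc: np.ndarray) -> np.ndarray:
    return np.clip(np.round(255.0 * np.power(10.0, -conc)), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stains: StainMatrix) -> StainConcentrationMaps:
    """Unmix an OD image into per-stain concentration maps.

    Row-vector convention: ``c = OD . M^-1`` so that ``OD = c . M``.
    """
    od = np.asarray(od, float)
    raw = od @ stains.inverse
    c = np.clip(raw, 0.0, None)
    return StainConcentrationMaps(
        hematoxylin=c[..., 0],
        dab=c[..., 1],
        residual=c[..., 2],
        raw=raw,
        dab_gray=_single_stain_gray(c[..., 1]),
        hema_gray=_single_stain_gray(c[..., 0]),
        dab_rgb=_single_stain_rgb(c[..., 1], stains.dab),
        hema_rgb=_single_stain_rgb(c[..., 0], stains.hematoxylin),
    )


def compose_od(
    c_h: np.ndarray, c_d: np.ndarray, stains: StainMatrix, c_r: np.ndarray | None = None
) -> np.ndarray:
    """Beer-Lambert forward composition of concentration planes into OD."""
    od = (
        np.asarray(c_h, float)[..., None] * stains.hematoxylin
        + np.asarray(c_d, float)[..., None] * stains.dab
    )
    if c_r is not None:
        od = od + np.asarray(c_r, float)[..., None] * stains.residual
    return od
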