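"""Seeded generator of H-DAB-like epidermis-strip images with ground truth.

There is no annotated public dataset for reconstructed-epidermis IHC, so
every pipeline stage is tested against fixtures built here: an elongated
tissue strip at a known angle on a near-white background, hematoxylin-blue
nuclei, and brown DAB patches covering a known fraction of the tissue.

Images are composed in optical density with the same default H-DAB stain
vectors the separation module uses (Beer-Lambert: ``I = 256 * 10^-OD - 1``),
so deconvolution of a noise-free fixture is exact in the stain span.  The
strip is a lens (two circular arcs meeting in tapered tips) rather than a
sharp-cornered rectangle: real epidermis strips taper at the ends, and the
pointed tips give the orientation search a sharply peaked objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .separation import StainMatrix, build_stain_matrix, compose_od


@dataclass(frozen=True)
class FixtureParams:
    """Geometry, staining and noise settings of one synthetic slide."""

    height: int = 480
    width: int = 640
    strip_angle: float = 25.0  # degrees CCW from horizontal
    strip_length: int = 420
    strip_thickness: int = 90
    dab_fraction: float = 0.2  # target fraction of tissue area
    nuclei_density: float = 5.0  # nuclei per 1000 tissue pixels
    noise_sd: float = 0.01  # stain-concentration noise, OD units
    artifact_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dab_fraction <= 1.0:
            raise ValueError("dab_fraction must be in [0, 1]")
        theta = np.deg2rad(self.strip_angle)
        ext_x = abs(np.cos(theta)) * self.strip_length + abs(np.sin(theta)) * self.strip_thickness
        ext_y = abs(np.sin(theta)) * self.strip_length + abs(np.cos(theta)) * self.strip_thickness
        if ext_x > self.width or ext_y > self.height:
            raise ValueError("strip does not fit in the frame at this angle")


@dataclass
class FixtureTruth:
    """Planted ground truth of a synthetic slide (pre-noise concentrations)."""

    tissue_mask: np.ndarray
    dab_mask: np.ndarray
    angle: float
    realized_dab_fraction: float
    c_h: np.ndarray = field(repr=False)
    c_d: np.ndarray = field(repr=False)


def _lens_mask(params: FixtureParams) -> np.ndarray:
    """Tapered strip: intersection of two disks, rotated to ``strip_angle``."""
    h, w = params.height, params.width
    t2 = params.strip_thickness / 2.0
    length = float(params.strip_length)
    r = (length**2 + params.strip_thickness**2) / (4.0 * params.strip_thickness)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a = np.deg2rad(params.strip_angle)
    # inverse of the CCW (y-down) forward rotation used everywhere else
    u = (xx - cx) * np.cos(a) - (yy - cy) * np.sin(a)
    v = (xx - cx) * np.sin(a) + (yy - cy) * np.cos(a)
    off = r - t2
    return (u**2 + (v - off) ** 2 <= r**2) & (u**2 + (v + off) ** 2 <= r**2)


def _stamp_disks(
    target: np.ndarray,
    allowed: np.ndarray,
    rng: np.random.Generator,
    goal_px: int,
    r_lo: int,
    r_hi: int,
) -> None:
    """Union random disks centered on ``allowed`` pixels into ``target``
    until it holds at least ``goal_px`` pixels of ``allowed``."""
    ys, xs = np.nonzero(allowed)
    h, w = target.shape
    guard = 0
    while int((target & allowed).sum()) < goal_px and guard < 10000:
        guard += 1
        i = rng.integers(ys.size)
        cy, cx = int(ys[i]), int(xs[i])
        r = int(rng.integers(r_lo, r_hi + 1))
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        target[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _add_nuclei(
    c_h: np.ndarray, tissue: np.ndarray, params: FixtureParams, rng: np.random.Generator
) -> None:
    """Elliptical Gaussian hematoxylin bumps at random tissue positions."""
    n = int(round(params.nuclei_density / 1000.0 * tissue.sum()))
    ys, xs = np.nonzero(tissue)
    h, w = tissue.shape
    for _ in range(n):
        i = rng.integers(ys.size)
        cy, cx = float(ys[i]), float(xs[i])
        a_ax = rng.uniform(3.0, 6.0)
        b_ax = rng.uniform(2.0, 4.0)
        amp = rng.uniform(0.5, 0.95)
        phi = rng.uniform(0, np.pi)
        half = int(np.ceil(3 * a_ax))
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        du = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
        dv = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
        c_h[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((du / a_ax) ** 2 + (dv / b_ax) ** 2))
    np.clip(c_h, 0.0, 1.3, out=c_h)


def generate_strip_image(
    params: FixtureParams = FixtureParams(),
    stains: StainMatrix | None = None,
) -> tuple[np.ndarray, FixtureTruth]:
    """Render one synthetic H-DAB slide and its ground truth.

    Deterministic given ``params.seed``.  The returned truth carries the
    planted (pre-noise) concentration fields, the exact tissue and DAB
    masks, the strip angle, and the realized DAB area fraction.
    """
    stains = stains or build_stain_matrix()
    rng = np.random.default_rng(params.seed)
    tissue = _lens_mask(params)
    tissue_px = int(tissue.sum())
    if tissue_px == 0:
        raise ValueError("infeasible geometry: empty tissue mask")

    # hematoxylin: cytoplasmic wash plus darker nuclei
    c_h = np.where(tissue, 0.35, 0.0)
    _add_nuclei(c_h, tissue, params, rng)

    # DAB: contiguous blobs grown until the target fraction is covered
    dab = np.zeros_like(tissue)
    if params.dab_fraction > 0:
        goal = int(round(params.dab_fraction * tissue_px))
        r_hi = max(3, params.strip_thickness // 8)
        _stamp_disks(dab, tissue, rng, goal, 2, r_hi)
        dab &= tissue
    c_d = np.where(dab, 0.9, 0.0)

    realized = float(dab.sum()) / tissue_px
    truth = FixtureTruth(
        tissue_mask=tissue,
        dab_mask=dab,
        angle=params.strip_angle,
        realized_dab_fraction=realized,
        c_h=c_h.copy(),
        c_d=c_d.copy(),
    )

    # stain-amount noise (only where the stain is present)
    c_h_n = c_h.copy()
    c_d_n = c_d.copy()
    if params.noise_sd > 0:
        c_h_n[tissue] += rng.normal(0.0, params.noise_sd, tissue_px)
        if dab.any():
            c_d_n[dab] += rng.normal(0.0, params.noise_sd, int(dab.sum()))
        np.clip(c_h_n, 0.0, None, out=c_h_n)
        np.clip(c_d_n, 0.0, None, out=c_d_n)

    od = compose_od(c_h_n, c_d_n, stains)
    image = np.clip(np.round(256.0 * np.power(10.0, -od) - 1.0), 0, 255).astype(np.uint8)

    # near-white jittered background
    bg = ~tissue
    image[bg] = rng.integers(247, 254, size=(int(bg.sum()), 3), dtype=np.int64).astype(np.uint8)

    # optional dark artifacts in the background
    if params.artifact_count > 0:
        art = np.zeros_like(tissue)
        for _ in range(params.artifact_count):
            ys, xs = np.nonzero(bg)
            i = rng.integers(ys.size)
            cy, cx = int(ys[i]), int(xs[i])
            r = int(rng.integers(4, 10))
            y0, y1 = max(0, cy - r), min(params.height, cy + r + 1)
            x0, x1 = max(0, cx - r), min(params.width, cx + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            art[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        art &= bg
        image[art] = 70
    return image, truth


def generate_labeled_set(
    n_pos: int, n_neg: int, seed: int = 0, **overrides
) -> list[tuple[np.ndarray, FixtureTruth, bool]]:
    """Positive/negative control set with per-image seeds from one master.

    Positives draw their DAB fraction uniformly from [0.05, 0.5]; negatives
    have none.  Extra keyword arguments override :class:`FixtureParams`
    fields shared by all images.
    """
    if n_pos + n_neg < 1:
        raise ValueError("need at least one image")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, FixtureTruth, bool]] = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        sub = int(rng.integers(2**31))
        frac = float(rng.uniform(0.05, 0.5)) if positive else 0.0
        angle = float(rng.uniform(1.0, 179.0))
        kwargs = {"strip_angle": angle, "dab_fraction": frac, "seed": sub}
        kwargs.update(overrides)
        params = FixtureParams(**kwargs)
        img, truth = generate_strip_image(params)
        out.append((img, truth, positive))
    return out
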