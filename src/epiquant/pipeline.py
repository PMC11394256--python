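"""End-to-end orchestration: single images and batch directories.

Stage order: color normalization -> stain deconvolution -> tissue masking
on the hematoxylin channel -> orientation search on the mask -> rotation
and crop of image, mask and DAB planes -> AP gate on the DAB grayscale ->
(if positive) k-means segmentation, DAB mask extraction and overlay.
Negative samples short-circuit after the gate and report zero occupancy.
"""

from __future__ import annotations

import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gating import GateParams, gate
from .io import REPORT_COLUMNS, SampleResult, load_rgb_image, save_image, save_mask, write_report
from .masking import MorphologyParams, make_tissue_mask
from .normalization import reinhard_normalize
from .orientation import RotationSearchParams, find_horizontal_rotation, rotate_and_crop
from .reference import resolve_reference
from .segmentation import ClusteringParams, draw_overlay, segment_dab
from .separation import build_stain_matrix, deconvolve, rgb_to_od

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


class PipelineStageError(RuntimeError):
    """Error raised by a pipeline stage, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    logger.info("stage %-12s %.3fs", stage, time.perf_counter() - t0)
    return out


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str = "sample",
    marker: str = "",
    out_dir: str | os.PathLike | None = None,
) -> SampleResult:
    """Process one RGB image and return its :class:`SampleResult`.

    Artifacts (tissue mask, DAB mask, overlay as PNG) are written when
    ``out_dir`` (or ``config.io.out_dir``) is set and the sample is
    DAB-positive.
    """
    config = config or PipelineConfig()
    out_dir = out_dir or config.io.out_dir

    if config.normalization.enabled:
        ref = resolve_reference(config.normalization.reference)
        work = _timed("normalize", reinhard_normalize, image, ref)
    else:
        work = image

    stains = build_stain_matrix(
        np.asarray(config.stains.h_vector, float),
        np.asarray(config.stains.dab_vector, float),
    )
    maps = _timed(
        "deconvolve",
        lambda: deconvolve(rgb_to_od(work, config.stains.background), stains),
    )

    tissue = _timed(
        "tissue_mask",
        make_tissue_mask,
        maps.hema_gray,
        MorphologyParams(
            se_radius=config.mask.se_radius,
            min_tissue_fraction=config.mask.min_tissue_fraction,
        ),
    )

    if config.rotation.enabled:
        rot = _timed(
            "rotation",
            find_horizontal_rotation,
            tissue,
            RotationSearchParams(
                angle_min=config.rotation.angle_min,
                angle_max=config.rotation.angle_max,
                angle_step=config.rotation.angle_step,
                coarse_to_fine=config.rotation.coarse_to_fine,
            ),
        )
        angle = rot.best_angle
        work_c, tissue_c, extras = _timed(
            "crop",
            rotate_and_crop,
            work,
            tissue,
            angle,
            config.rotation.margin_px,
            {"dab_gray": maps.dab_gray, "dab_rgb": maps.dab_rgb},
        )
        dab_gray_c = np.clip(np.round(extras["dab_gray"]), 0, 255)
        dab_rgb_c = np.clip(np.round(extras["dab_rgb"]), 0, 255)
    else:
        angle = 0.0
        work_c, tissue_c = work, tissue
        dab_gray_c, dab_rgb_c = maps.dab_gray, maps.dab_rgb

    gp = GateParams(
        pixel_threshold=config.gate.pixel_threshold, ap_cutoff=config.gate.ap_cutoff
    )
    g = _timed("gate", gate, dab_gray_c, tissue_c, gp)

    if not g.is_positive:
        logger.info("%s gated negative (AP=%.3f%% < %.3f%%)",
                    image_id, g.ap_percent, gp.ap_cutoff)
        return SampleResult(
            image_id=image_id,
            marker=marker,
            rotation_deg=float(angle),
            tissue_px=int(tissue_c.sum()),
            ap_percent=g.ap_percent,
            is_positive=False,
        )

    seg = _timed(
        "segment",
        segment_dab,
        dab_rgb_c,
        dab_gray_c,
        tissue_c,
        ClusteringParams(
            k_min=config.segment.k_min,
            k_max=config.segment.k_max,
            seed=config.segment.seed,
            n_init=config.segment.n_init,
            max_iter=config.segment.max_iter,
        ),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_mask(out / f"{image_id}_tissue_mask.png", tissue_c)
        save_mask(out / f"{image_id}_dab_mask.png", seg.dab_mask)
        save_image(out / f"{image_id}_overlay.png",
                   draw_overlay(np.asarray(work_c, np.uint8), seg.dab_mask))

    return SampleResult(
        image_id=image_id,
        marker=marker,
        rotation_deg=float(angle),
        tissue_px=int(tissue_c.sum()),
        ap_percent=g.ap_percent,
        is_positive=True,
        k_clusters=seg.k,
        dab_percent=seg.dab_percent,
        low_contrast=seg.low_contrast,
    )


def load_marker_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column CSV (filename, marker) into a dict."""
    df = pd.read_csv(path)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def summarize_markers(results: list[SampleResult]) -> pd.DataFrame:
    """Per-marker count, median and IQR of dab_percent among positives."""
    rows = []
    markers = sorted({r.marker for r in results})
    for m in markers:
        sub = [r.dab_percent for r in results if r.marker == m and r.is_positive]
        n_all = sum(1 for r in results if r.marker == m)
        if sub:
            q1, med, q3 = np.percentile(sub, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append(
            {"marker": m, "n_images": n_all, "n_positive": len(sub),
             "median_dab_percent": med, "q1_dab_percent": q1, "q3_dab_percent": q3}
        )
    return pd.DataFrame(rows)


def run_batch(
    input_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    marker_map: dict[str, str] | None = None,
    out_dir: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Process every readable image in a directory and write the report.

    Unreadable or tissue-less images are logged and recorded with NaN AP;
    the report CSV (and, when marker labels are given, a per-marker summary
    with NA for undefined medians) land in ``out_dir``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir or config.io.out_dir or input_dir)
    paths = sorted(
        p for p in Path(input_dir).iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not paths:
        raise ValueError(f"no readable images in {input_dir}")
    results: list[SampleResult] = []
    for p in paths:
        marker = (marker_map or {}).get(p.name, "")
        try:
            image = load_rgb_image(p)
            res = run_pipeline(image, config, image_id=p.stem, marker=marker,
                               out_dir=out_dir)
        except (IOError, ValueError, PipelineStageError) as exc:
            logger.warning("skipping %s: %s", p.name, exc)
            res = SampleResult(image_id=p.stem, marker=marker, ap_percent=np.nan)
        results.append(res)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(results, out_dir / "report.csv")
    if marker_map is not None:
        summary = summarize_markers(results)
        summary.to_csv(out_dir / "marker_summary.csv", index=False, na_rep="NA")
    return pd.DataFrame(
        [{c: getattr(r, c) for c in REPORT_COLUMNS} for r in results],
        columns=REPORT_COLUMNS,
    )
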