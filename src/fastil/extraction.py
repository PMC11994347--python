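"""Stage 1 — tissue masking, patch-grid generation, hematoxylin filtering.

Tissue is whatever is darker than glass: the slide is downsampled, converted
to BT.601 grayscale, and thresholded strictly below 170 (a pixel exactly at
170 is background); debris components below ``min_object_area_px`` are
dropped. Candidate patches form a non-overlapping grid of ``patch_size``
squares anchored at the level-0 origin; a patch is a candidate when at
least ``tissue_fraction_min`` of its footprint is tissue. The hematoxylin
filter then keeps patches whose mean hematoxylin optical density (standard
Ruifrok-Johnston HED deconvolution, decadic log) reaches ``h_threshold``
(0.017 by default) — discarding tissue without meaningful nuclear content.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.color import rgb2hed
from skimage.measure import block_reduce
from skimage.morphology import remove_small_objects

from .config import BT601_WEIGHTS, ExtractionConfig
from .image_io import PatchRecord, SlideHandle, read_region

__all__ = [
    "compute_tissue_mask",
    "mask_to_patch_grid",
    "hematoxylin_mean",
    "h_filter",
    "extract_patches",
]


def _grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma on the 0..255 scale (float64)."""
    r, g, b = BT601_WEIGHTS
    arr = rgb.astype(np.float64)
    return r * arr[..., 0] + g * arr[..., 1] + b * arr[..., 2]


def _downsampled_rgb(slide: SlideHandle, factor: int) -> np.ndarray:
    """Slide RGB at 1/factor scale, using the best stored pyramid level.

    Level-0 block means are used when no suitable level exists; a stored
    level with a smaller downsample is mean-reduced the rest of the way.
    """
    best = 0
    for lv, ds in enumerate(slide.downsample_per_level):
        if ds <= factor and float(ds).is_integer() and factor % int(ds) == 0:
            best = lv
    base = slide.level_array(best).astype(np.float64)
    remaining = factor // int(slide.downsample_per_level[best])
    if remaining > 1:
        base = block_reduce(base, (remaining, remaining, 1), np.mean)
    return base


def compute_tissue_mask(
    slide: SlideHandle, cfg: ExtractionConfig = ExtractionConfig()
) -> tuple[np.ndarray, int]:
    """Binary tissue mask at ``cfg.mask_downsample`` plus its scale factor.

    A mask pixel is tissue iff its grayscale value is strictly below
    ``cfg.gray_threshold``; connected components smaller than
    ``cfg.min_object_area_px`` are removed as debris.
    """
    rgb = _downsampled_rgb(slide, cfg.mask_downsample)
    gray = _grayscale(rgb)
    mask = gray < cfg.gray_threshold
    if cfg.min_object_area_px > 1:
        # drop components with area < min_object_area_px
        mask = remove_small_objects(mask, max_size=cfg.min_object_area_px - 1)
    return mask, cfg.mask_downsample


def mask_to_patch_grid(
    mask: np.ndarray,
    scale_factor: int,
    slide: SlideHandle,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> list[PatchRecord]:
    """Candidate patches from the tissue mask.

    The grid is non-overlapping, anchored at (0, 0), stride = patch size;
    partial edge patches are dropped. A patch qualifies when the tissue
    fraction of its footprint (measured on the mask, area-weighted at patch
    boundaries that split mask pixels) is >= ``cfg.tissue_fraction_min``.
    Output is sorted by (y, x).
    """
    p = cfg.patch_size
    slide_id = slide.path.stem if slide.path is not None else ""
    # cumulative-sum integral image for exact fractional footprints
    m = mask.astype(np.float64)
    integral = np.zeros((m.shape[0] + 1, m.shape[1] + 1))
    integral[1:, 1:] = m.cumsum(0).cumsum(1)

    def footprint_fraction(x0: float, y0: float, x1: float, y1: float) -> float:
        # axis-aligned box sum with bilinear handling of fractional edges
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, m.shape[1]), min(y1, m.shape[0])
        if x1 <= x0 or y1 <= y0:
            return 0.0

        def box(a0, b0, a1, b1):  # integer box sum
            return (
                integral[b1, a1] - integral[b0, a1] - integral[b1, a0] + integral[b0, a0]
            )

        # sample at mask resolution: sum over covered mask pixels weighted by
        # their covered area
        ia0, ib0 = int(np.floor(x0)), int(np.floor(y0))
        ia1, ib1 = int(np.ceil(x1)), int(np.ceil(y1))
        total = 0.0
        for by in range(ib0, ib1):
            wy = min(y1, by + 1) - max(y0, by)
            row = m[by, ia0:ia1]
            wxs = np.minimum(x1, np.arange(ia0, ia1) + 1) - np.maximum(
                x0, np.arange(ia0, ia1)
            )
            total += wy * float(np.dot(row, wxs))
        return total / ((x1 - x0) * (y1 - y0))

    records: list[PatchRecord] = []
    for y in range(0, slide.height0 - p + 1, p):
        for x in range(0, slide.width0 - p + 1, p):
            frac = footprint_fraction(
                x / scale_factor, y / scale_factor, (x + p) / scale_factor, (y + p) / scale_factor
            )
            if frac >= cfg.tissue_fraction_min:
                records.append(PatchRecord(x=x, y=y, patch_size=p, slide_id=slide_id))
    return records


def hematoxylin_mean(patch_rgb: np.ndarray) -> float:
    """Mean hematoxylin optical density of an 8-bit RGB patch.

    Uses the standard Ruifrok-Johnston stain separation into HED space on
    decadic optical densities (skimage's convention); a pure white patch has
    exactly zero optical density in every stain.
    """
    patch = np.asarray(patch_rgb, dtype=np.float64) / 255.0
    hed = rgb2hed(patch)
    return float(hed[..., 0].mean())


def h_filter(
    candidates: Sequence[PatchRecord],
    slide: SlideHandle,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> list[PatchRecord]:
    """Keep patches whose hematoxylin mean is >= ``cfg.h_threshold``.

    Each kept record stores its ``h_mean``; order is preserved and the
    output is a subset of the input.
    """
    kept: list[PatchRecord] = []
    for rec in candidates:
        patch = read_region(slide, rec.x, rec.y, rec.patch_size, rec.patch_size)
        h = hematoxylin_mean(patch)
        if h >= cfg.h_threshold:
            kept.append(rec.with_updates(h_mean=h))
    return kept


def extract_patches(
    slide: SlideHandle, cfg: ExtractionConfig = ExtractionConfig()
) -> tuple[list[PatchRecord], dict]:
    """Full stage 1: mask -> grid -> hematoxylin filter.

    Returns the retained records and a stage-count dict for the run manifest.
    """
    mask, scale = compute_tissue_mask(slide, cfg)
    grid = mask_to_patch_grid(mask, scale, slide, cfg)
    kept = h_filter(grid, slide, cfg)
    n_total = (slide.width0 // cfg.patch_size) * (slide.height0 // cfg.patch_size)
    counts = {
        "grid_total": n_total,
        "tissue_candidates": len(grid),
        "h_filtered": len(kept),
    }
    return kept, counts
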