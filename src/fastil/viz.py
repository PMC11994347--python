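"""Heatmap rendering of per-patch TIL densities over a downsampled slide.

Each retained patch footprint is painted with a colormap value proportional
to its density, clipped at ``clip_max`` (10,000 cells/mm² by default — the
clip absorbs outlier patches) and alpha-blended over the slide thumbnail.
Pixels outside retained patch footprints are left untouched.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .config import HeatmapSpec
from .image_io import PatchRecord, SlideHandle

__all__ = ["render_heatmap", "save_heatmap"]


def _thumbnail(slide: SlideHandle, factor: int) -> np.ndarray:
    from .extraction import _downsampled_rgb

    return np.clip(_downsampled_rgb(slide, factor), 0, 255).astype(np.uint8)


def render_heatmap(
    slide: SlideHandle,
    records: Sequence[PatchRecord],
    spec: HeatmapSpec = HeatmapSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Alpha-blend per-patch density colors over the slide thumbnail.

    Returns ``(overlay_rgb, painted_mask)`` at ``spec.overlay_downsample``
    scale; ``painted_mask`` flags the pixels inside retained patch
    footprints (everything else is the unmodified thumbnail). Records
    without a density are a contract error.
    """
    import matplotlib

    for rec in records:
        if rec.density is None:
            raise ValueError(
                f"record at (x={rec.x}, y={rec.y}) has no density; quantify first"
            )
    ds = spec.overlay_downsample
    overlay = _thumbnail(slide, ds).astype(np.float64)
    painted = np.zeros(overlay.shape[:2], dtype=bool)
    cmap = matplotlib.colormaps[spec.colormap]
    for rec in records:
        v = min(rec.density, spec.clip_max) / spec.clip_max
        color = np.array(cmap(v)[:3]) * 255.0
        r0, c0 = rec.y // ds, rec.x // ds
        r1 = min((rec.y + rec.patch_size) // ds, overlay.shape[0])
        c1 = min((rec.x + rec.patch_size) // ds, overlay.shape[1])
        overlay[r0:r1, c0:c1] = (
            (1 - spec.alpha) * overlay[r0:r1, c0:c1] + spec.alpha * color
        )
        painted[r0:r1, c0:c1] = True
    return np.clip(np.round(overlay), 0, 255).astype(np.uint8), painted


def save_heatmap(
    slide: SlideHandle,
    records: Sequence[PatchRecord],
    path,
    spec: HeatmapSpec = HeatmapSpec(),
) -> Path:
    """Render the overlay with a 0..clip_max colorbar and save as an image."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    overlay, _ = render_heatmap(slide, records, spec)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(overlay)
    ax.set_axis_off()
    sm = ScalarMappable(
        norm=Normalize(0, spec.clip_max), cmap=matplotlib.colormaps[spec.colormap]
    )
    cbar = fig.colorbar(sm, ax=ax, fraction=0.046)
    cbar.set_label("TILs density (cells/mm²)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
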