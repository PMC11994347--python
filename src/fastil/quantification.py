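"""Stage 3 — nucleus detection, TIL counting, and density scoring.

The quantifier is a pluggable contract (``quantify(patch_rgb, *, x0=0, y0=0)
-> list[CellDetection]``). Two implementations ship here: a classical
reference detector (hematoxylin threshold + connected components + size and
circularity gates) and an oracle that reads planted nuclei from synthetic
ground truth. A deep segmentation model can be plugged in through the same
contract without code changes.

Density scoring: the per-patch TIL count c_i is normalized by the physical
patch area,

    d_i = c_i / (patch_size * mpp)^2 * 10^6        [cells/mm^2]

the slide score is the mean of d_i over retained patches, and the patient
score is the mean of slide scores over the patient's k slides (a mean of
means, not a pooled patch mean; for k = 1 the two coincide). An empty
retained-patch set yields *no score* — an unevaluable slide is distinct
from a slide without TILs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from skimage.color import rgb2hed
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .config import DetectorParams
from .image_io import PatchRecord, SlideHandle, read_region
from .survival import EmptyScoreError

__all__ = [
    "CellDetection",
    "Quantifier",
    "ReferenceDetector",
    "OracleQuantifier",
    "SlideResult",
    "reference_detect",
    "patch_density",
    "slide_score",
    "patient_score",
    "quantify_patches",
]


@dataclass(frozen=True)
class CellDetection:
    """One detected nucleus in patch-local pixel coordinates."""

    x: float
    y: float
    cell_kind: str
    area_px: int

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")


class Quantifier(Protocol):
    """Contract for nucleus quantifiers; must be deterministic.

    ``x0``/``y0`` give the patch's level-0 origin for implementations that
    need slide context (the oracle); pixel-based detectors ignore them.
    """

    def quantify(
        self, patch_rgb: np.ndarray, *, x0: int = 0, y0: int = 0
    ) -> list[CellDetection]: ...


def reference_detect(
    patch_rgb: np.ndarray, params: DetectorParams = DetectorParams()
) -> list[CellDetection]:
    """Classical nucleus detection on the hematoxylin channel.

    The H channel is thresholded, 8-connected components are extracted, and
    components with area outside ``[min_area, max_area]`` are discarded. A
    component is a lymphocyte iff its area is at most ``lymph_area_max`` and
    its circularity ``4*pi*A/P^2`` is at least ``circ_min``; otherwise it is
    another cell type.
    """
    hed = rgb2hed(np.asarray(patch_rgb, dtype=np.float64) / 255.0)
    mask = hed[..., 0] > params.h_threshold
    labeled = cc_label(mask, connectivity=2)
    detections: list[CellDetection] = []
    for region in regionprops(labeled):
        area = int(region.area)
        if area < params.min_area or area > params.max_area:
            continue
        perim = region.perimeter
        circularity = 4.0 * math.pi * area / (perim**2) if perim > 0 else 1.0
        kind = (
            "lymphocyte"
            if area <= params.lymph_area_max and circularity >= params.circ_min
            else "other"
        )
        cy, cx = region.centroid
        detections.append(CellDetection(x=float(cx), y=float(cy), cell_kind=kind, area_px=area))
    return detections


class ReferenceDetector:
    """:func:`reference_detect` wrapped as a :class:`Quantifier`."""

    def __init__(self, params: DetectorParams = DetectorParams()):
        self.params = params

    def quantify(self, patch_rgb, *, x0: int = 0, y0: int = 0):
        return reference_detect(patch_rgb, self.params)


class OracleQuantifier:
    """Reads planted nuclei from synthetic ground truth.

    A nucleus belongs to the patch containing its center (half-open patch
    squares partition the grid, so counts are partition-exact).
    """

    def __init__(self, ground_truth, nominal_area_px: int = 28):
        self.gt = ground_truth
        self.nominal_area_px = nominal_area_px

    def quantify(self, patch_rgb, *, x0: int = 0, y0: int = 0):
        size = patch_rgb.shape[0]
        out = []
        for n in self.gt.nuclei:
            if x0 <= n.x < x0 + size and y0 <= n.y < y0 + size:
                out.append(
                    CellDetection(
                        x=n.x - x0, y=n.y - y0, cell_kind=n.cell_kind,
                        area_px=self.nominal_area_px,
                    )
                )
        return out


def patch_density(til_count: int, patch_size: int, mpp: float) -> float:
    """TIL density of one patch in cells/mm²: c / (patch_size*mpp)² * 10⁶."""
    if til_count < 0:
        raise ValueError("til_count must be non-negative")
    if patch_size <= 0 or mpp <= 0:
        raise ValueError("patch_size and mpp must be positive")
    return til_count / (patch_size * mpp) ** 2 * 1e6


def slide_score(densities: Sequence[float]) -> float:
    """Slide-level TILs score: mean per-patch density over retained patches."""
    if len(densities) == 0:
        raise EmptyScoreError("slide has no retained patches; no score defined")
    return float(np.mean(np.asarray(densities, dtype=float)))


def patient_score(per_slide_densities: Sequence[Sequence[float]]) -> float:
    """Patient-level TILs score: mean of slide means over the k slides.

    Each slide contributes equally regardless of its patch count; for a
    single slide this reduces to :func:`slide_score`.
    """
    if len(per_slide_densities) == 0:
        raise EmptyScoreError("patient has no slides; no score defined")
    means = []
    for j, dens in enumerate(per_slide_densities):
        if len(dens) == 0:
            raise EmptyScoreError(f"slide {j} has no retained patches; no score defined")
        means.append(slide_score(dens))
    return float(np.mean(means))


@dataclass(frozen=True)
class SlideResult:
    """Per-slide pipeline output.

    ``til_score`` is ``None`` for an unevaluable slide (no retained
    tumor/stroma patches) — deliberately distinct from a score of 0.
    """

    slide_id: str
    n_patches: int
    til_score: Optional[float]
    config_digest: str = ""

    @property
    def evaluable(self) -> bool:
        return self.til_score is not None


def quantify_patches(
    records: Sequence[PatchRecord],
    slide: SlideHandle,
    quantifier: Quantifier,
    config_digest: str = "",
) -> tuple[list[PatchRecord], SlideResult]:
    """Fill ``til_count`` and ``density`` per record and aggregate the slide.

    c_i is the number of lymphocyte detections in patch i; d_i follows the
    area normalization with the slide's mpp. A quantifier failure is
    re-raised naming the patch.
    """
    out: list[PatchRecord] = []
    for rec in records:
        patch = read_region(slide, rec.x, rec.y, rec.patch_size, rec.patch_size)
        try:
            detections = quantifier.quantify(patch, x0=rec.x, y0=rec.y)
        except Exception as exc:
            raise RuntimeError(
                f"quantifier failed on patch (x={rec.x}, y={rec.y}): {exc}"
            ) from exc
        c = sum(1 for d in detections if d.cell_kind == "lymphocyte")
        out.append(
            rec.with_updates(
                til_count=c, density=patch_density(c, rec.patch_size, slide.mpp)
            )
        )
    slide_id = out[0].slide_id if out else (slide.path.stem if slide.path else "")
    score = slide_score([r.density for r in out]) if out else None
    return out, SlideResult(
        slide_id=slide_id,
        n_patches=len(out),
        til_score=score,
        config_digest=config_digest,
    )
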