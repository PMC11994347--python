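"""Pipeline configuration objects and pinned numeric constants.

Every tunable default named here is part of the pipeline contract: the
tissue-mask gray threshold (170), the hematoxylin-mean threshold (0.017 in
decadic optical density after Ruifrok–Johnston deconvolution), the 768 px
patch size, and the 10,000 cells/mm² heatmap clip. Grayscale conversion is
pinned to ITU-R BT.601 luma so masks are bit-reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

#: ITU-R BT.601 luma weights used for every RGB -> grayscale conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Tissue classes assigned by stage 2, in fixed tie-break priority order.
TISSUE_CLASSES = ("tumor", "stroma", "necrosis", "normal")

#: Classes retained for TIL scoring (tumor tissue and stroma carry the
#: prognostically relevant lymphocyte infiltrate).
PROGNOSTIC_CLASSES = frozenset({"tumor", "stroma"})

#: Cell kinds distinguished by quantifiers.
CELL_KINDS = ("lymphocyte", "other")


# ---------------------------------------------------------------------------
# Synthetic H&E palette.
#
# Colors are chosen so the standard HED stain separation responds the way the
# pipeline assumes real H&E does: eosin-pink tissue fill has hematoxylin OD
# exactly 0 (a pure-eosin patch fails the 0.017 H-filter), nucleus violets
# have H >= 0.10 (nucleus-bearing patches pass), and the dusky necrosis fill
# sits just above threshold so sparse-nucleus necrotic tissue survives stage 1
# and is only discarded by the classifier. All tissue fills have BT.601 luma
# below the 170 mask threshold; the glass background (245) is above it.
# ---------------------------------------------------------------------------
BACKGROUND_GRAY = 245
EOSIN_TISSUE_RGB = (228, 120, 150)   # luma 155.7, H = 0.000
NECROSIS_FILL_RGB = (170, 145, 125)  # luma 150.2, H = 0.021
LYMPHOCYTE_RGB = (60, 30, 100)       # luma  47.0, H = 0.146
OTHER_NUCLEUS_RGB = (90, 60, 130)    # luma  77.0, H = 0.105


@dataclass(frozen=True)
class ExtractionConfig:
    """Stage-1 parameters: tissue masking, patch grid, hematoxylin filter.

    Attributes
    ----------
    gray_threshold:
        8-bit luma threshold; pixels strictly below it are tissue, pixels at
        or above it (glass, exactly 170 included) are background.
    min_object_area_px:
        Connected tissue components smaller than this (at mask scale) are
        discarded as debris.
    mask_downsample:
        Downsample factor of the working mask relative to level 0.
    patch_size:
        Side of the square level-0 patch in pixels.
    h_threshold:
        Minimum mean hematoxylin optical density for a patch to be kept;
        comparison is ``>=`` so a patch exactly at threshold is retained.
    tissue_fraction_min:
        Minimum tissue coverage of a patch footprint for grid candidacy.
    """

    gray_threshold: int = 170
    min_object_area_px: int = 64
    mask_downsample: int = 32
    patch_size: int = 768
    h_threshold: float = 0.017
    tissue_fraction_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.gray_threshold < 255:
            raise ValueError("gray_threshold must be in (0, 255)")
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.mask_downsample < 1:
            raise ValueError("mask_downsample must be >= 1")
        if not 0 < self.tissue_fraction_min <= 1:
            raise ValueError("tissue_fraction_min must be in (0, 1]")


@dataclass(frozen=True)
class DetectorParams:
    """Classical nucleus-detector parameters (pixel units at slide mpp).

    Defaults are quoted for 0.25 um/pixel material; when the slide is scanned
    at a different resolution, area parameters should be rescaled by
    ``(0.25 / mpp) ** 2``. These are stand-in values for a pluggable deep
    quantifier, not biological claims.
    """

    h_threshold: float = 0.06
    min_area: int = 20
    max_area: int = 600
    lymph_area_max: int = 250
    circ_min: float = 0.7

    def scaled(self, mpp: float, reference_mpp: float = 0.25) -> "DetectorParams":
        """Return a copy with area parameters rescaled to another mpp."""
        s = (reference_mpp / mpp) ** 2
        return dataclasses.replace(
            self,
            min_area=max(1, int(round(self.min_area * s))),
            max_area=max(1, int(round(self.max_area * s))),
            lymph_area_max=max(1, int(round(self.lymph_area_max * s))),
        )


@dataclass(frozen=True)
class HeuristicClassifierParams:
    """Feature thresholds for the rule-based reference classifier.

    Calibrated once against the synthetic generator's default class palette
    (blob densities per mm² of hematoxylin-positive components; small-blob
    fraction separates lymphocyte-rich stroma from normal tissue).
    """

    h_blob_threshold: float = 0.06
    min_blob_area: int = 6
    necrosis_blob_density_max: float = 600.0
    tumor_h_mean_min: float = 0.027
    stroma_small_blob_fraction_min: float = 0.13
    small_blob_area_max: int = 50


@dataclass(frozen=True)
class SamplingConfig:
    """Randomized patch subsampling: keep ``max(1, round(ratio * N))``."""

    ratio: float = 1.0
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")


@dataclass(frozen=True)
class HeatmapSpec:
    """Heatmap rendering options; densities are clipped at ``clip_max``."""

    clip_max: float = 10_000.0
    colormap: str = "turbo"
    overlay_downsample: int = 32
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.clip_max <= 0:
            raise ValueError("clip_max must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def config_digest(*configs) -> str:
    """Stable SHA-256 digest of one or more config dataclasses."""
    payload = [
        {type(c).__name__: dataclasses.asdict(c)} if dataclasses.is_dataclass(c) else c
        for c in configs
    ]
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
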