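"""Synthetic H&E-like slide and cohort generation with full ground truth.

The generator emulates the image content the pipeline consumes: a bright
glass background, eosin-pink tissue regions of four classes (tumor, stroma,
necrosis, normal lung), and hematoxylin-dark nucleus disks of two kinds
(small round lymphocytes, larger other cells) planted uniformly at known
densities. Every slide comes with a :class:`GroundTruth` carrying the
region map, tissue mask, and the exact list of planted nuclei, so tissue
masking, classification, quantification, and density scoring can each be
validated against truth.

Planted counts are deterministic — ``round(density x area_mm2)`` per region
and cell kind — so density-recovery tests carry no planting noise; a Poisson
option exists for stochastic counts. Matched survival cohorts draw
exponential event times whose log-hazard decreases linearly with the true
mean lymphocyte density (TILs protective), with independent uniform
censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon
from scipy.ndimage import gaussian_filter

from .config import (
    BACKGROUND_GRAY,
    EOSIN_TISSUE_RGB,
    LYMPHOCYTE_RGB,
    NECROSIS_FILL_RGB,
    OTHER_NUCLEUS_RGB,
    TISSUE_CLASSES,
)
from .image_io import SlideHandle, write_slide_tiff
from .survival import SurvivalRecord

__all__ = [
    "Region",
    "SlideSpec",
    "Nucleus",
    "GroundTruth",
    "SurvivalLinkParams",
    "DEFAULT_DENSITIES",
    "DEFAULT_NUCLEUS_RADIUS",
    "generate_slide",
    "generate_slide_to_file",
    "generate_cohort",
    "cohort_to_frame",
]

#: Default (lymphocyte, other-cell) densities per mm² for each region class.
#: Tumor and stroma carry the infiltrate; necrosis is nearly acellular
#: (< 5% of tumor nuclear density) so classifiers have a usable signal.
DEFAULT_DENSITIES: dict[str, tuple[float, float]] = {
    "tumor": (1500.0, 4000.0),
    "stroma": (800.0, 2500.0),
    "normal": (100.0, 2800.0),
    "necrosis": (20.0, 150.0),
}

#: Default nucleus radii in pixels (fixtures are rendered at 1 um/pixel, so
#: these approximate real nuclear sizes: lymphocytes ~6-7 um across, other
#: nuclei ~10 um).
DEFAULT_NUCLEUS_RADIUS: dict[str, int] = {"lymphocyte": 3, "other": 5}

_CLASS_CODE = {c: i + 1 for i, c in enumerate(TISSUE_CLASSES)}  # 0 = background
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}

_FILL_RGB = {
    "tumor": EOSIN_TISSUE_RGB,
    "stroma": EOSIN_TISSUE_RGB,
    "normal": EOSIN_TISSUE_RGB,
    "necrosis": NECROSIS_FILL_RGB,
}
_KIND_RGB = {"lymphocyte": LYMPHOCYTE_RGB, "other": OTHER_NUCLEUS_RGB}


@dataclass(frozen=True)
class Region:
    """A tissue region: an axis-aligned ``rect=(x, y, w, h)`` or a polygon."""

    region_class: str
    rect: Optional[tuple[int, int, int, int]] = None
    polygon: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.region_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("exactly one of rect or polygon must be given")


@dataclass(frozen=True)
class SlideSpec:
    """Full description of one synthetic slide."""

    width: int = 2304
    height: int = 2304
    mpp: float = 1.0
    background_gray: int = BACKGROUND_GRAY
    regions: tuple[Region, ...] = ()
    nuclei_density_per_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    nucleus_radius_px: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NUCLEUS_RADIUS)
    )
    gt_downsample: int = 32
    poisson_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.mpp <= 0:
            raise ValueError("width, height and mpp must be positive")
        for cls, (dl, do) in self.nuclei_density_per_class.items():
            if dl < 0 or do < 0:
                raise ValueError(f"negative density for class {cls!r}")


@dataclass(frozen=True)
class Nucleus:
    x: float
    y: float
    cell_kind: str
    region_class: str


@dataclass
class GroundTruth:
    """Everything the generator knows about a slide.

    Masks are stored at ``downsample`` (majority rule per block); nuclei are
    level-0 coordinates. ``planted_counts`` maps region index -> cell kind ->
    count actually planted.
    """

    downsample: int
    tissue_mask: np.ndarray
    region_map: np.ndarray
    nuclei: list[Nucleus]
    regions: tuple[Region, ...]
    planted_densities: list[dict[str, float]]
    planted_counts: list[dict[str, int]]
    region_area_mm2: list[float]
    mpp: float

    def region_class_at_block(self, row: int, col: int) -> Optional[str]:
        code = int(self.region_map[row, col])
        return _CODE_CLASS.get(code)

    def lymphocytes_in(self, x: int, y: int, size: int) -> list[Nucleus]:
        """Planted lymphocytes whose center falls in [x, x+size) x [y, y+size)."""
        return [
            n
            for n in self.nuclei
            if n.cell_kind == "lymphocyte"
            and x <= n.x < x + size
            and y <= n.y < y + size
        ]


def _rasterize(region: Region, width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the region's pixels; raises if out of bounds."""
    if region.rect is not None:
        x, y, w, h = region.rect
        if x < 0 or y < 0 or x + w > width or y + h > height or w <= 0 or h <= 0:
            raise ValueError(f"region rect {region.rect} outside slide bounds")
        rr, cc = np.mgrid[y : y + h, x : x + w]
        return rr.ravel(), cc.ravel()
    verts = np.asarray(region.polygon, dtype=float)
    if (
        verts[:, 0].min() < 0
        or verts[:, 1].min() < 0
        or verts[:, 0].max() > width
        or verts[:, 1].max() > height
    ):
        raise ValueError("region polygon outside slide bounds")
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(height, width))
    return rr, cc


def _block_reduce_labels(full: np.ndarray, ds: int) -> tuple[np.ndarray, np.ndarray]:
    """Majority-rule downsampling of a class-code map.

    Returns (tissue_mask, region_map) at scale ``ds``: a block is tissue iff
    at least half its level-0 pixels belong to any region; its class is the
    most frequent region class in the block (ties by class priority order).
    """
    h, w = full.shape
    hb, wb = -(-h // ds), -(-w // ds)
    padded = np.zeros((hb * ds, wb * ds), dtype=full.dtype)
    padded[:h, :w] = full
    blocks = padded.reshape(hb, ds, wb, ds)
    counts = np.stack(
        [(blocks == code).sum(axis=(1, 3)) for code in range(len(TISSUE_CLASSES) + 1)]
    )  # shape (n_codes, hb, wb); index 0 = background
    tissue_count = counts[1:].sum(axis=0)
    tissue_mask = tissue_count >= (ds * ds) / 2
    # argmax over classes 1..4; np.argmax ties -> lowest index = highest
    # priority class (tumor > stroma > necrosis > normal)
    region_map = np.where(tissue_mask, counts[1:].argmax(axis=0) + 1, 0).astype(np.uint8)
    return tissue_mask, region_map


def _sample_in_region(
    rng: np.random.Generator, rr: np.ndarray, cc: np.ndarray, count: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points over the region's pixel set (center-of-pixel jittered)."""
    if count == 0:
        return np.empty(0), np.empty(0)
    idx = rng.integers(0, len(rr), size=count)
    jitter = rng.random((count, 2))  # uniform within the chosen pixel
    ys = rr[idx] + jitter[:, 0]
    xs = cc[idx] + jitter[:, 1]
    return xs, ys


def _paint_disks(
    image: np.ndarray,
    region_id: np.ndarray,
    rid: int,
    xs: np.ndarray,
    ys: np.ndarray,
    radius: float,
    color: np.ndarray,
) -> None:
    """Rasterize many equal-radius disks at once, clipped to their region.

    A pixel belongs to a disk iff its center distance to the (float) nucleus
    center is at most the radius; disks never paint outside the region.
    """
    if len(xs) == 0:
        return
    H, W = region_id.shape
    r_int = int(np.ceil(radius)) + 1
    d = np.arange(-r_int, r_int + 1)
    dy, dx = np.meshgrid(d, d, indexing="ij")
    dy, dx = dy.ravel(), dx.ravel()
    ay = np.floor(ys).astype(np.int64)
    ax = np.floor(xs).astype(np.int64)
    rows = ay[:, None] + dy[None, :]
    cols = ax[:, None] + dx[None, :]
    inside = (
        (rows - ys[:, None]) ** 2 + (cols - xs[:, None]) ** 2 <= radius**2
    )
    inside &= (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    rows, cols = rows[inside], cols[inside]
    keep = region_id[rows, cols] == rid
    image[rows[keep], cols[keep]] = color


def generate_slide(spec: SlideSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic slide and its ground truth.

    Identical spec (including seed) yields a byte-identical image. Nucleus
    counts per region and kind are ``round(density x area_mm2)`` (or Poisson
    when ``spec.poisson_counts``); positions are uniform over the region's
    pixels; disks are clipped at region boundaries so background stays clean.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    image = np.full((H, W, 3), spec.background_gray, dtype=np.uint8)
    region_id = np.full((H, W), -1, dtype=np.int16)
    class_code = np.zeros((H, W), dtype=np.uint8)

    px_area_mm2 = (spec.mpp / 1000.0) ** 2
    nuclei: list[Nucleus] = []
    planted_counts: list[dict[str, int]] = []
    planted_densities: list[dict[str, float]] = []
    region_area: list[float] = []

    rasters = []
    for i, region in enumerate(spec.regions):
        rr, cc = _rasterize(region, W, H)
        if np.any(region_id[rr, cc] != -1):
            raise ValueError(f"region {i} overlaps an earlier region")
        region_id[rr, cc] = i
        class_code[rr, cc] = _CLASS_CODE[region.region_class]
        rasters.append((rr, cc))

    # Fill tissue, then texture necrosis, then plant nuclei on top.
    for i, region in enumerate(spec.regions):
        rr, cc = rasters[i]
        image[rr, cc] = _FILL_RGB[region.region_class]
        if region.region_class == "necrosis":
            # low-contrast smeared texture: smooth zero-mean field added
            # equally to all channels, small enough to keep luma < 170
            noise = gaussian_filter(rng.standard_normal((H, W)), sigma=4)
            noise = np.clip(noise * 12.0, -10, 10)
            vals = image[rr, cc].astype(np.int16) + noise[rr, cc, None].astype(np.int16)
            image[rr, cc] = np.clip(vals, 120, 168).astype(np.uint8)

    for i, region in enumerate(spec.regions):
        rr, cc = rasters[i]
        area_mm2 = len(rr) * px_area_mm2
        region_area.append(area_mm2)
        lymph_d, other_d = spec.nuclei_density_per_class.get(
            region.region_class, (0.0, 0.0)
        )
        planted_densities.append({"lymphocyte": lymph_d, "other": other_d})
        counts = {}
        for kind, dens in (("other", other_d), ("lymphocyte", lymph_d)):
            if spec.poisson_counts:
                n = int(rng.poisson(dens * area_mm2))
            else:
                n = int(round(dens * area_mm2))
            counts[kind] = n
            xs, ys = _sample_in_region(rng, rr, cc, n)
            radius = spec.nucleus_radius_px.get(kind, DEFAULT_NUCLEUS_RADIUS[kind])
            color = np.array(_KIND_RGB[kind], dtype=np.uint8)
            _paint_disks(image, region_id, i, xs, ys, radius, color)
            nuclei.extend(
                Nucleus(float(x), float(y), kind, region.region_class)
                for x, y in zip(xs, ys)
            )
        planted_counts.append(counts)

    tissue_mask, region_map = _block_reduce_labels(class_code, spec.gt_downsample)
    gt = GroundTruth(
        downsample=spec.gt_downsample,
        tissue_mask=tissue_mask,
        region_map=region_map,
        nuclei=nuclei,
        regions=spec.regions,
        planted_densities=planted_densities,
        planted_counts=planted_counts,
        region_area_mm2=region_area,
        mpp=spec.mpp,
    )
    return image, gt


def generate_slide_to_file(
    spec: SlideSpec, path, with_pyramid: bool = False
) -> tuple[Path, GroundTruth]:
    """Render a slide and write it as a TIFF carrying the mpp tag."""
    image, gt = generate_slide(spec)
    levels = []
    if with_pyramid:
        # 2x mean-downsampled level; enough to exercise pyramid reading
        h2, w2 = image.shape[0] // 2 * 2, image.shape[1] // 2 * 2
        lv = (
            image[:h2, :w2]
            .reshape(h2 // 2, 2, w2 // 2, 2, 3)
            .mean(axis=(1, 3))
            .astype(np.uint8)
        )
        levels = [lv]
    out = write_slide_tiff(image, path, spec.mpp, pyramid_levels=levels)
    return out, gt


def slide_handle_from_spec(spec: SlideSpec) -> tuple[SlideHandle, GroundTruth]:
    """Render in memory and wrap as a :class:`SlideHandle` (no disk I/O)."""
    image, gt = generate_slide(spec)
    return SlideHandle.from_array(image, spec.mpp), gt


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalLinkParams:
    """Exponential survival model linked to true lymphocyte density.

    hazard_i = baseline_hazard * exp(log_hr_per_1000 * (d_i - reference) / 1000)

    A negative ``log_hr_per_1000`` makes TIL density protective. Censoring
    times are uniform on (0, censor_time_max]; ``censor_time_max=None``
    disables censoring. Times are in years.
    """

    log_hr_per_1000: float = -0.5
    baseline_hazard: float = 0.12
    reference_density: float = 1500.0
    censor_time_max: Optional[float] = 12.0


def _cohort_slide_spec(
    density: float, seed: int, patch_size: int = 768, mpp: float = 1.0
) -> SlideSpec:
    """Standard cohort slide: 3p x 3p with a 2p x 2p tumor block and a
    p x 2p stroma column, both grid-aligned; stroma infiltrate tracks the
    tumor infiltrate at 60%."""
    p = patch_size
    dens = dict(DEFAULT_DENSITIES)
    dens["tumor"] = (density, dens["tumor"][1])
    dens["stroma"] = (0.6 * density, dens["stroma"][1])
    return SlideSpec(
        width=3 * p,
        height=3 * p,
        mpp=mpp,
        regions=(
            Region("tumor", rect=(0, 0, 2 * p, 2 * p)),
            Region("stroma", rect=(2 * p, 0, p, 2 * p)),
        ),
        nuclei_density_per_class=dens,
        seed=seed,
    )


def generate_cohort(
    n_patients: int,
    density_grid: tuple[float, float] = (200.0, 3000.0),
    survival_link_params: Optional[SurvivalLinkParams] = None,
    seed: int = 0,
    patch_size: int = 768,
    mpp: float = 1.0,
) -> tuple[list[SlideSpec], list[SurvivalRecord]]:
    """Simulate a cohort of slides with matched censored survival outcomes.

    Per-patient true mean lymphocyte densities are uniform over
    ``density_grid``; each patient gets one standard cohort slide (seeded
    reproducibly from ``seed``) and one :class:`SurvivalRecord` whose
    ``score`` and ``true_density`` both carry the planted tumor density, so
    the record set can be used directly to measure the prognostic ceiling.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    link = survival_link_params or SurvivalLinkParams()
    rng = np.random.default_rng(seed)
    lo, hi = density_grid
    densities = rng.uniform(lo, hi, size=n_patients)

    specs: list[SlideSpec] = []
    records: list[SurvivalRecord] = []
    for i, d in enumerate(densities):
        slide_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(_cohort_slide_spec(float(d), slide_seed, patch_size, mpp))
        hazard = link.baseline_hazard * np.exp(
            link.log_hr_per_1000 * (d - link.reference_density) / 1000.0
        )
        t_event = rng.exponential(1.0 / hazard)
        if link.censor_time_max is None:
            time, event = t_event, 1
        else:
            t_cens = rng.uniform(0.0, link.censor_time_max)
            time, event = min(t_event, t_cens), int(t_event <= t_cens)
        records.append(
            SurvivalRecord(
                patient_id=f"P{i:04d}",
                time=float(max(time, 1e-9)),
                event=event,
                score=float(d),
                true_density=float(d),
            )
        )
    return specs, records


def cohort_to_frame(records: Sequence[SurvivalRecord]):
    """Cohort as a pandas DataFrame (patient_id, time, event, true_density)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "true_density": [r.true_density for r in records],
        }
    )


def evaluate_cohort_pipeline(
    specs: Sequence[SlideSpec],
    survival: Sequence[SurvivalRecord],
    ratios: Sequence[float] = (1.0,),
    base_seed: int = 0,
) -> dict[float, list[SurvivalRecord]]:
    """Run the oracle-model pipeline over a synthetic cohort.

    Each patient's slide is rendered, stage 1 runs once, and for every
    sampling ratio the downstream stages (sample -> oracle classify ->
    filter -> oracle quantify -> score) produce a pipeline TILs score.
    Returns, per ratio, the survival records with ``score`` replaced by the
    measured pipeline score (patients whose slide is unevaluable at that
    ratio are dropped). Deterministic given ``base_seed``.
    """
    from .classification import OracleClassifier, classify_patches, filter_prognostic
    from .extraction import extract_patches
    from .quantification import OracleQuantifier, quantify_patches
    from .sampling import sample_patches

    out: dict[float, list[SurvivalRecord]] = {float(r): [] for r in ratios}
    for k, (spec, rec) in enumerate(zip(specs, survival)):
        handle, gt = slide_handle_from_spec(spec)
        records, _ = extract_patches(handle)
        classifier = OracleClassifier(gt)
        quantifier = OracleQuantifier(gt)
        for ratio in ratios:
            seed = int(
                np.random.default_rng([base_seed, k, int(ratio * 10**6)]).integers(
                    0, 2**31 - 1
                )
            )
            sampled = sample_patches(records, ratio, seed) if records else []
            labeled = classify_patches(sampled, handle, classifier)
            kept = filter_prognostic(labeled)
            _, result = quantify_patches(kept, handle, quantifier)
            if result.evaluable:
                out[float(ratio)].append(rec.with_score(result.til_score))
    return out


# ---------------------------------------------------------------------------
# Ground-truth serialization (JSON for nuclei/regions, PNG for masks)
# ---------------------------------------------------------------------------


def write_ground_truth(gt: GroundTruth, outdir) -> Path:
    from PIL import Image as PILImage

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    PILImage.fromarray((gt.tissue_mask * 255).astype(np.uint8)).save(
        outdir / "tissue_mask.png"
    )
    PILImage.fromarray(gt.region_map).save(outdir / "region_map.png")
    meta = {
        "downsample": gt.downsample,
        "mpp": gt.mpp,
        "region_area_mm2": gt.region_area_mm2,
        "planted_densities": gt.planted_densities,
        "planted_counts": gt.planted_counts,
        "nuclei": [
            {"x": n.x, "y": n.y, "cell_kind": n.cell_kind, "region_class": n.region_class}
            for n in gt.nuclei
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(meta))
    return outdir
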