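"""Slide access and tabular I/O.

Slides are exposed through :class:`SlideHandle`, a uniform view over
pyramidal TIFFs (read via tifffile SubIFD series), flat TIFFs, and flat
PNG/JPEG images (read via Pillow). Flat images are treated as one-level
pyramids. The physical resolution (microns per pixel, mpp) is taken from
TIFF resolution tags when present; otherwise opening fails unless the caller
supplies ``mpp_override``.

Patch tables are TSV files with the fixed header
``slide_id  x  y  patch_size  h_mean  label  til_count  density``; absent
optional fields serialize as empty strings and round-trip losslessly
(integers bit-exact, reals at 17 significant digits).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

__all__ = [
    "SlideHandle",
    "PatchRecord",
    "MissingMppError",
    "SlideOpenError",
    "BoundsError",
    "PatchTableParseError",
    "open_slide",
    "read_region",
    "write_slide_tiff",
    "write_patch_table",
    "read_patch_table",
]


class SlideOpenError(IOError):
    """The file could not be read as a slide image."""


class MissingMppError(ValueError):
    """No microns-per-pixel metadata found and no override supplied."""


class BoundsError(ValueError):
    """A requested region falls outside the slide level's extent."""


class PatchTableParseError(ValueError):
    """A patch table file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


@dataclass(frozen=True)
class SlideHandle:
    """An open slide: per-level pixel data, downsample factors, and mpp.

    ``mpp`` refers to level 0 and is assumed isotropic. ``downsample_per_level``
    is strictly increasing with level and equals 1.0 at level 0.
    """

    path: Optional[Path]
    width0: int
    height0: int
    downsample_per_level: tuple[float, ...]
    mpp: float
    _levels: tuple[np.ndarray, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.width0 <= 0 or self.height0 <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        ds = self.downsample_per_level
        if ds[0] != 1.0 or any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError("downsample factors must start at 1.0 and increase")

    @property
    def levels(self) -> int:
        return len(self._levels)

    def level_shape(self, level: int) -> tuple[int, int]:
        """(height, width) of the stored image at ``level``."""
        arr = self._levels[level]
        return arr.shape[0], arr.shape[1]

    def level_array(self, level: int = 0) -> np.ndarray:
        """The full RGB array at ``level`` (read-only view)."""
        return self._levels[level]

    @classmethod
    def from_array(
        cls,
        image: np.ndarray,
        mpp: float,
        path: Optional[Path] = None,
        extra_levels: Sequence[np.ndarray] = (),
    ) -> "SlideHandle":
        """Wrap an in-memory RGB array (plus optional pyramid levels)."""
        image = _as_rgb_uint8(image)
        levels = [image] + [_as_rgb_uint8(lv) for lv in extra_levels]
        ds = tuple(image.shape[1] / lv.shape[1] for lv in levels)
        for lv in levels:
            lv.setflags(write=False)
        return cls(
            path=path,
            width0=image.shape[1],
            height0=image.shape[0],
            downsample_per_level=ds,
            mpp=float(mpp),
            _levels=tuple(levels),
        )


def _as_rgb_uint8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise SlideOpenError("expected an RGB image")
    return np.ascontiguousarray(image[..., :3], dtype=np.uint8)


def _mpp_from_tiff_page(page) -> Optional[float]:
    """Microns per pixel from TIFF XResolution/ResolutionUnit tags."""
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimeter
        return 1e4 / pixels_per_unit
    if unit == 2:  # inch
        return 25400.0 / pixels_per_unit
    return None


def open_slide(path: os.PathLike | str, mpp_override: Optional[float] = None) -> SlideHandle:
    """Open a pyramidal TIFF or flat RGB image as a :class:`SlideHandle`.

    ``mpp_override`` takes precedence over file metadata; if the file carries
    no resolution metadata and no override is given, a
    :class:`MissingMppError` names the missing field.
    """
    path = Path(path)
    if not path.is_file():
        raise SlideOpenError(f"slide file not found: {path}")
    if mpp_override is not None and mpp_override <= 0:
        raise ValueError("mpp_override must be positive")

    levels: list[np.ndarray] = []
    mpp: Optional[float] = None
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            for lv in series.levels:
                levels.append(_as_rgb_uint8(lv.asarray()))
            mpp = _mpp_from_tiff_page(series.pages[0])
    except tifffile.TiffFileError:
        try:
            with Image.open(path) as im:
                dpi = im.info.get("dpi")
                levels.append(_as_rgb_uint8(np.asarray(im.convert("RGB"))))
            if dpi and dpi[0]:
                mpp = 25400.0 / float(dpi[0])
        except UnidentifiedImageError as exc:
            raise SlideOpenError(f"not a readable slide image: {path}") from exc
    except (OSError, ValueError) as exc:
        raise SlideOpenError(f"failed to read slide {path}: {exc}") from exc

    if mpp_override is not None:
        mpp = mpp_override
    if mpp is None:
        raise MissingMppError(
            f"{path}: no microns-per-pixel (mpp) metadata in file; "
            "pass mpp_override to supply it"
        )
    return SlideHandle.from_array(levels[0], mpp, path=path, extra_levels=levels[1:])


def read_region(
    handle: SlideHandle, x: int, y: int, w: int, h: int, level: int = 0
) -> np.ndarray:
    """Read a ``h x w`` RGB region at ``level``.

    ``x``/``y`` are given in the level-0 frame and mapped to the level by its
    downsample factor; ``w``/``h`` are pixels at the requested level.
    """
    if not 0 <= level < handle.levels:
        raise BoundsError(f"level {level} out of range (slide has {handle.levels})")
    if w <= 0 or h <= 0:
        raise BoundsError("region width and height must be positive")
    ds = handle.downsample_per_level[level]
    xl = int(round(x / ds))
    yl = int(round(y / ds))
    lh, lw = handle.level_shape(level)
    if xl < 0 or yl < 0 or xl + w > lw or yl + h > lh:
        raise BoundsError(
            f"region (x={x}, y={y}, w={w}, h={h}) at level {level} exceeds "
            f"level extent {lw}x{lh}"
        )
    return handle.level_array(level)[yl : yl + h, xl : xl + w]


def write_slide_tiff(
    image: np.ndarray,
    path: os.PathLike | str,
    mpp: float,
    pyramid_levels: Sequence[np.ndarray] = (),
) -> Path:
    """Write an RGB array as a (optionally pyramidal) TIFF with mpp tags.

    The mpp is stored as pixels-per-centimeter resolution tags, which
    :func:`open_slide` reads back. Extra ``pyramid_levels`` are written as
    SubIFDs of the base image.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    path = Path(path)
    image = _as_rgb_uint8(image)
    res = 1e4 / mpp  # pixels per centimeter
    with tifffile.TiffWriter(path) as tw:
        tw.write(
            image,
            photometric="rgb",
            resolution=(res, res),
            resolutionunit="CENTIMETER",
            subifds=len(pyramid_levels),
        )
        for lv in pyramid_levels:
            lv = _as_rgb_uint8(lv)
            ds = image.shape[1] / lv.shape[1]
            tw.write(
                lv,
                photometric="rgb",
                resolution=(res / ds, res / ds),
                resolutionunit="CENTIMETER",
                subfiletype=1,
            )
    return path


# ---------------------------------------------------------------------------
# Patch records and their TSV table.
# ---------------------------------------------------------------------------

#: Fixed column order of the patch table.
PATCH_TABLE_COLUMNS = (
    "slide_id",
    "x",
    "y",
    "patch_size",
    "h_mean",
    "label",
    "til_count",
    "density",
)

VALID_LABELS = frozenset({"tumor", "stroma", "necrosis", "normal"})


@dataclass(frozen=True)
class PatchRecord:
    """One candidate patch: level-0 coordinates plus accumulated annotations.

    The patch covers the half-open square ``[x, x+patch_size) x
    [y, y+patch_size)`` in level-0 pixels. Annotations (``h_mean``, ``label``,
    ``til_count``, ``density``) are filled in by successive pipeline stages
    and are ``None`` until then. ``scores`` holds per-class classifier
    probabilities; it is carried in memory only, not serialized.
    """

    x: int
    y: int
    patch_size: int
    slide_id: str = ""
    h_mean: Optional[float] = None
    label: Optional[str] = None
    til_count: Optional[int] = None
    density: Optional[float] = None
    scores: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("patch coordinates must be non-negative")
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.til_count is not None and self.til_count < 0:
            raise ValueError("til_count must be non-negative")
        if self.density is not None and self.til_count is None:
            raise ValueError("density requires til_count to be present")

    def with_updates(self, **kwargs) -> "PatchRecord":
        return replace(self, **kwargs)


def _fmt_float(v: Optional[float]) -> str:
    return "" if v is None else format(float(v), ".17g")


def write_patch_table(records: Sequence[PatchRecord], path: os.PathLike | str) -> Path:
    """Write records as TSV; empty cells encode absent optional fields."""
    path = Path(path)
    lines = ["\t".join(PATCH_TABLE_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.slide_id,
                    str(r.x),
                    str(r.y),
                    str(r.patch_size),
                    _fmt_float(r.h_mean),
                    r.label or "",
                    "" if r.til_count is None else str(r.til_count),
                    _fmt_float(r.density),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_patch_table(path: os.PathLike | str) -> list[PatchRecord]:
    """Read a patch table written by :func:`write_patch_table`.

    Raises :class:`PatchTableParseError` with a 1-based line number on any
    malformed header, row width, or field value.
    """
    path = Path(path)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise PatchTableParseError(f"cannot read patch table {path}: {exc}") from exc

    lines = raw.splitlines()
    if not lines:
        raise PatchTableParseError("empty patch table", line=1)
    header = tuple(lines[0].split("\t"))
    if header != PATCH_TABLE_COLUMNS:
        missing = set(PATCH_TABLE_COLUMNS) - set(header)
        raise PatchTableParseError(
            f"bad header {header!r}" + (f"; missing columns {sorted(missing)}" if missing else ""),
            line=1,
        )

    records: list[PatchRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(PATCH_TABLE_COLUMNS):
            raise PatchTableParseError(
                f"expected {len(PATCH_TABLE_COLUMNS)} columns, got {len(cells)}",
                line=lineno,
            )
        row = dict(zip(PATCH_TABLE_COLUMNS, cells))
        try:
            records.append(
                PatchRecord(
                    slide_id=row["slide_id"],
                    x=int(row["x"]),
                    y=int(row["y"]),
                    patch_size=int(row["patch_size"]),
                    h_mean=float(row["h_mean"]) if row["h_mean"] else None,
                    label=row["label"] or None,
                    til_count=int(row["til_count"]) if row["til_count"] else None,
                    density=float(row["density"]) if row["density"] else None,
                )
            )
        except ValueError as exc:
            raise PatchTableParseError(str(exc), line=lineno) from exc
    return records
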