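"""Shared fixtures: synthetic slides with ground truth.

Expensive slides are session-scoped; everything is generated from fixed
seeds so the suite is deterministic end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from fastil.synthetic import Region, SlideSpec, generate_slide, slide_handle_from_spec

PATCH = 768


@pytest.fixture(scope="session")
def standard_slide():
    """2304² slide: grid-aligned 2x2-patch tumor block + 1x2-patch stroma
    column, default densities; bottom third is glass."""
    spec = SlideSpec(
        width=3 * PATCH,
        height=3 * PATCH,
        mpp=1.0,
        seed=7,
        regions=(
            Region("tumor", rect=(0, 0, 2 * PATCH, 2 * PATCH)),
            Region("stroma", rect=(2 * PATCH, 0, PATCH, 2 * PATCH)),
        ),
    )
    handle, gt = slide_handle_from_spec(spec)
    return spec, handle, gt


@pytest.fixture(scope="session")
def tumor_slide_1500():
    """Grid-aligned pure-tumor block with planted lymphocyte density
    exactly 1500/mm² (density-recovery fixture)."""
    spec = SlideSpec(
        width=3 * PATCH,
        height=3 * PATCH,
        mpp=1.0,
        seed=21,
        regions=(Region("tumor", rect=(0, 0, 2 * PATCH, 2 * PATCH)),),
        nuclei_density_per_class={"tumor": (1500.0, 4000.0)},
    )
    handle, gt = slide_handle_from_spec(spec)
    return spec, handle, gt


@pytest.fixture(scope="session")
def homogeneous_slide_36():
    """6x6-patch slide fully covered by homogeneous tumor tissue (sampling
    experiments need many exchangeable patches)."""
    spec = SlideSpec(
        width=6 * PATCH,
        height=6 * PATCH,
        mpp=1.0,
        seed=13,
        regions=(Region("tumor", rect=(0, 0, 6 * PATCH, 6 * PATCH)),),
        nuclei_density_per_class={"tumor": (1500.0, 4000.0)},
    )
    handle, gt = slide_handle_from_spec(spec)
    return spec, handle, gt


@pytest.fixture()
def flat_white_image():
    return np.full((256, 256, 3), 255, dtype=np.uint8)


def make_class_patch(region_class: str, seed: int = 0, densities=None) -> tuple:
    """One full-patch region of the given class; returns (image, gt)."""
    kwargs = {}
    if densities is not None:
        kwargs["nuclei_density_per_class"] = densities
    spec = SlideSpec(
        width=PATCH,
        height=PATCH,
        mpp=1.0,
        seed=seed,
        regions=(Region(region_class, rect=(0, 0, PATCH, PATCH)),),
        **kwargs,
    )
    return generate_slide(spec)
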