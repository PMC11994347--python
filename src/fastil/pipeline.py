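"""End-to-end pipeline: extract -> (sample) -> classify -> filter ->
quantify -> score -> heatmap, with a reproducible run manifest.

The manifest records the config digest, a content digest of the slide,
every seed used, and the stage-wise patch counts (which are non-increasing
along the pipeline). Identical inputs and seeds give identical outputs.
A slide whose retained patch set is empty is reported as unevaluable, not
as a score of zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .classification import PatchClassifier, classify_patches, filter_prognostic
from .config import ExtractionConfig, HeatmapSpec, SamplingConfig, config_digest
from .extraction import extract_patches
from .image_io import PatchRecord, SlideHandle, open_slide, write_patch_table
from .quantification import Quantifier, SlideResult, quantify_patches
from .sampling import sample_patches
from .viz import save_heatmap

__all__ = ["PipelineOutput", "run_pipeline"]

logger = logging.getLogger("fastil")


@dataclass
class PipelineOutput:
    result: SlideResult
    records: list[PatchRecord]
    manifest: dict
    outdir: Optional[Path] = None
    artifacts: dict[str, Path] = field(default_factory=dict)


def _slide_digest(slide: SlideHandle) -> str:
    return hashlib.sha256(slide.level_array(0).tobytes()).hexdigest()


def run_pipeline(
    slide: Union[SlideHandle, str, Path],
    classifier: PatchClassifier,
    quantifier: Quantifier,
    extraction: ExtractionConfig = ExtractionConfig(),
    sampling: Optional[SamplingConfig] = None,
    heatmap: Optional[HeatmapSpec] = None,
    mpp_override: Optional[float] = None,
    outdir: Optional[Union[str, Path]] = None,
) -> PipelineOutput:
    """Run the whole TIL-scoring pipeline on one slide.

    ``slide`` may be a path or an open handle. With ``outdir`` set, the
    patch table (TSV), slide result (JSON), run manifest (JSON), and — when
    ``heatmap`` is given — the overlay PNG are written there.
    """
    if not isinstance(slide, SlideHandle):
        slide = open_slide(slide, mpp_override=mpp_override)
    slide_id = slide.path.stem if slide.path is not None else "slide"

    records, counts = extract_patches(slide, extraction)
    logger.info("stage 1 (extract): %d candidates", len(records))

    if sampling is not None and sampling.ratio < 1.0 and records:
        records = sample_patches(records, sampling.ratio, sampling.seed)
    counts["sampled"] = len(records)
    logger.info("sampling: %d patches", len(records))

    labeled = classify_patches(records, slide, classifier)
    kept = filter_prognostic(labeled)
    counts["classified"] = len(labeled)
    counts["prognostic"] = len(kept)
    logger.info("stage 2 (classify/filter): %d prognostic patches", len(kept))

    digest = config_digest(extraction, sampling or SamplingConfig())
    quantified, result = quantify_patches(kept, slide, quantifier, config_digest=digest)
    counts["quantified"] = len(quantified)
    if result.evaluable:
        logger.info("stage 3 (quantify): TILs score %.1f cells/mm²", result.til_score)
    else:
        logger.warning("slide %s is unevaluable: no retained tumor/stroma patches", slide_id)

    manifest = {
        "slide_id": slide_id,
        "slide_digest": _slide_digest(slide),
        "config_digest": digest,
        "mpp": slide.mpp,
        "patch_size": extraction.patch_size,
        "sampling_ratio": sampling.ratio if sampling else 1.0,
        "sampling_seed": sampling.seed if sampling else None,
        "stage_counts": counts,
        "til_score": result.til_score,
        "evaluable": result.evaluable,
    }

    output = PipelineOutput(
        result=SlideResult(
            slide_id=slide_id,
            n_patches=result.n_patches,
            til_score=result.til_score,
            config_digest=digest,
        ),
        records=quantified,
        manifest=manifest,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        output.outdir = outdir
        output.artifacts["patch_table"] = write_patch_table(
            quantified, outdir / f"{slide_id}_patches.tsv"
        )
        result_path = outdir / f"{slide_id}_result.json"
        result_path.write_text(
            json.dumps(
                {
                    "slide_id": slide_id,
                    "n_patches": result.n_patches,
                    "til_score": result.til_score,
                    "config_digest": digest,
                },
                indent=2,
            )
        )
        output.artifacts["result"] = result_path
        manifest_path = outdir / f"{slide_id}_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        output.artifacts["manifest"] = manifest_path
        if heatmap is not None and quantified:
            output.artifacts["heatmap"] = save_heatmap(
                slide, quantified, outdir / f"{slide_id}_heatmap.png", heatmap
            )
    return output
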