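"""Randomized patch subsampling and the Monte-Carlo stability harness.

Sampling happens after stage-1 extraction and before classification: a
uniform draw without replacement of ``m = max(1, round(ratio * N))`` patches
(round half to even) cuts the work passed to the classifier and quantifier.
Because the slide score is a mean over patches, simple random sampling keeps
it unbiased; the harness quantifies the induced variance by replicating the
downstream pipeline over a ratio grid and reporting score and c-index
mean ± sd per ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import PatchClassifier, classify_patches, filter_prognostic
from .image_io import PatchRecord, SlideHandle
from .quantification import Quantifier, quantify_patches
from .survival import SurvivalRecord, concordance_index

__all__ = [
    "sample_patches",
    "SlideContext",
    "monte_carlo_stability",
    "stability_table_to_csv",
]


def sample_patches(
    records: Sequence[PatchRecord], ratio: float, seed: int
) -> list[PatchRecord]:
    """Uniform subsample without replacement; input order preserved.

    Keeps ``m = max(1, round(ratio * N))`` records (banker's rounding).
    Identical (records, ratio, seed) yields an identical subset.
    """
    if not records:
        raise ValueError("cannot sample from an empty record list")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    n = len(records)
    m = max(1, round(ratio * n))
    if m >= n:
        return list(records)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    return [records[i] for i in idx]


@dataclass
class SlideContext:
    """One slide prepared for repeated downstream runs.

    ``records`` is the stage-1 (extracted, unclassified) patch set; the
    classifier and quantifier are slide-bound so oracles can carry their
    ground truth.
    """

    patient_id: str
    handle: SlideHandle
    records: list[PatchRecord]
    classifier: PatchClassifier
    quantifier: Quantifier


def _replicate_scores(
    contexts: Sequence[SlideContext], ratio: float, seed: int
) -> dict[str, Optional[float]]:
    """Patient scores for one replicate (None where a slide is unevaluable)."""
    scores: dict[str, Optional[float]] = {}
    for k, ctx in enumerate(contexts):
        # per-slide stream: unique per (replicate seed, slide) so slides
        # sample independently but reproducibly
        slide_seed = np.random.default_rng([seed, k]).integers(0, 2**31 - 1)
        sampled = sample_patches(ctx.records, ratio, int(slide_seed))
        labeled = classify_patches(sampled, ctx.handle, ctx.classifier)
        kept = filter_prognostic(labeled)
        _, result = quantify_patches(kept, ctx.handle, ctx.quantifier)
        scores[ctx.patient_id] = result.til_score
    return scores


def monte_carlo_stability(
    contexts: Sequence[SlideContext],
    ratios: Sequence[float],
    replicates: int,
    survival: Sequence[SurvivalRecord],
    base_seed: int = 0,
) -> pd.DataFrame:
    """Score and c-index stability across sampling ratios.

    For each ratio and replicate r the downstream pipeline (sample ->
    classify -> filter -> quantify -> score) runs with the replicate seed
    ``base_seed + r``; the cohort c-index treats the TILs score as
    protective. Returns one row per ratio with the replicate mean and sd of
    the cohort-mean score and of the c-index. Fully reproducible from
    ``base_seed``.
    """
    if len(contexts) < 2:
        raise ValueError("stability harness needs >= 2 slides")
    if not ratios:
        raise ValueError("ratio list is empty")
    by_patient = {r.patient_id: r for r in survival}
    rows = []
    for ratio in ratios:
        mean_scores = np.empty(replicates)
        cindices = np.empty(replicates)
        for r in range(replicates):
            scores = _replicate_scores(contexts, ratio, base_seed + r)
            vals = [s for s in scores.values() if s is not None]
            mean_scores[r] = float(np.mean(vals)) if vals else np.nan
            scored = [
                by_patient[pid].with_score(s)
                for pid, s in scores.items()
                if s is not None and pid in by_patient
            ]
            cindices[r] = concordance_index(
                scored, direction="higher_score_lower_risk"
            )
        rows.append(
            {
                "ratio": ratio,
                "score_mean": float(np.nanmean(mean_scores)),
                "score_sd": float(np.nanstd(mean_scores, ddof=1)) if replicates > 1 else 0.0,
                "cindex_mean": float(np.nanmean(cindices)),
                "cindex_sd": float(np.nanstd(cindices, ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def stability_table_to_csv(table: pd.DataFrame) -> str:
    """Fixed-format CSV rendering (17 significant digits, byte-stable)."""
    return table.to_csv(index=False, float_format="%.17g")
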