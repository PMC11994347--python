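"""Stage-3 behavior: nucleus detection, density normalization (exact
arithmetic), slide and patient aggregation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from fastil.classification import OracleClassifier, classify_patches, filter_prognostic
from fastil.config import DetectorParams, EOSIN_TISSUE_RGB, LYMPHOCYTE_RGB
from fastil.extraction import compute_tissue_mask, h_filter, mask_to_patch_grid
from fastil.quantification import (
    OracleQuantifier,
    patch_density,
    patient_score,
    quantify_patches,
    reference_detect,
    slide_score,
)
from fastil.survival import EmptyScoreError

FIXTURE_PARAMS = DetectorParams(
    h_threshold=0.06, min_area=10, max_area=200, lymph_area_max=50, circ_min=0.6
)


def pink_patch(size=512):
    return np.full((size, size, 3), EOSIN_TISSUE_RGB, dtype=np.uint8)


class TestReferenceDetect:
    def test_blank_white_patch_empty(self):
        patch = np.full((256, 256, 3), 255, dtype=np.uint8)
        assert reference_detect(patch, FIXTURE_PARAMS) == []

    def test_twelve_planted_disks_all_found(self):
        """12 non-touching lymphocyte disks: exactly 12 lymphocyte detections."""
        patch = pink_patch()
        centers = [(64 + 96 * i, 64 + 96 * j) for i in range(4) for j in range(3)]
        for cy, cx in centers:
            rr, cc = draw_disk((cy, cx), 3, shape=patch.shape[:2])
            patch[rr, cc] = LYMPHOCYTE_RGB
        det = reference_detect(patch, FIXTURE_PARAMS)
        assert len(det) == 12
        assert all(d.cell_kind == "lymphocyte" for d in det)
        got = {(round(d.y), round(d.x)) for d in det}
        assert got == set(centers)

    def test_translation_equivariance(self):
        patch = pink_patch(256)
        rr, cc = draw_disk((80, 90), 3)
        patch[rr, cc] = LYMPHOCYTE_RGB
        shifted = np.roll(patch, (17, -23), axis=(0, 1))
        d0 = reference_detect(patch, FIXTURE_PARAMS)
        d1 = reference_detect(shifted, FIXTURE_PARAMS)
        assert len(d0) == len(d1) == 1
        assert d1[0].y - d0[0].y == pytest.approx(17)
        assert d1[0].x - d0[0].x == pytest.approx(-23)
        assert d1[0].area_px == d0[0].area_px

    def test_large_blob_classified_other(self):
        patch = pink_patch(256)
        rr, cc = draw_disk((128, 128), 6)
        patch[rr, cc] = LYMPHOCYTE_RGB  # area ~113 > lymph_area_max 50
        det = reference_detect(patch, FIXTURE_PARAMS)
        assert [d.cell_kind for d in det] == ["other"]

    def test_oversized_component_discarded(self):
        patch = pink_patch(256)
        rr, cc = draw_disk((128, 128), 20)  # area ~1257 > max_area 200
        patch[rr, cc] = LYMPHOCYTE_RGB
        assert reference_detect(patch, FIXTURE_PARAMS) == []


class TestPatchDensity:
    def test_zero_count(self):
        assert patch_density(0, 768, 0.25) == 0.0

    def test_hand_evaluated_example(self):
        """c=100, 768-px patch at 0.25 um/px: (768*0.25)² = 36864 um², so
        d = 100/36864 * 1e6 ≈ 2712.67 cells/mm²."""
        assert patch_density(100, 768, 0.25) == pytest.approx(2712.6736, abs=1e-3)

    def test_halving_mpp_quadruples_density(self):
        assert patch_density(100, 768, 0.125) == pytest.approx(
            4 * patch_density(100, 768, 0.25)
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        c=st.integers(0, 10**6),
        patch=st.integers(1, 4096),
        mpp_hundredths=st.integers(1, 400),
    )
    def test_matches_exact_rational_arithmetic(self, c, patch, mpp_hundredths):
        """Float evaluation agrees with exact big-integer rationals."""
        mpp = mpp_hundredths / 100
        exact = Fraction(c) / (Fraction(patch) * Fraction(mpp_hundredths, 100)) ** 2 * 10**6
        assert patch_density(c, patch, mpp) == pytest.approx(float(exact), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            patch_density(1, 0, 0.25)
        with pytest.raises(ValueError):
            patch_density(1, 768, -1.0)


class TestScores:
    def test_slide_mean(self):
        assert slide_score([1000.0, 2000.0, 3000.0]) == 2000.0
        assert slide_score([42.0]) == 42.0

    def test_slide_order_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.random(50) * 1e4
        assert slide_score(v) == pytest.approx(slide_score(v[::-1]))

    def test_empty_slide_is_no_score(self):
        with pytest.raises(EmptyScoreError):
            slide_score([])

    def test_patient_reduces_to_slide_for_k1(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            d = list(rng.random(rng.integers(1, 10)) * 5000)
            assert patient_score([d]) == pytest.approx(slide_score(d))

    def test_patient_is_mean_of_slide_means_not_pooled(self):
        """Slides with means 100 (n=10) and 300 (n=1): patient score is 200,
        not the pooled 1300/11 ≈ 118.2."""
        slides = [[100.0] * 10, [300.0]]
        assert patient_score(slides) == pytest.approx(200.0)
        pooled = float(np.mean([d for s in slides for d in s]))
        assert pooled == pytest.approx(1300 / 11)
        assert patient_score(slides) != pytest.approx(pooled)

    def test_identical_slides_common_mean(self):
        assert patient_score([[500.0, 700.0]] * 3) == pytest.approx(600.0)

    def test_empty_slide_in_list_rejected(self):
        with pytest.raises(EmptyScoreError):
            patient_score([[100.0], []])


class TestQuantifyPatches:
    def stage12(self, handle, gt):
        mask, scale = compute_tissue_mask(handle)
        grid = mask_to_patch_grid(mask, scale, handle)
        kept = h_filter(grid, handle)
        labeled = classify_patches(kept, handle, OracleClassifier(gt))
        return filter_prognostic(labeled)

    def test_oracle_quantifier_recovers_planted_density(self, tumor_slide_1500):
        _, handle, gt = tumor_slide_1500
        records = self.stage12(handle, gt)
        quantified, result = quantify_patches(records, handle, OracleQuantifier(gt))
        assert result.evaluable
        assert result.til_score == pytest.approx(1500.0, rel=0.05)
        # counts partition the planted lymphocytes exactly (grid-aligned region)
        total = sum(r.til_count for r in quantified)
        assert total == gt.planted_counts[0]["lymphocyte"]

    def test_zero_lymphocyte_slide_scores_zero(self, tumor_slide_1500):
        from fastil.synthetic import Region, SlideSpec, slide_handle_from_spec

        spec = SlideSpec(
            width=1536, height=1536, mpp=1.0, seed=2,
            regions=(Region("tumor", rect=(0, 0, 1536, 1536)),),
            nuclei_density_per_class={"tumor": (0.0, 4000.0)},
        )
        handle, gt = slide_handle_from_spec(spec)
        records = self.stage12(handle, gt)
        assert records  # H-filter passes on other-cell nuclei
        _, result = quantify_patches(records, handle, OracleQuantifier(gt))
        assert result.til_score == 0.0

    def test_density_linear_in_count(self, tumor_slide_1500):
        _, handle, gt = tumor_slide_1500
        records = self.stage12(handle, gt)
        quantified, result = quantify_patches(records, handle, OracleQuantifier(gt))
        doubled = [
            patch_density(2 * r.til_count, r.patch_size, handle.mpp)
            for r in quantified
        ]
        assert slide_score(doubled) == pytest.approx(2 * result.til_score)

    def test_empty_retained_set_unevaluable(self, tumor_slide_1500):
        _, handle, gt = tumor_slide_1500
        _, result = quantify_patches([], handle, OracleQuantifier(gt))
        assert result.til_score is None
        assert not result.evaluable
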