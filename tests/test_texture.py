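"""Masked GLCM and Haralick contrast/entropy: hand oracles, exhaustive
enumeration, an independent library cross-check, and invariances."""

import math

import numpy as np
import pytest

from osteoflow.texture import (
    EmptyRegionError,
    GLCM,
    InvalidOffsetError,
    TextureParams,
    compute_glcm,
    haralick_contrast,
    haralick_entropy,
    measure_cell,
    measure_cells,
    quantize_masked,
    texture_measures,
)
from osteoflow.segmentation import max_intensity_projection

from conftest import make_projection


def brute_force_glcm(img, mask, offset, levels, symmetric=True):
    """Independent oracle: enumerate every pixel pair in pure Python."""
    h, w = img.shape
    counts = np.zeros((levels, levels))
    n = 0
    offsets = [offset, (-offset[0], -offset[1])] if symmetric else [offset]
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    counts[img[r, c], img[r2, c2]] += 1
                    n += 1
    return (counts / n if n else counts), n


def brute_force_features(p):
    contrast = sum(
        (i - j) ** 2 * p[i, j] for i in range(p.shape[0]) for j in range(p.shape[1])
    )
    entropy = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(p.shape[0])
        for j in range(p.shape[1])
        if p[i, j] > 0
    )
    return contrast, entropy


class TestQuantizeMasked:
    def test_constant_region_maps_to_zero(self):
        img = np.full((4, 4), 7.0)
        q = quantize_masked(img, np.ones((4, 4), bool), 8)
        assert (q == 0).all()

    def test_equally_spaced_values_map_bijectively(self):
        img = np.array([[0.0, 10.0], [20.0, 30.0]])
        q = quantize_masked(img, np.ones((2, 2), bool), 4)
        np.testing.assert_array_equal(q, [[0, 1], [2, 3]])

    def test_ramp_matches_direct_formula(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        mask = np.ones((4, 4), bool)
        q = quantize_masked(img, mask, 4)
        vmin, vmax = img.min(), img.max()
        expected = np.minimum(
            ((img - vmin) / (vmax - vmin) * 4).astype(int), 3
        )
        np.testing.assert_array_equal(q, expected)

    def test_outside_mask_is_negative(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        q = quantize_masked(np.ones((3, 3)), mask, 8)
        assert q[0, 0] == -1 and q[1, 1] == 0

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            quantize_masked(np.ones((3, 3)), np.zeros((3, 3), bool), 8)


class TestComputeGLCM:
    def test_constant_2x2_pairs(self):
        q = np.zeros((2, 2), dtype=int)
        glcm = compute_glcm(q, np.ones((2, 2), bool), (0, 1), levels=2, symmetric=True)
        # two horizontal adjacencies, counted in both directions
        assert glcm.n_pairs == 4
        assert glcm.matrix[0, 0] == 1.0
        assert glcm.matrix.sum() == pytest.approx(1.0)

    def test_checkerboard_off_diagonal(self):
        q = np.indices((4, 4)).sum(axis=0) % 2
        glcm = compute_glcm(q, np.ones((4, 4), bool), (0, 1), levels=2, symmetric=True)
        assert glcm.matrix[0, 1] == pytest.approx(0.5)
        assert glcm.matrix[1, 0] == pytest.approx(0.5)
        assert glcm.matrix[0, 0] == glcm.matrix[1, 1] == 0.0

    def test_mask_blocking_all_pairs_gives_degenerate(self):
        mask = np.zeros((3, 3), bool)
        mask[::2, ::2] = True  # isolated pixels at offset (0,1)
        q = np.zeros((3, 3), dtype=int)
        glcm = compute_glcm(q, mask, (0, 1), levels=2)
        assert glcm.degenerate
        assert haralick_contrast(glcm) is None
        assert haralick_entropy(glcm) is None

    def test_zero_offset_rejected(self):
        with pytest.raises(InvalidOffsetError):
            compute_glcm(np.zeros((3, 3), int), np.ones((3, 3), bool), (0, 0), 2)

    def test_symmetric_matrix_equals_transpose(self):
        rng = np.random.default_rng(0)
        q = rng.integers(0, 8, (12, 12))
        glcm = compute_glcm(q, np.ones((12, 12), bool), (1, -1), levels=8, symmetric=True)
        np.testing.assert_allclose(glcm.matrix, glcm.matrix.T)
        assert glcm.matrix.sum() == pytest.approx(1.0)


class TestHaralickFeatures:
    def test_constant_image_zero_contrast_zero_entropy(self):
        q = np.zeros((4, 4), dtype=int)
        glcm = compute_glcm(q, np.ones((4, 4), bool), (0, 1), levels=8)
        assert haralick_contrast(glcm) == 0.0
        assert haralick_entropy(glcm) == 0.0

    def test_checkerboard_contrast_one_entropy_one_bit(self):
        q = np.indices((6, 6)).sum(axis=0) % 2
        glcm = compute_glcm(q, np.ones((6, 6), bool), (0, 1), levels=2)
        assert haralick_contrast(glcm) == pytest.approx(1.0)
        assert haralick_entropy(glcm) == pytest.approx(1.0)

    def test_uniform_glcm_entropy_is_log2_cells(self):
        p = np.full((4, 4), 1 / 16)
        glcm = GLCM(matrix=p, levels=4, offset=(0, 1), symmetric=True, n_pairs=16)
        assert haralick_entropy(glcm) == pytest.approx(4.0)

    def test_bounds_on_random_images(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = int(rng.integers(2, 9))
            q = rng.integers(0, g, (10, 10))
            glcm = compute_glcm(q, np.ones((10, 10), bool), (0, 1), levels=g)
            assert 0 <= haralick_contrast(glcm) <= (g - 1) ** 2
            assert 0 <= haralick_entropy(glcm) <= 2 * math.log2(g)


class TestOracles:
    def test_all_512_binary_3x3_images_match_enumeration(self):
        mask = np.ones((3, 3), bool)
        for bits in range(512):
            img = np.array([(bits >> k) & 1 for k in range(9)]).reshape(3, 3)
            glcm = compute_glcm(img, mask, (0, 1), levels=2, symmetric=True)
            p_ref, n_ref = brute_force_glcm(img, mask, (0, 1), 2, symmetric=True)
            assert glcm.n_pairs == n_ref
            np.testing.assert_allclose(glcm.matrix, p_ref)
            if n_ref:
                c_ref, e_ref = brute_force_features(p_ref)
                assert haralick_contrast(glcm) == pytest.approx(c_ref, abs=1e-12)
                assert haralick_entropy(glcm) == pytest.approx(e_ref, abs=1e-12)

    def test_matches_skimage_on_random_regions(self):
        # independent reference implementation on full rectangular masks
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(2)
        for _ in range(20):
            g = 8
            q = rng.integers(0, g, (32, 32)).astype(np.uint8)
            mask = np.ones((32, 32), bool)
            for dr, dc, angle in [(0, 1, 0.0), (1, 0, -np.pi / 2)]:
                ref = graycomatrix(
                    q, [1], [angle], levels=g, symmetric=True, normed=True
                )[:, :, 0, 0]
                # skimage angle convention: angle 0 is (0,+1); -pi/2 is (+1,0)
                glcm = compute_glcm(q, mask, (dr, dc), levels=g, symmetric=True)
                np.testing.assert_allclose(glcm.matrix, ref, atol=1e-6)
                idx = np.arange(g)
                ref_contrast = ((idx[:, None] - idx[None, :]) ** 2 * ref).sum()
                p = ref[ref > 0]
                ref_entropy = -(p * np.log2(p)).sum()
                assert haralick_contrast(glcm) == pytest.approx(ref_contrast, abs=1e-6)
                assert haralick_entropy(glcm) == pytest.approx(ref_entropy, abs=1e-6)

    def test_masked_regions_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = rng.integers(0, 4, (12, 12))
            mask = rng.uniform(size=(12, 12)) < 0.7
            if not mask.any():
                continue
            for offset in [(0, 2), (2, 0), (1, 1), (1, -1)]:
                glcm = compute_glcm(q, mask, offset, levels=4)
                p_ref, n_ref = brute_force_glcm(q, mask, offset, 4)
                assert glcm.n_pairs == n_ref
                np.testing.assert_allclose(glcm.matrix, p_ref, atol=1e-12)


class TestMeasureCell:
    @staticmethod
    def _single_cell_projection():
        rng = np.random.default_rng(4)
        actin = rng.uniform(0, 500, (32, 32))
        runx2 = np.zeros((32, 32))
        nucleus = np.zeros((32, 32), bool)
        nucleus[12:20, 12:20] = True
        cyto = np.zeros((32, 32), bool)
        cyto[6:28, 6:28] = True
        runx2[nucleus] = 42.0
        return make_projection(np.zeros((32, 32)), actin, runx2), nucleus, cyto

    def test_constant_runx2_recovered(self):
        proj, nucleus, cyto = self._single_cell_projection()
        m = measure_cell(proj, nucleus, cyto)
        assert m.runx2_mean == 42.0
        assert m.runx2_integrated == 42.0 * nucleus.sum()

    def test_cytoplasm_must_contain_nucleus(self):
        proj, nucleus, _ = self._single_cell_projection()
        bad_cyto = np.zeros((32, 32), bool)
        bad_cyto[0:10, 0:10] = True
        with pytest.raises(ValueError, match="contain"):
            measure_cell(proj, nucleus, bad_cyto)

    def test_affine_rescaling_invariance(self):
        proj, nucleus, cyto = self._single_cell_projection()
        m1 = measure_cell(proj, nucleus, cyto)
        scaled = make_projection(
            proj["dapi"], proj["phalloidin"] * 3 + 7, proj["runx2"]
        )
        m2 = measure_cell(scaled, nucleus, cyto)
        assert m2.contrast == pytest.approx(m1.contrast, rel=1e-12)
        assert m2.entropy == pytest.approx(m1.entropy, rel=1e-12)

    def test_four_direction_average_and_metadata(self):
        proj, nucleus, cyto = self._single_cell_projection()
        m = measure_cell(proj, nucleus, cyto, TextureParams(levels=8, distance=3))
        assert len(m.per_direction) == 4
        vals = [v["contrast"] for v in m.per_direction.values()]
        assert m.contrast == pytest.approx(np.mean(vals))

    def test_ground_truth_masks_recover_generator_runx2(self, clean_scene):
        stack, truth = clean_scene
        proj = max_intensity_projection(stack)
        measurements = measure_cells(proj, truth.nucleus_labels, truth.cell_labels)
        by_id = {m.cell_id: m for m in measurements}
        for _, row in truth.cells.iterrows():
            assert by_id[row.label].runx2_mean == pytest.approx(row.runx2_true, abs=1e-12)

    def test_glcm_normalization_for_all_measured_cells(self, clean_scene):
        stack, truth = clean_scene
        proj = max_intensity_projection(stack)
        params = TextureParams()
        for lab in range(1, int(truth.nucleus_labels.max()) + 1):
            mask = truth.cell_labels == lab
            quant = quantize_masked(proj["phalloidin"], mask, params.levels)
            for offset in params.offsets:
                glcm = compute_glcm(quant, mask, offset, params.levels)
                assert glcm.matrix.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(glcm.matrix, glcm.matrix.T)


class TestPhenotypeSeparation:
    def test_peripheral_fibres_score_higher_on_both_features(self):
        # the osteogenic phenotype should separate on median contrast AND
        # entropy at matched whole-cell brightness
        from osteoflow.synthetic import PhenotypeSpec, render_phenotype

        rng = np.random.default_rng(10)
        medians = {}
        for ph in (PhenotypeSpec.homogeneous(), PhenotypeSpec.peripheral()):
            cs, es = [], []
            for _ in range(30):
                layer, mask = render_phenotype((81, 81), (40, 40), 32, ph, rng, 250.0)
                c, e, _, _ = texture_measures(layer, mask)
                cs.append(c)
                es.append(e)
            medians[ph.kind] = (np.median(cs), np.median(es))
        hom, per = medians["homogeneous_filaments"], medians["peripheral_stress_fibres"]
        assert per[0] > hom[0]
        assert per[1] > hom[1]
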