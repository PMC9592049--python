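import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srdenoise.boundary import (
    BinaryMask,
    ConfusionCounts,
    binarize,
    boundary_scores,
    confusion,
    equalize,
    evaluate_boundary,
    isodata_threshold,
    overlay,
)

from oracles import brute_force_isodata, harmonic_mean, truth_table_confusion


class TestEqualize:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 3.3)
        assert np.array_equal(equalize(img), img)

    def test_uniform_histogram_preserved_up_to_monotone_relabeling(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        out = equalize(img)
        order_in = np.argsort(img.ravel(), kind="stable")
        assert np.all(np.diff(out.ravel()[order_in]) >= 0)
        assert out.min() >= 0 and out.max() <= 255

    def test_output_cdf_is_near_linear_on_bimodal_image(self, rng):
        img = np.concatenate(
            [rng.normal(40, 12, 2048), rng.normal(180, 20, 2048)]
        ).reshape(64, 64)
        out = equalize(img)
        values = np.unique(out)
        ecdf = np.searchsorted(np.sort(out.ravel()), values, side="right") / out.size
        # inclusive CDF at each output level sits on the ideal ramp v/255
        assert np.max(np.abs(255 * ecdf - values)) <= 255 / 256 + 1e-9


class TestIsoData:
    def test_two_value_fixed_points(self):
        img = np.array([[10.0, 200.0]] * 8)
        assert isodata_threshold(img) == pytest.approx(105.0)
        img2 = np.array([[0.0, 255.0]] * 8)
        assert isodata_threshold(img2) == pytest.approx(127.5)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            isodata_threshold(np.ones((4, 4)))

    def test_matches_exhaustive_fixed_point_search(self, rng):
        img = np.concatenate(
            [rng.normal(60, 15, 3000), rng.normal(190, 10, 1096)]
        ).reshape(64, 64)
        t = isodata_threshold(img)
        t_brute = brute_force_isodata(img)
        bin_width = (img.max() - img.min()) / 256
        assert abs(t - t_brute) <= bin_width


class TestBinarizeConfusion:
    def test_binarize_edges(self):
        img = np.array([[10.0, 200.0]] * 4)
        assert binarize(img, 5.0).pixels.all()
        assert not binarize(img, 300.0).pixels.any()
        assert binarize(img, 105.0).count == 4  # midpoint splits exactly

    def test_identical_and_empty_masks(self):
        m = BinaryMask(np.eye(8, dtype=bool))
        counts, masks = confusion(m, m)
        assert masks["FP"].count == 0 and masks["FN"].count == 0
        assert counts.count_AND == counts.count_Ans == 8
        empty = BinaryMask(np.zeros((8, 8), dtype=bool))
        counts2, masks2 = confusion(empty, m)
        assert counts2.count_AND == 0
        assert np.array_equal(masks2["NOR"].pixels, ~m.pixels)

    def test_counts_match_truth_table_enumeration(self, rng):
        o = rng.random((8, 8)) > 0.5
        a = rng.random((8, 8)) > 0.4
        counts, masks = confusion(BinaryMask(o), BinaryMask(a))
        ref = truth_table_confusion(o, a)
        assert counts.count_O == ref["O"]
        assert counts.count_Ans == ref["Ans"]
        assert counts.count_AND == ref["AND"]
        assert counts.count_NOR == ref["NOR"]
        assert masks["FP"].count == ref["FP"]
        assert masks["FN"].count == ref["FN"]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        o = BinaryMask(rng.random((12, 12)) > rng.random())
        a = BinaryMask(rng.random((12, 12)) > rng.random())
        counts, masks = confusion(o, a)
        total = counts.count_AND + counts.count_NOR + masks["FP"].count + masks["FN"].count
        assert total == counts.total_pixels
        assert counts.count_IAns == counts.total_pixels - counts.count_Ans

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(BinaryMask(np.zeros((4, 4), bool)), BinaryMask(np.zeros((5, 5), bool)))


class TestScores:
    def test_identical_masks_score_one(self):
        c = ConfusionCounts(count_O=30, count_Ans=30, count_AND=30, count_NOR=34, total_pixels=64)
        s = boundary_scores(c)
        assert (s.precision, s.recall, s.specificity, s.f_measure) == (1.0, 1.0, 1.0, 1.0)

    def test_printed_arithmetic_fixture(self):
        c = ConfusionCounts(count_O=100, count_Ans=80, count_AND=50, count_NOR=870, total_pixels=1000)
        s = boundary_scores(c)
        assert s.precision == pytest.approx(0.5)
        assert s.recall == pytest.approx(0.625)
        assert s.specificity == pytest.approx(870 / 920)
        assert s.f_measure == pytest.approx(0.5556, abs=1e-4)

    @given(
        count_and=st.integers(0, 50),
        extra_o=st.integers(0, 50),
        extra_ans=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f_is_harmonic_mean(self, count_and, extra_o, extra_ans):
        count_o = count_and + extra_o
        count_ans = count_and + extra_ans
        total = 500
        nor = total - (count_o + count_ans - count_and)
        s = boundary_scores(
            ConfusionCounts(count_O=count_o, count_Ans=count_ans, count_AND=count_and, count_NOR=nor, total_pixels=total)
        )
        if count_o and count_ans and count_and:
            assert s.f_measure == pytest.approx(harmonic_mean(s.precision, s.recall), abs=1e-12)
            for v in (s.precision, s.recall, s.specificity, s.f_measure):
                assert 0.0 <= v <= 1.0

    def test_degenerate_denominators_flagged(self):
        c = ConfusionCounts(count_O=0, count_Ans=10, count_AND=0, count_NOR=54, total_pixels=64)
        s = boundary_scores(c)
        assert math.isnan(s.precision) and math.isnan(s.f_measure)
        assert "count_O" in s.undefined_reason


class TestOverlayAndPipeline:
    def test_overlay_colour_code(self):
        o = BinaryMask(np.array([[1, 1], [0, 0]], dtype=bool))
        a = BinaryMask(np.array([[1, 0], [1, 0]], dtype=bool))
        _, masks = confusion(o, a)
        rgb = overlay(masks)
        assert tuple(rgb[0, 0]) == (0, 0, 255)  # TP blue
        assert tuple(rgb[0, 1]) == (255, 0, 255)  # FP magenta
        assert tuple(rgb[1, 0]) == (0, 255, 0)  # FN green
        assert tuple(rgb[1, 1]) == (0, 0, 0)

    def test_answer_vs_itself_scores_one(self, nuclei_batch):
        _, answer = nuclei_batch
        scores, rgb, _ = evaluate_boundary(answer.pixels, answer.pixels)
        assert scores.f_measure == pytest.approx(1.0)
        assert not (rgb[..., 0] > 0).any()  # no magenta/green

    def test_inverted_answer_has_near_zero_precision(self, nuclei_batch):
        _, answer = nuclei_batch
        inverted = answer.pixels.max() - answer.pixels
        scores, _, _ = evaluate_boundary(inverted, answer.pixels)
        assert scores.precision < 0.2

    def test_pipeline_is_deterministic(self, nuclei_batch):
        stack, answer = nuclei_batch
        s1, rgb1, _ = evaluate_boundary(stack.frames[0], answer.pixels)
        s2, rgb2, _ = evaluate_boundary(stack.frames[0], answer.pixels)
        assert s1 == s2
        assert np.array_equal(rgb1, rgb2)

    def test_thresholds_are_independent_not_shared(self):
        """Each image is binarized at its own IsoData threshold."""
        rng = np.random.default_rng(0)
        # three-level test image vs two-level answer: the answer's threshold
        # falls above the test image's middle level, its own below it
        img_o = np.repeat([10.0, 100.0, 200.0], [512, 308, 204])
        img_ans = np.repeat([10.0, 200.0], [717, 307])
        rng.shuffle(img_o)
        rng.shuffle(img_ans)
        img_o, img_ans = img_o.reshape(32, 32), img_ans.reshape(32, 32)
        _, _, counts = evaluate_boundary(img_o, img_ans)
        eq_o, eq_ans = equalize(img_o), equalize(img_ans)
        t_o, t_ans = isodata_threshold(eq_o), isodata_threshold(eq_ans)
        middle = np.unique(eq_o)[1]
        assert t_o < middle < t_ans  # the fixture separates the thresholds
        independent, _ = confusion(binarize(eq_o, t_o), binarize(eq_ans, t_ans))
        shared, _ = confusion(binarize(eq_o, t_ans), binarize(eq_ans, t_ans))
        assert counts == independent
        assert counts != shared

    def test_answer_binarization_recovers_true_mask(self, nuclei_batch, nuclei_clean):
        """Equalize+IsoData on the answer traces the true cell mask (F >= 0.95)."""
        _, answer = nuclei_batch
        eq = equalize(answer.pixels)
        mask = binarize(eq, isodata_threshold(eq))
        truth = BinaryMask(nuclei_clean.cell_masks)
        counts, _ = confusion(mask, truth)
        assert boundary_scores(counts).f_measure >= 0.95
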