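"""DICE/accuracy formulas, 2D/3D aggregation, and rater-reliability protocols."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bmelseg.metrics import (
    ConfusionCounts,
    EmptySlicePolicy,
    SliceScope,
    accuracy,
    confusion,
    dice,
    dice2d,
    dice3d,
    evaluate_model,
    reliability_report,
)
from bmelseg.phantom import PhantomConfig, RaterJitter, generate_study, simulate_rater

# 3x3 printed toy: pred has 3 positives, truth has 3, overlap 2
PRED_TOY = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]])
TRUTH_TOY = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0]])


class TestConfusion:
    def test_empty_masks_all_true_negative(self):
        c = confusion(np.zeros((3, 3)), np.zeros((3, 3)))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 9)

    def test_identical_masks_have_no_errors(self):
        c = confusion(TRUTH_TOY, TRUTH_TOY)
        assert c.fp == 0 and c.fn == 0

    def test_hand_counted_toy(self):
        c = confusion(PRED_TOY, TRUTH_TOY)
        assert (c.tp, c.fp, c.fn) == (2, 1, 1)
        assert c.total == 9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDice:
    def test_empty_masks_with_smoothing_score_one(self):
        assert dice(ConfusionCounts(0, 0, 0, 9), epsilon=1e-6) == 1.0

    def test_hand_computed_two_thirds(self):
        assert dice(confusion(PRED_TOY, TRUTH_TOY), epsilon=0.0) == pytest.approx(2 / 3)

    def test_perfect_nonempty_prediction_scores_one_for_any_epsilon(self):
        for eps in (0.0, 1e-6, 1.0):
            assert dice(confusion(TRUTH_TOY, TRUTH_TOY), eps) == 1.0

    def test_undefined_without_smoothing(self):
        with pytest.raises(ZeroDivisionError):
            dice(ConfusionCounts(0, 0, 0, 9), epsilon=0.0)


class TestAccuracy:
    def test_perfect_prediction(self):
        assert accuracy(confusion(TRUTH_TOY, TRUTH_TOY)) == 1.0

    def test_hand_computed_point_eight(self):
        assert accuracy(ConfusionCounts(tp=1, tn=7, fp=1, fn=1)) == pytest.approx(0.8)

    def test_true_negative_abundance_inflates_accuracy_not_dice(self):
        base = ConfusionCounts(tp=2, fp=1, fn=1, tn=5)
        padded = ConfusionCounts(tp=2, fp=1, fn=1, tn=1005)
        assert dice(base, 0.0) == dice(padded, 0.0)
        assert accuracy(padded) > accuracy(base)


def test_dice3d_equals_flatten_and_count_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        pred = rng.uniform(size=(4, 6, 6)) > 0.6
        truth = rng.uniform(size=(4, 6, 6)) > 0.6
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        expected = (2 * tp + 1e-6) / (2 * tp + 1e-6 + fp + fn)
        assert dice3d(pred, truth) == pytest.approx(expected)


class TestDice2d:
    def test_scopes_agree_when_every_slice_has_lesion(self):
        rng = np.random.default_rng(1)
        truth = np.ones((3, 4, 4), dtype=bool)
        pred = rng.uniform(size=(3, 4, 4)) > 0.3
        assert dice2d(pred, truth, scope=SliceScope.ALL_SLICES) == pytest.approx(
            dice2d(pred, truth, scope=SliceScope.LESION_SLICES)
        )

    def test_perfect_prediction_with_empty_slices(self):
        truth = np.zeros((4, 4, 4), dtype=bool)
        truth[:2, 1:3, 1:3] = True
        assert dice2d(truth, truth) == pytest.approx(1.0)
        assert dice2d(truth, truth, scope=SliceScope.LESION_SLICES) == pytest.approx(1.0)

    def test_empty_slices_skew_all_slices_mean_upward(self):
        """Empty slices score eps/eps = 1 and pull the all-slices mean above
        the lesion-slices mean; hand-checked on a 4-slice volume."""
        truth = np.zeros((4, 3, 3), dtype=bool)
        pred = np.zeros_like(truth)
        # slices 0-1 empty & predicted empty; slices 2-3 score 2*1/(2+2) = 0.5
        for k in (2, 3):
            truth[k, 0, 0] = truth[k, 0, 1] = True
            pred[k, 0, 0] = pred[k, 2, 2] = True
        all_mean = dice2d(pred, truth)
        lesion_mean = dice2d(pred, truth, scope=SliceScope.LESION_SLICES)
        assert lesion_mean == pytest.approx(0.5, abs=1e-5)
        assert all_mean == pytest.approx((1.0 + 1.0 + 0.5 + 0.5) / 4, abs=1e-5)
        assert all_mean > lesion_mean

    def test_no_lesion_slices_in_scope_rejected(self):
        empty = np.zeros((2, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            dice2d(empty, empty, scope=SliceScope.LESION_SLICES)


class TestEvaluateModel:
    def test_single_volume_single_rater(self):
        pred = {"v": PRED_TOY[None]}
        raters = {"r1": {"v": TRUTH_TOY[None]}}
        table = evaluate_model(pred, raters, epsilon=0.0)
        overall = table.set_index("rater").loc["overall", "dice3d_mean"]
        assert overall == pytest.approx(2 / 3)

    def test_duplicate_raters_leave_overall_unchanged(self):
        pred = {"v": PRED_TOY[None]}
        raters = {"r1": {"v": TRUTH_TOY[None]}, "r2": {"v": TRUTH_TOY[None]}}
        table = evaluate_model(pred, raters, epsilon=0.0).set_index("rater")
        assert table.loc["overall", "dice3d_mean"] == pytest.approx(
            table.loc["r1", "dice3d_mean"]
        )

    def test_volumes_then_raters_averaging_order(self):
        """Constructed per-volume/per-rater DICEs {1.0, 0.5; 0.8, 0.6} must
        aggregate to ((1.0+0.5)/2 + (0.8+0.6)/2)/2 = 0.725."""
        def mask(positives, n=12):
            m = np.zeros(n, dtype=bool)
            m[list(positives)] = True
            return m.reshape(1, 3, 4)

        pred = {"v1": mask({0, 1, 2}), "v2": mask({0, 1, 2})}
        raters = {
            # rater A: dice(v1)=1.0 (identical); dice(v2)=0.5 (TP1, FP2)
            "A": {"v1": mask({0, 1, 2}), "v2": mask({0})},
            # rater B: dice(v1)=0.8 (TP2, FP1); dice(v2)=0.6 (TP3, FN4)
            "B": {"v1": mask({0, 1}), "v2": mask({0, 1, 2, 3, 4, 5, 6})},
        }
        # verify the intended per-cell scores with the formula directly
        assert dice3d(pred["v1"], raters["A"]["v1"], 0.0) == pytest.approx(1.0)
        assert dice3d(pred["v2"], raters["A"]["v2"], 0.0) == pytest.approx(0.5)
        assert dice3d(pred["v1"], raters["B"]["v1"], 0.0) == pytest.approx(0.8)
        assert dice3d(pred["v2"], raters["B"]["v2"], 0.0) == pytest.approx(0.6)
        table = evaluate_model(pred, raters, epsilon=0.0).set_index("rater")
        assert table.loc["overall", "dice3d_mean"] == pytest.approx(0.725)

    def test_missing_mask_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            evaluate_model({"v": PRED_TOY[None]}, {"r": {}})


class TestReliability:
    def test_duplicate_annotation_sets_score_one(self, lesioned_study):
        masks = {"v": lesioned_study.lesion_truth.data}
        table = reliability_report({"r1": [masks, dict(masks)], "r2": [masks]})
        assert np.allclose(table["dice3d"], 1.0)
        intra = table[table["kind"] == "intra"]
        assert len(intra) == 1

    def test_zero_jitter_raters_agree_perfectly(self):
        cfg = dataclasses.replace(
            PhantomConfig(), rater_jitter=RaterJitter(0.0, 0, 0.0), n_raters=2
        )
        study = generate_study(cfg, seed=50)
        sets = {
            "r1": [{"v": study.rater_masks[0].data}],
            "r2": [{"v": study.rater_masks[1].data}],
        }
        table = reliability_report(sets)
        inter = table[table["kind"] == "inter"]
        assert np.allclose(inter["dice3d"], 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_intra_rater_agreement_exceeds_inter_on_average(self, seed, small_config):
        """A rater's repeats (small jitter) agree better than two raters
        (full jitter), averaged over 20 simulated volumes."""
        small = RaterJitter(threshold_sd=0.03, morph_radius=0, p_miss=0.0)
        full = RaterJitter(threshold_sd=0.10, morph_radius=1, p_miss=0.1)
        rng = np.random.default_rng(seed)
        r1a, r1b, r2 = {}, {}, {}
        n_done = 0
        while n_done < 20:
            study = generate_study(small_config, int(rng.integers(2**31)))
            if not study.lesion_truth.data.any():
                continue
            vid = f"v{n_done}"
            base = int(rng.integers(2**31 - 10))
            r1a[vid] = simulate_rater(study, small, base).data
            r1b[vid] = simulate_rater(study, small, base + 1).data
            r2[vid] = simulate_rater(study, full, base + 2).data
            n_done += 1
        table = reliability_report({"r1": [r1a, r1b], "r2": [r2]}).set_index("kind")
        assert table.loc["intra", "dice3d"] >= table.loc["inter", "dice3d"]


# ---- property tests -------------------------------------------------------

mask_pair = st.integers(0, 2**32 - 1).map(
    lambda s: tuple(np.random.default_rng(s).uniform(size=(2, 4, 5, 5)) > 0.5)
)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(mask_pair)
def test_dice_is_symmetric_and_bounded(masks):
    a, b = masks
    d_ab = dice3d(a, b)
    d_ba = dice3d(b, a)
    assert d_ab == d_ba
    assert 0.0 <= d_ab <= 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(mask_pair, st.floats(1e-12, 1e-3))
def test_smoothed_dice_converges_to_unsmoothed(masks, eps):
    a, b = masks
    c = confusion(a, b)
    if c.tp + c.fp + c.fn == 0:
        return
    assert dice(c, eps) == pytest.approx(dice(c, 0.0), abs=1e-3)


def test_dice3d_immune_to_appended_empty_slices():
    rng = np.random.default_rng(4)
    pred = rng.uniform(size=(3, 5, 5)) > 0.5
    truth = rng.uniform(size=(3, 5, 5)) > 0.5
    pad = np.zeros((2, 5, 5), dtype=bool)
    assert dice3d(np.concatenate([pred, pad]), np.concatenate([truth, pad]),
                  epsilon=0.0) == dice3d(pred, truth, epsilon=0.0)
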