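import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmpmaze import (
    SessionConfig,
    TETRAGRAMS,
    TurnSequence,
    bias_percentage,
    classify_laterality,
    cohort_class_summary,
    count_tetragrams,
    per_bin_consistency,
)
from fmpmaze.laterality import tetragram_counts_per_bin


def seq_of(tokens, times=None):
    tokens = np.array(list(tokens), dtype="<U1")
    times = np.asarray(
        times if times is not None else np.arange(1.0, len(tokens) + 1.0), float
    )
    return TurnSequence(subject_id="f0", tokens=tokens, turn_times_s=times)


class TestCountTetragrams:
    def test_sixteen_categories(self):
        assert len(TETRAGRAMS) == 16 == 2**4
        assert TETRAGRAMS[0] == "llll" and TETRAGRAMS[-1] == "rrrr"

    def test_alternating_stream_counts_windows(self):
        prof = count_tetragrams(seq_of("LRLRLR"))
        assert prof.n_tetragrams == 3
        assert prof.counts["lrlr"] == 2 and prof.counts["rlrl"] == 1
        assert prof.alternation_score == 1.0
        assert prof.repetition_score == 0.0

    def test_pure_repetition(self):
        prof = count_tetragrams(seq_of("LLLL"))
        assert prof.counts["llll"] == 1 and prof.n_tetragrams == 1
        assert prof.repetition_score == 1.0

    def test_short_stream_is_degenerate_not_error(self):
        prof = count_tetragrams(seq_of("LRL"))
        assert prof.n_tetragrams == 0
        assert all(c == 0 for c in prof.counts.values())
        assert np.isnan(prof.alternation_score)
        assert all(np.isnan(v) for v in prof.rel_freq.values())

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("LR"), min_size=0, max_size=200))
    def test_window_conservation_and_normalization(self, tokens):
        prof = count_tetragrams(np.array(tokens, dtype="<U1"))
        assert prof.n_tetragrams == max(0, len(tokens) - 3)
        assert sum(prof.counts.values()) == prof.n_tetragrams
        if prof.n_tetragrams:
            assert abs(sum(prof.rel_freq.values()) - 1.0) < 1e-12
            assert 0.0 <= prof.alternation_score + prof.repetition_score <= 1.0

    def test_per_bin_windows_assigned_to_final_turn(self, cfg):
        # 5 turns straddling the first bin edge: windows complete at turns
        # 4 and 5, whose times put them in bins 0 and 1
        seq = seq_of("LLLLL", times=[1.0, 2.0, 3.0, 4.0, 601.0])
        table = tetragram_counts_per_bin(seq, cfg)
        assert table.loc[0, "llll"] == 1
        assert table.loc[1, "llll"] == 1
        assert table["repetitions"].sum() == 2


class TestBiasPercentage:
    def test_direct_formula(self):
        tokens = np.array(list("RRRRRRRLLL"), dtype="<U1")
        assert bias_percentage(tokens, "R") == 70.0
        assert bias_percentage(tokens, "L") == 30.0

    def test_all_one_side(self):
        tokens = np.array(list("LLLL"), dtype="<U1")
        assert bias_percentage(tokens, "L") == 100.0

    def test_empty_is_missing_not_zero(self):
        assert np.isnan(bias_percentage(np.array([], dtype="<U1"), "R"))

    def test_bernoulli_stream_within_99pct_interval(self):
        rng = np.random.default_rng(21)
        tokens = np.where(rng.random(500) < 0.65, "R", "L").astype("<U1")
        pct = bias_percentage(tokens, "R")
        half = 2.576 * 100 * np.sqrt(0.65 * 0.35 / 500)
        assert abs(pct - 65.0) < half

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("LR"), min_size=1, max_size=100))
    def test_sides_are_complementary(self, tokens):
        arr = np.array(tokens, dtype="<U1")
        assert bias_percentage(arr, "L") + bias_percentage(arr, "R") == pytest.approx(100.0)


class TestPerBinConsistency:
    def test_identical_bins_have_zero_cv(self, cfg):
        # 10 turns per bin, 7 R / 3 L in each of the 6 bins
        tokens, times = [], []
        for b in range(6):
            tokens += list("RRRRRRRLLL")
            times += list(b * 600.0 + np.arange(10.0))
        cons = per_bin_consistency(seq_of(tokens, times), cfg)
        assert cons.mean_R_pct == pytest.approx(70.0)
        assert cons.cv_R_pct == pytest.approx(0.0)
        assert cons.n_bins_used == 6

    def test_two_bin_sample_sd_oracle(self, cfg):
        # bin 0: 3/5 R = 60 %, bin 1: 4/5 R = 80 %; other bins empty
        tokens = list("RRRLL") + list("RRRRL")
        times = list(np.arange(5.0)) + list(600.0 + np.arange(5.0))
        cons = per_bin_consistency(seq_of(tokens, times), cfg)
        assert cons.mean_R_pct == pytest.approx(70.0)
        # frozen from the sample-SD (n-1) closed form: sd(60, 80) = sqrt(200)
        assert cons.cv_R_pct == pytest.approx(20.203050891043385)
        assert cons.n_bins_empty == 4

    def test_fewer_than_two_usable_bins_is_missing(self, cfg):
        cons = per_bin_consistency(seq_of("RRL", [1.0, 2.0, 3.0]), cfg)
        assert np.isnan(cons.mean_R_pct) and np.isnan(cons.cv_R_pct)

    def test_stationary_biased_fish_has_low_cv(self, cfg):
        # 100 turns per bin at a constant 70 % right bias: binomial SD per
        # bin is ~4.6 pct points, so CV across bins stays well under 15 %
        rng = np.random.default_rng(4)
        tokens = np.where(rng.random(600) < 0.7, "R", "L").astype("<U1")
        times = np.linspace(0.0, 3599.0, 600)
        cons = per_bin_consistency(seq_of(tokens, times), cfg)
        assert cons.cv_R_pct < 15.0


class TestClassification:
    @pytest.mark.parametrize(
        "bias_R, expected",
        [
            (60.0, "non_biased"),  # strict threshold: exactly 60 is not biased
            (60.1, "right_biased"),
            (39.9, "left_biased"),
            (40.0, "non_biased"),
            (50.0, "non_biased"),
        ],
    )
    def test_strict_threshold(self, bias_R, expected):
        assert classify_laterality(bias_R, 60.0) == expected

    def test_undefined_bias_is_unlabelled(self):
        assert classify_laterality(float("nan")) is None

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("LR"), min_size=1, max_size=120))
    def test_flipping_tokens_swaps_sided_labels(self, tokens):
        arr = np.array(tokens, dtype="<U1")
        flipped = np.where(arr == "L", "R", "L").astype("<U1")
        lab = classify_laterality(bias_percentage(arr, "R"))
        lab_f = classify_laterality(bias_percentage(flipped, "R"))
        swap = {"left_biased": "right_biased", "right_biased": "left_biased",
                "non_biased": "non_biased"}
        assert lab_f == swap[lab]


class TestCohortClassSummary:
    def test_single_right_biased_fish(self):
        out = cohort_class_summary(["right_biased"])
        assert out.set_index("label").loc["right_biased", "pct"] == 100.0

    def test_percentages_match_draws_exactly(self):
        labels = ["left_biased"] * 3 + ["non_biased"] * 5 + ["right_biased"] * 2
        out = cohort_class_summary(labels).set_index("label")
        assert out.loc["left_biased", "pct"] == pytest.approx(30.0)
        assert out.loc["non_biased", "pct"] == pytest.approx(50.0)
        assert out["count"].sum() == 10

    def test_no_included_subjects_is_error(self):
        with pytest.raises(ValueError, match="no included"):
            cohort_class_summary([])
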