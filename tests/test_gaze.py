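"""Saccade classification, ratio statistics, and planned contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prcmatch import (ContractError, DegenerateVarianceError, Fixation,
                      FramesGeometry, SaccadeCounts, UndefinedRatioError,
                      classify_saccades, interaction_contrast, ratio_summary,
                      simple_effect)
from prcmatch.gaze import (DEFAULT_GEOMETRY, analyze_gaze, counts_to_frame,
                           detect_fixations, fixations_from_frame,
                           read_fixations, write_fixations)

L = (250.0, 250.0)  # centre of left frame
R = (758.0, 250.0)  # centre of right frame
GAP = (504.0, 250.0)  # inside the 8 px gap
OUT = (2000.0, 2000.0)


def _fix(points, trial=1):
    return [Fixation(x, y, onset_ms=100.0 * i, duration_ms=50.0, trial_index=trial)
            for i, (x, y) in enumerate(points)]


class TestClassify:
    @pytest.mark.parametrize("points,w,b", [
        ([L, R, L, R], 0, 3),            # alternating: every saccade crosses
        ([L, L, L, R], 2, 1),
        ([L], 0, 0),                      # single fixation
        ([], 0, 0),                       # empty trial marker, not an error
        ([L, GAP, R], 0, 0),              # gap fixations excluded by default
        ([L, OUT, L, L], 1, 0),           # out-of-frame pair dropped from T
    ])
    def test_examples(self, points, w, b):
        c = classify_saccades(_fix(points))
        assert (c.W, c.B, c.T) == (w, b, w + b)

    def test_nearest_policy_keeps_gap_fixations(self):
        c = classify_saccades(_fix([L, GAP, R]), out_of_frame="nearest")
        # the gap point is nearer the right frame: L->gap crosses, gap->R stays
        assert (c.W, c.B, c.T) == (1, 1, 2)

    def test_frame_boundaries_inclusive(self):
        g = DEFAULT_GEOMETRY
        assert g.which_frame(0.0, 0.0) == 0
        assert g.which_frame(500.0, 500.0) == 0
        assert g.which_frame(508.0, 0.0) == 1
        assert g.which_frame(504.0, 250.0) is None
        assert g.which_frame(250.0, 501.0) is None

    def test_matches_bruteforce_enumeration(self):
        """Classification equals independent pair-by-pair enumeration."""
        rng = np.random.default_rng(99)
        geom = FramesGeometry()
        for _ in range(300):
            n = int(rng.integers(0, 15))
            pts = np.column_stack([rng.uniform(-100, 1200, n),
                                   rng.uniform(-100, 600, n)])
            fixes = _fix(map(tuple, pts))
            c = classify_saccades(fixes)
            # oracle: direct enumeration with inline geometry
            def frame_of(x, y):
                if not 0 <= y <= 500:
                    return None
                if 0 <= x <= 500:
                    return 0
                if 508 <= x <= 1008:
                    return 1
                return None
            w = b = 0
            for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
                f1, f2 = frame_of(x1, y1), frame_of(x2, y2)
                if f1 is None or f2 is None:
                    continue
                if f1 == f2:
                    w += 1
                else:
                    b += 1
            assert (c.W, c.B, c.T) == (w, b, w + b)


class TestRatioSummary:
    @pytest.mark.parametrize("counts,wt,bt,ratio", [
        ([(2, 2, 4), (3, 3, 6)], 0.5, 0.5, 1.0),
        ([(4, 1, 5), (1, 4, 5)], 0.5, 0.5, 1.0),
        ([(3, 1, 4), (1, 1, 2)], 0.625, 0.375, 0.625 / 0.375),
    ])
    def test_hand_arithmetic(self, counts, wt, bt, ratio):
        s = ratio_summary([SaccadeCounts(*c, trial_index=i)
                           for i, c in enumerate(counts)])
        assert s.within_total_avg == pytest.approx(wt)
        assert s.between_total_avg == pytest.approx(bt)
        assert s.within_between == pytest.approx(ratio)

    def test_all_within_raises_undefined_ratio(self):
        with pytest.raises(UndefinedRatioError) as ei:
            ratio_summary([SaccadeCounts(3, 0, 3)])
        assert ei.value.within_total_avg == 1.0
        assert ei.value.between_total_avg == 0.0

    def test_empty_or_all_zero_trials_rejected(self):
        with pytest.raises(ContractError):
            ratio_summary([])
        with pytest.raises(ContractError):
            ratio_summary([SaccadeCounts(0, 0, 0)])

    def test_zero_count_trials_skipped(self):
        s = ratio_summary([SaccadeCounts(0, 0, 0), SaccadeCounts(1, 1, 2)])
        assert s.n_trials_used == 1

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(1, 20)),
                    min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_averages_sum_to_one_and_order_invariant(self, wb):
        counts = [SaccadeCounts(w, b, w + b) for w, b in wb if w + b > 0]
        if not any(c.B for c in counts) or not counts:
            return
        s1 = ratio_summary(counts)
        assert s1.within_total_avg + s1.between_total_avg == pytest.approx(1.0)
        s2 = ratio_summary(list(reversed(counts)))
        assert s2.within_between == pytest.approx(s1.within_between)


class TestContrasts:
    CONDS = ("high_ambiguity", "low_ambiguity", "difficult_size", "easy_size")

    def test_null_contrast_gives_t_zero_p_half(self):
        vals = {"high_ambiguity": [1, 2, 3], "low_ambiguity": [1, 2, 3],
                "difficult_size": [4, 5, 6], "easy_size": [4, 5, 6]}
        res = interaction_contrast(vals)
        assert res.t == 0.0
        assert res.p == 0.5

    def test_df_is_n_minus_one(self, rng):
        vals = {c: rng.normal(size=16) for c in self.CONDS}
        assert interaction_contrast(vals).df == 15

    def test_zero_variance_nonzero_mean_raises(self):
        vals = {"high_ambiguity": [2, 2, 2], "low_ambiguity": [1, 1, 1],
                "difficult_size": [0, 0, 0], "easy_size": [0, 0, 0]}
        with pytest.raises(DegenerateVarianceError):
            interaction_contrast(vals)

    def test_missing_condition_rejected(self, rng):
        vals = {c: rng.normal(size=8) for c in self.CONDS[:3]}
        with pytest.raises(ContractError):
            interaction_contrast(vals)

    def test_matches_scipy_one_sample(self, rng):
        vals = {c: rng.normal(size=12) for c in self.CONDS}
        contrast = ((np.asarray(vals["high_ambiguity"])
                     - np.asarray(vals["low_ambiguity"]))
                    - (np.asarray(vals["difficult_size"])
                       - np.asarray(vals["easy_size"])))
        expect = stats.ttest_1samp(contrast, 0.0)
        res = interaction_contrast(vals, tail="two")
        assert res.t == pytest.approx(expect.statistic)
        assert res.p == pytest.approx(expect.pvalue)

    def test_simple_effect_paired(self, rng):
        a, b = rng.normal(size=16), rng.normal(size=16)
        res = simple_effect(a, b, tail="two")
        expect = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(expect.statistic)
        assert res.p == pytest.approx(expect.pvalue)
        assert res.df == 15

    def test_simple_effect_edge_cases(self):
        res = simple_effect([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0  # identical vectors
        with pytest.raises(DegenerateVarianceError):
            simple_effect([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])  # constant shift
        with pytest.raises(ContractError):
            simple_effect([1.0], [2.0])


class TestTables:
    def test_fixation_table_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "trial_index": [1, 1, 2], "x_px": [10.0, 600.0, 20.0],
            "y_px": [10.0, 20.0, 30.0], "onset_ms": [0.0, 100.0, 0.0],
            "duration_ms": [90.0, 80.0, 70.0]})
        p = tmp_path / "fix.csv"
        write_fixations(df, p)
        back = read_fixations(p)
        pd.testing.assert_frame_equal(back.reset_index(drop=True), df)

    def test_reader_accepts_tabs_and_validates(self, tmp_path):
        p = tmp_path / "fix.tsv"
        p.write_text("trial_index\tx_px\ty_px\tonset_ms\tduration_ms\n"
                     "1\t10\t10\t0\t100\n")
        assert len(read_fixations(p)) == 1
        bad = tmp_path / "bad.csv"
        bad.write_text("trial,x,y\n1,2,3\n")
        with pytest.raises(ContractError):
            read_fixations(bad)

    def test_analyze_gaze_nonmatch_filter(self, exp3_high_ambiguity):
        # two fixations inside the left frame for every trial
        rows = []
        for t in exp3_high_ambiguity.trials:
            rows += [(t.trial_index, 100.0, 100.0, 0.0, 100.0),
                     (t.trial_index, 700.0, 100.0, 150.0, 100.0)]
        df = pd.DataFrame(rows, columns=["trial_index", "x_px", "y_px",
                                         "onset_ms", "duration_ms"])
        counts, summary = analyze_gaze(df, exp3_high_ambiguity,
                                       trials="nonmatch")
        assert len(counts) == 36
        assert summary.between_total_avg == 1.0
        counts_all, _ = analyze_gaze(df, exp3_high_ambiguity, trials="all")
        assert len(counts_all) == 72
        with pytest.raises(ContractError):
            analyze_gaze(df, None, trials="nonmatch")
        assert set(counts_to_frame(counts).columns) == {"trial_index", "W",
                                                        "B", "T"}

    def test_fixations_from_frame_orders_by_onset(self):
        df = pd.DataFrame({
            "trial_index": [1, 1], "x_px": [1.0, 2.0], "y_px": [1.0, 2.0],
            "onset_ms": [200.0, 0.0], "duration_ms": [50.0, 50.0]})
        fixes = fixations_from_frame(df)[1]
        assert [f.onset_ms for f in fixes] == [0.0, 200.0]


class TestDetector:
    def test_two_fixations_with_fast_jump(self):
        t = np.arange(0, 400, 2.0)
        x = np.where(t < 200, 100.0, 800.0)
        x[100] = 450.0  # single transition sample -> high velocity
        samples = pd.DataFrame({"t_ms": t, "x_px": x,
                                "y_px": np.full_like(t, 250.0)})
        fixes = detect_fixations(samples, velocity_threshold_px_per_ms=5.0)
        assert len(fixes) == 2
        assert fixes[0].x_px == pytest.approx(100.0)
        assert fixes[1].x_px == pytest.approx(800.0)
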