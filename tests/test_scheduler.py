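"""Schedule construction: counts, counterbalancing, uniqueness, round trips."""

import numpy as np
import pytest

from prcmatch import (ConfigurationError, ContractError, FeaturePools,
                      PoolDepletionError, build_condition_schedule,
                      build_experiment_schedules, comparison_trial_indices,
                      counterbalance_report, generate_object_trial,
                      generate_size_trial)
from prcmatch.scheduler import (HIGH_AMBIGUITY, LOW_AMBIGUITY, FILLER,
                                ObjectStimulusSpec, every_third_indices,
                                read_schedule_csv, read_schedule_json,
                                unique_shape_ids, write_schedule_csv,
                                write_schedule_json)


def _hamming(trial):
    a, b = trial.stimuli
    return sum(x != y for x, y in zip(a.features, b.features))


class TestObjectTrials:
    @pytest.mark.parametrize("condition,is_match,expected_hamming", [
        (HIGH_AMBIGUITY, False, 1),
        (HIGH_AMBIGUITY, True, 0),
        (LOW_AMBIGUITY, False, 3),
        (LOW_AMBIGUITY, True, 0),
        (FILLER, False, 3),
    ])
    def test_feature_hamming_distance(self, rng, condition, is_match,
                                      expected_hamming):
        pools = FeaturePools()
        for _ in range(20):
            t = generate_object_trial(condition, is_match, pools, rng)
            assert _hamming(t) == expected_hamming

    def test_rotations_within_range_and_independent(self, rng):
        pools = FeaturePools()
        rotations = []
        for _ in range(50):
            t = generate_object_trial(HIGH_AMBIGUITY, True, pools, rng)
            for s in t.stimuli:
                assert 15.0 <= s.rotation_deg <= 165.0
            rotations.append(t.stimuli[0].rotation_deg
                             == t.stimuli[1].rotation_deg)
        assert not all(rotations)  # match trials redraw rotation per object

    def test_frames_opposite(self, rng):
        t = generate_object_trial(LOW_AMBIGUITY, False, FeaturePools(), rng)
        assert {s.frame_side for s in t.stimuli} == {"left", "right"}

    def test_pool_depletion_raises(self, rng):
        pools = FeaturePools(capacity=3)
        generate_object_trial(HIGH_AMBIGUITY, True, pools, rng)  # uses 2
        with pytest.raises(PoolDepletionError):
            generate_object_trial(LOW_AMBIGUITY, False, pools, rng)

    def test_filler_namespace_disjoint(self, rng):
        pools = FeaturePools()
        obj = generate_object_trial(HIGH_AMBIGUITY, False, pools, rng)
        fil = generate_object_trial(FILLER, False, pools, rng)
        obj_ids = {s.inner_shape_id for s in obj.stimuli}
        obj_ids |= {s.outer_shape_id for s in obj.stimuli}
        fil_ids = {s.inner_shape_id for s in fil.stimuli}
        fil_ids |= {s.outer_shape_id for s in fil.stimuli}
        assert not obj_ids & fil_ids
        assert all(s.fill_id >= 100 for s in fil.stimuli)


class TestSizeTrials:
    def test_difficult_nonmatch_bounds(self, rng):
        for _ in range(200):
            t = generate_size_trial("difficult", False, rng)
            s1, s2 = t.stimuli
            assert 67 <= s1.side_px <= 247 and 67 <= s2.side_px <= 247
            assert 9 <= abs(s1.side_px - s2.side_px) <= 15

    def test_easy_match_equal_sides(self, rng):
        for _ in range(20):
            t = generate_size_trial("easy", True, rng)
            assert t.stimuli[0].side_px == t.stimuli[1].side_px
            assert 40 <= t.stimuli[0].side_px <= 268

    def test_difficult_delta_support_exhaustive(self):
        # 10,000 sampled trials cover the integer support {9..15} exactly
        rng = np.random.default_rng(7)
        deltas = {
            abs(t.stimuli[0].side_px - t.stimuli[1].side_px)
            for t in (generate_size_trial("difficult", False, rng)
                      for _ in range(10_000))
        }
        assert deltas == set(range(9, 16))

    def test_jitter_misaligns_edges(self, rng):
        for _ in range(50):
            t = generate_size_trial("easy", False, rng)
            s1, s2 = t.stimuli
            assert s1.jitter_x != s2.jitter_x
            assert s1.jitter_y != s2.jitter_y


class TestScheduleCounts:
    @pytest.mark.parametrize("experiment", ["exp1", "exp3"])
    @pytest.mark.parametrize("condition", ["high_ambiguity", "low_ambiguity",
                                           "difficult_size", "easy_size"])
    def test_basic_block_72_trials(self, experiment, condition):
        sched = build_condition_schedule(experiment, condition, 5)
        assert len(sched.trials) == 72
        assert sum(t.is_match for t in sched.trials) == 36
        assert sum(not t.is_match for t in sched.trials) == 36

    def test_exp4_high_interference_counts(self, exp4_high_interference):
        trials = exp4_high_interference.trials
        assert len(trials) == 88
        assert sum(t.is_match for t in trials) == 44
        assert all(t.condition == HIGH_AMBIGUITY for t in trials)

    def test_exp4_low_interference_structure(self, exp4_low_interference):
        trials = exp4_low_interference.trials
        assert len(trials) == 88
        comp = [t for t in trials if t.condition == HIGH_AMBIGUITY]
        fill = [t for t in trials if t.condition == FILLER]
        assert len(comp) == 30
        assert sum(t.is_match for t in comp) == 15
        assert len(fill) == 58
        assert sum(t.is_match for t in fill) == 29
        # repeating [comparison, filler, filler] pattern
        for t in trials:
            expected = HIGH_AMBIGUITY if t.trial_index % 3 == 1 else FILLER
            assert t.condition == expected

    def test_fmri_miniblocks(self):
        sched = build_condition_schedule("fmri", "high_ambiguity", 11)
        trials = sched.trials
        assert len(trials) == 108
        assert sum(not t.is_match for t in trials) == 72
        blocks = {}
        for t in trials:
            blocks.setdefault(t.miniblock, []).append(t)
        assert len(blocks) == 36
        for mb in blocks.values():
            assert len(mb) == 3
            assert sum(not t.is_match for t in mb) >= 1
        sessions = {t.session for t in trials}
        assert sessions == {1, 2, 3, 4}
        for s in sessions:
            assert sum(t.session == s for t in trials) == 27

    def test_count_invariants_hold_over_many_seeds(self):
        for seed in range(100):
            hi = build_condition_schedule("exp4", "high_interference", seed)
            lo = build_condition_schedule("exp4", "low_interference", seed)
            assert sum(t.is_match for t in hi.trials) == 44
            comp = [t for t in lo.trials if t.is_comparison]
            assert len(comp) == 30
            assert sum(t.is_match for t in comp) == 15
            fm = build_condition_schedule("fmri", "easy_size", seed)
            nm = {}
            for t in fm.trials:
                nm[t.miniblock] = nm.get(t.miniblock, 0) + (not t.is_match)
            assert all(v >= 1 for v in nm.values())

    def test_unknown_experiment_or_condition(self):
        with pytest.raises(ConfigurationError):
            build_condition_schedule("exp9", "high_ambiguity", 0)
        with pytest.raises(ConfigurationError):
            build_condition_schedule("exp4", "easy_size", 0)


class TestComparisonTrials:
    def test_every_third_positions(self):
        assert every_third_indices(6) == [1, 4]
        assert every_third_indices(88) == list(range(1, 89, 3))

    def test_both_exp4_variants_share_30_positions(
            self, exp4_high_interference, exp4_low_interference):
        hi = comparison_trial_indices(exp4_high_interference)
        lo = comparison_trial_indices(exp4_low_interference)
        assert hi == lo
        assert len(hi) == 30

    def test_low_interference_comparisons_are_high_ambiguity(
            self, exp4_low_interference):
        idx = set(comparison_trial_indices(exp4_low_interference))
        for t in exp4_low_interference.trials:
            if t.trial_index in idx:
                assert t.condition == HIGH_AMBIGUITY and t.is_comparison

    def test_wrong_experiment_rejected(self, exp3_high_ambiguity):
        with pytest.raises(ContractError):
            comparison_trial_indices(exp3_high_ambiguity)


class TestCounterbalance:
    def test_exp3_balanced_exactly(self, exp3_high_ambiguity):
        counts = counterbalance_report(exp3_high_ambiguity)
        assert counts == {"inner": 12, "outer": 12, "fill": 12}

    def test_exp4_high_within_one(self, exp4_high_interference):
        counts = counterbalance_report(exp4_high_interference)
        assert sum(counts.values()) == 44
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_empty_schedule_all_zero(self):
        assert counterbalance_report([]) == {"inner": 0, "outer": 0,
                                             "fill": 0}


class TestUniquenessAndDeterminism:
    def test_shape_ids_unique_across_experiment(self):
        scheds = build_experiment_schedules("exp3", 9)
        assert unique_shape_ids(scheds.values())
        seen = set()
        for sched in scheds.values():
            for t in sched.trials:
                for s in t.stimuli:
                    if isinstance(s, ObjectStimulusSpec):
                        seen.update((s.inner_shape_id, s.outer_shape_id))
        assert len(seen) > 200  # many distinct ids actually consumed

    def test_same_seed_byte_identical_files(self, tmp_path):
        for ext, writer in (("csv", write_schedule_csv),
                            ("json", write_schedule_json)):
            paths = []
            for i in (1, 2):
                sched = build_condition_schedule("exp4", "low_interference", 17)
                p = tmp_path / f"s{i}.{ext}"
                writer(sched, p)
                paths.append(p.read_bytes())
            assert paths[0] == paths[1]

    def test_csv_round_trip_lossless(self, tmp_path, exp4_low_interference):
        p = tmp_path / "sched.csv"
        write_schedule_csv(exp4_low_interference, p)
        back = read_schedule_csv(p)
        assert back.experiment == "exp4"
        assert back.seed == exp4_low_interference.seed
        assert back.trials == exp4_low_interference.trials

    def test_json_round_trip_lossless(self, tmp_path, exp3_high_ambiguity):
        p = tmp_path / "sched.json"
        write_schedule_json(exp3_high_ambiguity, p)
        back = read_schedule_json(p)
        assert back == exp3_high_ambiguity
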