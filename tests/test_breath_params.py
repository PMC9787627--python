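"""Breath events, debounce, cycle timing, window summaries, physiology."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffresp.breath_params import (
    EXHALATION,
    INHALATION,
    BreathEvent,
    BreathTrackerState,
    SubjectProfile,
    alignment_check,
    collapse_runs,
    debounce_exhalations,
    finalize_window,
    ideal_body_weight,
    tidal_volume,
    track_breaths,
    update_cycle_times,
)
from diffresp.config import PipelineConfig

BOUNDS = (0.4, 8.0)


class TestCollapseRuns:
    def test_single_run_collapses_to_onset(self):
        labels = np.array([0, 0, -1, -1, -1, 0])
        t = np.arange(6) * 0.05
        events = collapse_runs(labels, t)
        assert events == [BreathEvent(t=0.10, kind=EXHALATION)]

    def test_all_zeros_empty(self):
        assert collapse_runs(np.zeros(10), np.arange(10) * 0.1) == []

    def test_alternating_single_sample_runs(self):
        labels = np.array([1, -1, 1])
        events = collapse_runs(labels, np.array([0.0, 0.1, 0.2]))
        assert [e.kind for e in events] == [INHALATION, EXHALATION, INHALATION]
        assert [e.t for e in events] == [0.0, 0.1, 0.2]

    def test_adjacent_opposite_runs_both_reported(self):
        labels = np.array([0, 1, 1, -1, -1, 0])
        events = collapse_runs(labels, np.arange(6) * 1.0)
        assert [(e.t, e.kind) for e in events] == [(1.0, 1), (3.0, -1)]


class TestDebounce:
    def test_close_exhalation_discarded_without_moving_reference(self):
        events = [BreathEvent(t, EXHALATION) for t in (0.0, 0.5, 2.0)]
        kept, np_count = debounce_exhalations(events, t_min=1.1)
        assert np_count == 2
        assert [e.t for e in kept] == [0.0, 2.0]

    def test_single_exhalation_counts(self):
        kept, np_count = debounce_exhalations([BreathEvent(3.0, EXHALATION)], 1.1)
        assert np_count == 1 and len(kept) == 1

    def test_regular_train_above_threshold_all_kept(self):
        times = [1.2 * k for k in range(25)]  # every 1.2 s for 30 s
        events = [BreathEvent(t, EXHALATION) for t in times]
        kept, np_count = debounce_exhalations(events, t_min=1.0)
        # enumeration oracle: all gaps are 1.2 > 1.0, none discarded
        expected = sum(1 for _ in times)
        assert np_count == expected == len(kept)

    def test_inhalations_pass_through(self):
        events = [
            BreathEvent(0.0, EXHALATION),
            BreathEvent(0.2, INHALATION),
            BreathEvent(0.5, EXHALATION),
        ]
        kept, np_count = debounce_exhalations(events, t_min=1.1)
        assert np_count == 1
        assert [e.kind for e in kept] == [EXHALATION, INHALATION]


class TestUpdateCycleTimes:
    def test_ti_from_inhalation_then_exhalation(self):
        state = BreathTrackerState()
        update_cycle_times(state, BreathEvent(10.0, INHALATION), BOUNDS, BOUNDS)
        update_cycle_times(state, BreathEvent(11.5, EXHALATION), BOUNDS, BOUNDS)
        assert state.TI_count == 1
        assert state.TI_sum == pytest.approx(1.5)

    def test_te_from_exhalation_then_inhalation(self):
        state = BreathTrackerState()
        update_cycle_times(state, BreathEvent(11.5, EXHALATION), BOUNDS, BOUNDS)
        update_cycle_times(state, BreathEvent(12.3, INHALATION), BOUNDS, BOUNDS)
        assert state.TE_count == 1
        assert state.TE_sum == pytest.approx(0.8)

    def test_implausible_candidate_rejected(self):
        state = BreathTrackerState()
        update_cycle_times(state, BreathEvent(0.0, INHALATION), BOUNDS, BOUNDS)
        update_cycle_times(state, BreathEvent(12.0, EXHALATION), BOUNDS, BOUNDS)
        assert state.TI_count == 0 and state.TI_sum == 0.0

    def test_out_of_order_event_rejected_and_counted(self):
        state = BreathTrackerState()
        update_cycle_times(state, BreathEvent(5.0, INHALATION), BOUNDS, BOUNDS)
        update_cycle_times(state, BreathEvent(4.0, EXHALATION), BOUNDS, BOUNDS)
        assert state.rejected_events == 1
        assert state.TI_count == 0


class TestFinalizeWindow:
    def test_rr_from_peak_count(self):
        config = PipelineConfig()
        state = BreathTrackerState()
        state.NP = 13
        summary = finalize_window(state, config, vt_liters=None)
        assert summary.RR == pytest.approx(26.0)

    def test_hand_arithmetic_of_window_formulas(self):
        config = PipelineConfig()
        state = BreathTrackerState()
        state.NP = 12
        state.TI_sum, state.TI_count = 14.4, 12
        state.TE_sum, state.TE_count = 9.6, 12
        s = finalize_window(state, config, vt_liters=0.5)
        assert s.TI_med == pytest.approx(1.2)
        assert s.TE_med == pytest.approx(0.8)
        assert s.IER == pytest.approx(1.5)
        assert s.V == pytest.approx(25.0)  # 0.5 L * 60 / 1.2 s

    def test_empty_window_flags_undefined(self):
        config = PipelineConfig()
        state = BreathTrackerState()
        s = finalize_window(state, config, vt_liters=0.5)
        assert s.RR == 0.0 and s.NP == 0
        assert s.TI_med is None and s.TE_med is None
        assert s.IER is None and s.V is None

    def test_state_reset_advances_window(self):
        config = PipelineConfig()
        state = BreathTrackerState(start_time=30.0)
        state.NP, state.TI_sum, state.TI_count = 5, 6.0, 5
        finalize_window(state, config, None)
        assert state.start_time == 60.0
        assert state.NP == 0 and state.TI_count == 0 and state.TI_sum == 0.0


class TestTrackBreaths:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(st.floats(min_value=1.05, max_value=6.0), min_size=1, max_size=60)
    )
    def test_rr_always_even_integer_at_tw_30(self, gaps):
        t = np.cumsum(gaps)
        events = [BreathEvent(float(ti), EXHALATION) for ti in t]
        config = PipelineConfig()
        summaries, _ = track_breaths(events, t_end=float(t[-1]) + 1, config=config)
        for s in summaries:
            assert s.RR == 2 * s.NP
            assert float(s.RR).is_integer()

    def test_np_equals_bruteforce_recount(self, rng):
        times = np.unique(np.round(np.cumsum(rng.uniform(0.3, 4.0, 60)), 3))
        events = [BreathEvent(float(t), EXHALATION) for t in times]
        kept, np_total = debounce_exhalations(events, t_min=1.0)
        config = PipelineConfig()
        summaries, _ = track_breaths(kept, t_end=float(times[-1]) + 1, config=config)
        for s in summaries:
            brute = sum(
                1 for e in kept
                if e.kind == EXHALATION
                and s.window_start <= e.t < s.window_start + s.tw
            )
            assert s.NP == brute
        assert np_total == sum(1 for e in kept if e.kind == EXHALATION)

    def test_defined_medians_respect_bounds(self, rng):
        # random alternating inhale/exhale events with a mix of plausible
        # and implausible gaps
        t, kind, events = 0.0, INHALATION, []
        for _ in range(200):
            t += float(rng.uniform(0.05, 5.0))
            events.append(BreathEvent(t, kind))
            kind = -kind
        config = PipelineConfig()
        summaries, _ = track_breaths(events, t_end=t + 1, config=config)
        for s in summaries:
            if s.TI_med is not None:
                assert config.ti_bounds[0] <= s.TI_med <= config.ti_bounds[1]
            if s.TE_med is not None:
                assert config.te_bounds[0] <= s.TE_med <= config.te_bounds[1]
            if s.IER is not None:
                assert s.IER > 0


class TestPhysiologyFormulas:
    @pytest.mark.parametrize(
        "height,sex,expected",
        [
            (152.4, "male", 50.0),
            (152.4, "female", 45.5),
            (182.0, "male", 76.936),
            (182.0, "female", 72.436),
        ],
    )
    def test_ideal_body_weight(self, height, sex, expected):
        assert ideal_body_weight(height, sex) == pytest.approx(expected)

    def test_ibw_clamped_at_zero_for_tiny_heights(self):
        with pytest.warns(UserWarning):
            assert ideal_body_weight(30.0, "female") == 0.0

    def test_ibw_rejects_unknown_sex(self):
        with pytest.raises(ValueError):
            ideal_body_weight(170.0, "other")

    @pytest.mark.parametrize("ibw,expected", [(50.0, 350.0), (0.0, 0.0), (76.936, 538.552)])
    def test_tidal_volume(self, ibw, expected):
        assert tidal_volume(ibw) == pytest.approx(expected)

    def test_subject_profile_vt_liters(self):
        subject = SubjectProfile(sex="male", height_cm=182.0, weight_kg=78.0)
        assert subject.tidal_volume_liters == pytest.approx(0.538552)


class TestAlignmentCheck:
    def test_zero_signal_is_aligned(self):
        assert alignment_check(np.zeros(100), tol=0.01)

    def test_large_offset_is_misaligned(self):
        assert not alignment_check(np.full(100, 0.3), tol=0.05)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            alignment_check(np.array([]), tol=0.05)

    def test_separates_aligned_from_misaligned_simulation(self):
        # calibration: still, breath held; misaligned back sensor = 10°
        # rotation seen through per-axis gain imperfection
        from diffresp.signal_core import build_diff_signal
        from diffresp.synthgen import ScenarioSpec, simulate_dual_imu

        common = dict(
            condition="seated", duration=35.0, seed=21, cycles=(),
            motion_amplitude=0.0, cardiac_amplitude=0.0,
        )
        aligned = ScenarioSpec(**common)
        misaligned = ScenarioSpec(
            **common, back_tilt_deg=10.0, back_gain=(1.0, 1.0, 0.96)
        )
        levels = {}
        for name, spec in (("ok", aligned), ("bad", misaligned)):
            front, back, _ = simulate_dual_imu(spec)
            diff, _ = build_diff_signal(front, back, fs=spec.fs)
            levels[name] = float(np.mean(np.abs(diff.da)))
        tol = 0.5 * (levels["ok"] + levels["bad"])
        assert levels["ok"] < levels["bad"]
        front, back, _ = simulate_dual_imu(aligned)
        diff, _ = build_diff_signal(front, back, fs=aligned.fs)
        assert alignment_check(diff.da, tol)
        front, back, _ = simulate_dual_imu(misaligned)
        diff, _ = build_diff_signal(front, back, fs=misaligned.fs)
        assert not alignment_check(diff.da, tol)
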