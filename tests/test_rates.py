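"""Rate metrics: window BPM conventions, pooling identities, interval
features, and smoothed group rate conservation."""

import numpy as np
import pytest

from blinkengage.rates import (
    bpm,
    instantaneous_rate,
    interval_vector,
    scene_rates,
)
from blinkengage.synth import (
    CohortParams,
    ParticipantProfile,
    make_schedules,
    simulate_blinks,
    simulate_cohort,
)
from blinkengage.types import (
    BlinkEvent,
    GROUP_LAND,
    GROUP_WATER,
    ParticipantRecord,
    RateProfile,
    ValidationError,
    expected_profile_length,
)

from conftest import make_events, two_scene_schedule


class TestBpm:
    def test_three_blinks_in_half_minute(self):
        assert bpm(make_events([1, 2, 3]), [(0.0, 30.0)]) == 6.0

    def test_zero_blinks(self):
        assert bpm([], [(0.0, 30.0)]) == 0.0

    def test_onset_at_window_end_not_counted(self):
        assert bpm(make_events([30.0]), [(0.0, 30.0)]) == 0.0
        assert bpm(make_events([0.0]), [(0.0, 30.0)]) == 2.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValidationError, match="exposure"):
            bpm([], [])

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            bpm([], [(0.0, 10.0), (5.0, 15.0)])

    def test_pooled_rate_is_count_over_time_not_mean_of_rates(self):
        # 6 blinks in a 60 s window, 0 in a 30 s window: pooled = 4 bpm,
        # mean of per-window rates would be 3 bpm
        events = make_events(np.linspace(1, 50, 6))
        windows = [(0.0, 60.0), (60.0, 90.0)]
        assert bpm(events, windows) == pytest.approx(4.0)


class TestSceneRates:
    def test_category_rates_and_metric(self):
        sched = two_scene_schedule()  # land 0-60, water 60-120
        rec = ParticipantRecord(
            "P01", GROUP_LAND, "attended_odd",
            events={"v": make_events([10, 30, 70, 80, 90, 100])},
        )
        r = scene_rates(rec, {"v": sched})
        assert r.bpm_land == pytest.approx(2.0)
        assert r.bpm_water == pytest.approx(4.0)
        assert r.metric == pytest.approx(-2.0)
        assert r.bpm_session == pytest.approx(3.0)

    def test_relevant_relabeling_by_group(self):
        sched = two_scene_schedule()
        events = {"v": make_events([10, 70, 80])}
        land_rec = ParticipantRecord("A", GROUP_LAND, "attended_odd", events=dict(events))
        water_rec = ParticipantRecord("B", GROUP_WATER, "attended_even", events=dict(events))
        ra = scene_rates(land_rec, {"v": sched})
        rb = scene_rates(water_rec, {"v": sched})
        assert ra.bpm_relevant == ra.bpm_land and ra.bpm_irrelevant == ra.bpm_water
        assert rb.bpm_relevant == rb.bpm_water and rb.bpm_irrelevant == rb.bpm_land

    def test_symmetric_streams_zero_metric(self):
        sched = two_scene_schedule()
        rec = ParticipantRecord(
            "P01", GROUP_LAND, "attended_odd",
            events={"v": make_events([10, 20, 70, 80])},
        )
        assert scene_rates(rec, {"v": sched}).metric == 0.0

    def test_missing_schedule_rejected(self):
        rec = ParticipantRecord(
            "P01", GROUP_LAND, "attended_odd", events={"v?": make_events([1])}
        )
        with pytest.raises(ValidationError, match="schedule"):
            scene_rates(rec, {})

    def test_simulated_participant_suppressed(self):
        """Sign-reversal probability is Poisson-negligible at rho=0.5 with
        a full session of exposure."""
        records, schedules, _ = simulate_cohort(CohortParams(seed=5))
        for rec in records[:5]:
            r = scene_rates(rec, schedules)
            assert r.bpm_relevant < r.bpm_irrelevant


class TestIntervalVector:
    def _record(self, onsets, condition_s=5.0, duration=10.0):
        sched = two_scene_schedule(condition_s=condition_s)
        return (
            ParticipantRecord(
                "P01", GROUP_LAND, "attended_odd", events={"v": make_events(onsets)}
            ),
            {"v": sched},
        )

    def test_worked_example_two_bins(self):
        rec, scheds = self._record([1.0, 2.0, 7.0])  # 10 s video, interval 5
        profile = interval_vector(rec, scheds, 5.0)
        assert list(profile.values) == [24.0, 12.0]

    def test_interval_ten_on_120s_video(self):
        rec, scheds = self._record([], condition_s=60.0)
        assert len(interval_vector(rec, scheds, 10.0)) == 12

    def test_zero_events_zero_vector(self):
        rec, scheds = self._record([], condition_s=60.0)
        profile = interval_vector(rec, scheds, 7.0)
        assert len(profile) == expected_profile_length([120.0], 7.0) == 17
        assert np.all(profile.values == 0)

    def test_trailing_partial_bin_dropped(self):
        rec, scheds = self._record([9.5], condition_s=5.0)  # blink in partial bin
        profile = interval_vector(rec, scheds, 4.0)
        assert len(profile) == 2  # floor(10/4)
        assert np.all(profile.values == 0)

    def test_exposure_weighted_mean_equals_session_rate(self):
        """When no partial bins are dropped, the profile's mean equals the
        pooled session rate exactly."""
        records, schedules, _ = simulate_cohort(
            CohortParams(n_land=2, n_water=2, seed=3),
            target_duration_s=120.0,
            conditions=(5.0, 10.0),  # 120 s videos: no partial 5 s bins
        )
        for rec in records:
            profile = interval_vector(rec, schedules, 5.0)
            session = scene_rates(rec, schedules).bpm_session
            assert profile.values.mean() == pytest.approx(session, abs=1e-9)

    def test_videos_concatenated_in_condition_order(self):
        s1 = two_scene_schedule(condition_s=5.0, video_id="b_long")
        s2 = two_scene_schedule(condition_s=2.5, video_id="a_short")
        rec = ParticipantRecord(
            "P01", GROUP_LAND, "attended_odd",
            events={"b_long": make_events([0.5]), "a_short": []},
        )
        profile = interval_vector(rec, {"b_long": s1, "a_short": s2}, 5.0)
        # a_short (condition 2.5, one 5 s bin) comes first, then b_long
        assert list(profile.values) == [0.0, 12.0, 0.0]


class TestInstantaneousRate:
    def test_single_blink_mass_conserved(self):
        t, rate = instantaneous_rate([[BlinkEvent(30.0, 0.2)]], 60.0, bandwidth_s=1.0)
        blinks = np.sum(rate) / 30.0 / 60.0  # integral of bpm dt over minutes
        assert blinks == pytest.approx(1.0, abs=1e-9)

    def test_zero_events_zero_series(self):
        _, rate = instantaneous_rate([[], []], 10.0)
        assert np.all(rate == 0)

    def test_group_rate_lower_in_relevant_scenes(self):
        (sched,) = make_schedules(120.0, [5], "land")
        rng = np.random.default_rng(17)
        event_sets = []
        for k in range(30):
            prof = ParticipantProfile(
                f"P{k}", GROUP_LAND, "attended_odd", lambda_bpm=12.0, rho=0.5
            )
            event_sets.append(simulate_blinks(prof, sched, rng))
        t, rate = instantaneous_rate(event_sets, sched.duration_s, bandwidth_s=0.5)
        rel = np.zeros(len(t), dtype=bool)
        for start, end in sched.windows("land"):
            rel |= (t >= start) & (t < end)
        assert rate[rel].mean() < rate[~rel].mean()
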