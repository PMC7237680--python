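"""Generator behavior: schedule arithmetic, cohort calibration, blink-stream
rate targets, and pupil-trace rendering."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from blinkengage.rates import count_in_windows, scene_rates
from blinkengage.synth import (
    CohortParams,
    ParticipantProfile,
    calibrate_truncated_normal,
    make_schedules,
    make_schedule_sets,
    render_pupil_trace,
    sample_cohort,
    simulate_blinks,
    simulate_cohort,
)
from blinkengage.types import (
    CONDITIONS_S,
    GROUP_LAND,
    BlinkEvent,
    ValidationError,
    validate_event_list,
)

from conftest import make_events


class TestMakeSchedules:
    def test_single_sixty_second_condition(self):
        (s,) = make_schedules(120.0, [60], "land")
        assert [(sc.category, sc.onset_s, sc.offset_s) for sc in s.scenes] == [
            ("land", 0.0, 60.0),
            ("water", 60.0, 120.0),
        ]

    def test_one_second_scenes_water_first(self):
        (s,) = make_schedules(120.0, [1], "water")
        assert len(s.scenes) == 120
        assert s.scenes[0].category == "water"
        assert s.scenes[1].category == "land"
        assert s.duration_s == 120.0

    def test_even_rounding_drops_odd_scene(self):
        # floor(120/50) = 2 after even-rounding: two scenes, 100 s total
        (s,) = make_schedules(120.0, [50], "land")
        assert len(s.scenes) == 2
        assert s.duration_s == 100.0

    def test_condition_too_long_for_two_scenes(self):
        with pytest.raises(ValidationError, match="two scenes"):
            make_schedules(100.0, [60], "land")

    def test_default_set_fits_study_envelope(self):
        for sched in make_schedule_sets().values():
            sched.validate_duration_envelope()
        # both counterbalanced stimulus sets, all 13 conditions
        assert len(make_schedule_sets()) == 2 * len(CONDITIONS_S)

    def test_category_exposure_balanced(self):
        for sched in make_schedules(160.0, CONDITIONS_S, "water"):
            land = sum(e - s for s, e in sched.windows("land"))
            water = sum(e - s for s, e in sched.windows("water"))
            assert land == water


class TestSampleCohort:
    def test_default_rates_within_printed_range(self):
        profiles = sample_cohort(CohortParams(seed=1))
        assert len(profiles) == 21
        for p in profiles:
            assert 2.0 <= p.lambda_bpm <= 26.0

    def test_degenerate_sd_gives_constant_rates(self):
        profiles = sample_cohort(CohortParams(rate_sd_bpm=0.0, seed=1))
        assert all(p.lambda_bpm == 12.6 for p in profiles)

    def test_large_sample_mean_matches_calibration_target(self):
        params = CohortParams(n_land=5000, n_water=5000, seed=11)
        rates = np.array([p.lambda_bpm for p in sample_cohort(params)])
        assert abs(rates.mean() - 12.6) < 0.2
        assert abs(rates.std(ddof=1) - 6.7) < 0.2

    def test_calibrated_truncated_moments_by_numeric_integration(self):
        """Independent oracle: integrate the truncated density directly."""
        mu, sigma = calibrate_truncated_normal(12.6, 6.7, (2.0, 26.0))
        norm = stats.norm(mu, sigma)
        mass = norm.cdf(26.0) - norm.cdf(2.0)
        mean, _ = integrate.quad(lambda x: x * norm.pdf(x) / mass, 2.0, 26.0)
        ex2, _ = integrate.quad(lambda x: x * x * norm.pdf(x) / mass, 2.0, 26.0)
        assert abs(mean - 12.6) < 1e-6
        assert abs(math.sqrt(ex2 - mean**2) - 6.7) < 1e-6

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_truncated_normal(30.0, 6.7, (2.0, 26.0))  # mean outside
        with pytest.raises(ValidationError):
            calibrate_truncated_normal(12.6, 8.0, (2.0, 26.0))  # SD above cap

    def test_group_split_and_parity_counterbalancing(self):
        profiles = sample_cohort(CohortParams(seed=3))
        assert sum(p.group == GROUP_LAND for p in profiles) == 11
        assert sum(p.parity == "attended_odd" for p in profiles) == 11

    def test_reproducible_from_seed(self):
        a = sample_cohort(CohortParams(seed=9))
        b = sample_cohort(CohortParams(seed=9))
        assert a == b


class TestSimulateBlinks:
    """Realized-rate oracles: long-run event count / exposure time under the
    dead-time-compensated intensity."""

    @staticmethod
    def _realized_rates(rho, lam, n_videos, seed):
        prof = ParticipantProfile("X", GROUP_LAND, "attended_odd", lambda_bpm=lam, rho=rho)
        (sched,) = make_schedules(120.0, [60], "land")
        rng = np.random.default_rng(seed)
        rel = irr = 0
        for _ in range(n_videos):
            events = simulate_blinks(prof, sched, rng)
            rel += count_in_windows(events, sched.windows("land"))
            irr += count_in_windows(events, sched.windows("water"))
        minutes = n_videos * 1.0  # one minute per category per video
        return rel / minutes, irr / minutes, rel, irr

    def test_realized_rates_match_targets_at_half_suppression(self):
        rel_rate, irr_rate, rel, irr = self._realized_rates(0.5, 12.0, 5000, 11)
        assert abs(rel_rate - 6.0) <= 3 * math.sqrt(rel) / 5000
        assert abs(irr_rate - 18.0) <= 3 * math.sqrt(irr) / 5000

    def test_no_suppression_equalizes_categories(self):
        rel_rate, irr_rate, rel, irr = self._realized_rates(1.0, 12.0, 5000, 12)
        se = math.sqrt(rel + irr) / 5000
        assert abs(rel_rate - irr_rate) <= 3 * se

    def test_session_rate_is_rho_invariant_in_expectation(self):
        _, _, rel, irr = self._realized_rates(0.5, 12.0, 5000, 11)
        session = (rel + irr) / (2 * 5000)
        assert abs(session - 12.0) <= 3 * math.sqrt(rel + irr) / (2 * 5000)

    def test_events_sorted_nonoverlapping_within_video(self):
        prof = ParticipantProfile("X", GROUP_LAND, "attended_odd", lambda_bpm=25.0, rho=0.5)
        (sched,) = make_schedules(160.0, [5], "land")
        for seed in range(20):
            events = simulate_blinks(prof, sched, seed)
            validate_event_list(events)
            assert all(0 <= e.onset_s < sched.duration_s for e in events)

    def test_fixed_seed_reproducible(self):
        prof = ParticipantProfile("X", GROUP_LAND, "attended_odd", lambda_bpm=12.0, rho=0.5)
        (sched,) = make_schedules(120.0, [10], "land")
        assert simulate_blinks(prof, sched, 5) == simulate_blinks(prof, sched, 5)


def test_every_participant_suppressed_across_cohorts():
    """Task-consistent sign for all participants at the default suppression
    (the all-participants effect), across replicate cohorts."""
    for seed in range(25):
        records, schedules, _ = simulate_cohort(CohortParams(seed=1000 + seed))
        for rec in records:
            r = scene_rates(rec, schedules)
            assert r.bpm_relevant < r.bpm_irrelevant, rec.participant_id


class TestRenderPupilTrace:
    def test_no_events_no_noise_constant_and_valid(self):
        trace = render_pupil_trace([], 2.0, noise_sd=0.0)
        assert np.all(trace.valid)
        assert np.ptp(trace.diameter) == 0

    def test_single_blink_invalid_run_inside_blink_window(self):
        trace = render_pupil_trace(make_events([5.0], duration=0.3), 10.0, noise_sd=0.0)
        invalid = np.flatnonzero(~trace.valid)
        assert len(invalid) > 0
        assert np.all(np.diff(invalid) == 1)  # one contiguous run
        assert trace.t[invalid[0]] >= 5.0
        assert trace.t[invalid[-1]] <= 5.3

    def test_blink_past_trace_end_truncated_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            trace = render_pupil_trace(make_events([1.9], duration=0.3), 2.0)
        assert "truncated" in caplog.text
        assert len(trace) == 120

    def test_center_deflects_downward_during_blink(self):
        trace = render_pupil_trace(make_events([1.0], duration=0.3), 3.0, noise_sd=0.0)
        assert trace.center_y.min() < trace.center_y.max()
        occluded = trace.diameter < trace.diameter.max() / 2
        assert trace.center_y[occluded].mean() < trace.center_y[~occluded].mean()
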