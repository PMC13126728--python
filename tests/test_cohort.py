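"""Synthetic cohort presets, paired-panel generation, stress series."""

import numpy as np
import pytest

from openwindow import (
    generate_paired_panel,
    generate_stress_series,
    table_marker_presets,
    table_training_schedule,
)
from openwindow.cohort import MarkerSpec, StressSeries, TrainingSchedule, preset


class TestPresets:
    def test_eighteen_markers(self):
        specs = table_marker_presets()
        assert len(specs) == 18
        families = {s.marker: s.family for s in specs}
        assert families["IL-6"] == "lognormal"
        assert families["B cell"] == "truncated_normal"

    def test_transcribed_moments(self):
        assert preset("B cell").mean_pre == 263.19
        assert preset("CD3+CD4+ T cell").mean_post == 584.35
        assert preset("IL-10").sd_pre == 3.5390

    def test_post_sd_typo_rows_flagged_and_imputed(self):
        flagged = {s.marker for s in table_marker_presets() if s.sd_post_imputed}
        assert flagged == {"Monocyte", "Eosinophil", "Basophil"}
        # the impossible printed post-SDs (equal to the means) are replaced
        # by the pre-training SDs
        assert preset("Monocyte").sd_post == preset("Monocyte").sd_pre

    def test_byte_stable_across_calls(self):
        assert table_marker_presets() == table_marker_presets()

    def test_schedule_transcription(self):
        sched = table_training_schedule()
        assert len(sched) == 28
        assert sched.session(2, "Thu").bla_mean == 11.2  # all-out lactate tolerance
        assert sched.session(1, "Tue").hr_mean == 178
        training = [s for s in sched.sessions if s.is_training]
        assert len(training) == 22  # six slots carry no lactate value

    def test_severe_sessions_hit_lactate_floor(self):
        for s in table_training_schedule().sessions:
            if s.zone in ("Severe", "Extreme"):
                assert s.bla_mean >= 6.8

    def test_active_recovery_flag(self):
        sched = table_training_schedule(active_recovery_as_moderate=True)
        assert sched.session(1, "Sun").is_training
        assert len([s for s in sched.sessions if s.is_training]) == 23


class TestPairedPanelGeneration:
    def test_same_seed_identical(self):
        specs = table_marker_presets()
        a = generate_paired_panel(specs, n=22, seed=5)
        b = generate_paired_panel(specs, n=22, seed=5)
        np.testing.assert_array_equal(a.pre, b.pre)
        np.testing.assert_array_equal(a.post, b.post)

    def test_non_negative_values(self):
        panel = generate_paired_panel(table_marker_presets(), n=200, seed=1)
        assert (panel.pre >= 0).all() and (panel.post >= 0).all()

    @pytest.mark.parametrize("marker", ["Leukocyte", "IL-6", "CD3+CD4+ T cell"])
    def test_moment_recovery(self, marker):
        spec = preset(marker)
        panel = generate_paired_panel([spec], n=100_000, seed=3, add_cd4_cd8_ratio=False)
        pre, post = panel.column(marker)
        assert pre.mean() == pytest.approx(spec.mean_pre, rel=0.01)
        assert post.mean() == pytest.approx(spec.mean_post, rel=0.01)
        assert pre.std(ddof=1) == pytest.approx(spec.sd_pre, rel=0.02)
        assert post.std(ddof=1) == pytest.approx(spec.sd_post, rel=0.02)

    def test_intra_subject_correlation(self):
        spec = preset("CD3+CD4+ T cell")
        panel = generate_paired_panel([spec], n=10_000, seed=8, add_cd4_cd8_ratio=False)
        pre, post = panel.column(spec.marker)
        assert np.corrcoef(pre, post)[0, 1] == pytest.approx(0.85, abs=0.02)

    def test_near_perfect_correlation_limit(self):
        spec = MarkerSpec("x", 100.0, 10.0, 100.0, 10.0, pre_post_correlation=0.999)
        panel = generate_paired_panel([spec], n=2_000, seed=2, add_cd4_cd8_ratio=False)
        pre, post = panel.column("x")
        assert np.corrcoef(pre, post)[0, 1] > 0.99

    def test_zero_sd_gives_constant_columns(self):
        spec = MarkerSpec("x", 5.0, 0.0, 4.0, 0.0)
        panel = generate_paired_panel([spec], n=50, seed=1, add_cd4_cd8_ratio=False)
        pre, post = panel.column("x")
        assert np.all(pre == 5.0) and np.all(post == 4.0)

    def test_ratio_is_emergent_per_athlete(self):
        panel = generate_paired_panel(table_marker_presets(), n=500, seed=6)
        cd4_pre, cd4_post = panel.column("CD3+CD4+ T cell")
        cd8_pre, cd8_post = panel.column("CD3+CD8+ T cell")
        r_pre, r_post = panel.column("cd4_cd8_ratio")
        np.testing.assert_allclose(r_pre, cd4_pre / cd8_pre)
        np.testing.assert_allclose(r_post, cd4_post / cd8_post)
        # the cohort-level ratio means act as a calibration check: the
        # drawn cohort should invert from ~1.35 to below 1.0
        assert r_pre.mean() > 1.0 > r_post.mean()

    def test_too_few_athletes(self):
        with pytest.raises(ValueError):
            generate_paired_panel(table_marker_presets(), n=1, seed=0)


class TestStressSeries:
    def test_all_rest_schedule_is_silent(self):
        sched = TrainingSchedule(
            tuple(
                type(s)(s.week, s.day, "Rest", "Rest")
                for s in table_training_schedule().sessions
            )
        )
        series = generate_stress_series(sched, ticks_per_day=10, seed=0)
        assert np.all(series.lactate_injection == 0)
        assert np.all(series.glucose_drain == 0)
        assert series.pulse_days == 0

    def test_training_day_count_and_shape(self):
        series = generate_stress_series(table_training_schedule(), ticks_per_day=10, seed=1)
        assert len(series) == 280
        assert series.pulse_days == 22
        assert (series.lactate_injection >= 0).all()
        assert (series.glucose_drain >= 0).all()

    def test_deterministic(self):
        a = generate_stress_series(table_training_schedule(), seed=9)
        b = generate_stress_series(table_training_schedule(), seed=9)
        np.testing.assert_array_equal(a.lactate_injection, b.lactate_injection)

    def test_first_interval_session_pulse_amplitude(self):
        """Mean week-1 Tuesday pulse matches the session's lactate draw."""
        decay = 0.5 ** (1 / 3)
        amps = []
        for s in range(300):
            series = generate_stress_series(table_training_schedule(), seed=s)
            lac = series.lactate_injection
            # remove the decayed carry-over of Monday's pulse
            amps.append(lac[10] - lac[9] * decay)
        assert np.mean(amps) == pytest.approx(8.2, abs=0.2)

    def test_scaling_and_indexing(self):
        series = generate_stress_series(table_training_schedule(), seed=0)
        doubled = series.scaled(2.0)
        assert doubled.lactate_injection[10] == pytest.approx(2 * series.lactate_injection[10])
        assert series.at(10_000) == (0.0, 0.0)  # past the end

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            TrainingSchedule(())
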