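"""Generator contracts: rate profiles, trial structure, determinism,
laterality and count conservation."""

import numpy as np
import pytest

from dcnlearn import features as ft
from dcnlearn import sigproc
from dcnlearn import synthgen as sg

SEED = 7


def cond(stim: sg.StimulusType, limb: sg.Limb = sg.Limb.LEFT_FORE):
    return sg.StimulusCondition(stim, limb)


class TestConditionsAndSchedule:
    def test_sixteen_distinct_conditions(self):
        assert len(sg.ALL_CONDITIONS) == 16
        assert len(set(sg.ALL_CONDITIONS)) == 16

    def test_trial_durations(self):
        sched = sg.TrialSchedule()
        assert sched.duration_s(cond(sg.StimulusType.DOWEL)) == pytest.approx(4.8)
        assert sched.duration_s(cond(sg.StimulusType.FLEXION)) == pytest.approx(7.2)

    def test_full_schedule_enumerates_1600_trials(self):
        assert len(sg.TrialSchedule().enumerate_trials()) == 1600

    def test_reduced_schedule_one_trial_per_condition(self):
        sched = sg.TrialSchedule(trials_per_set=1, sets=1)
        assert len(sched.enumerate_trials()) == 16


class TestRateProfile:
    def test_dowel_peaks_within_10_ms_of_onset(self, desk_config):
        t = np.arange(-0.05, 1.0, 1e-4)
        r = sg.response_rate_profile(cond(sg.StimulusType.DOWEL), t, desk_config)
        assert 0.0 <= t[np.argmax(r)] <= 0.010

    def test_dowel_offset_transient_peaks_within_10_ms(self, desk_config):
        on = desk_config.schedule.stimulus_on_s
        t = np.arange(on - 0.05, on + 0.2, 1e-4)
        r = sg.response_rate_profile(cond(sg.StimulusType.DOWEL), t, desk_config)
        assert on <= t[np.argmax(r)] <= on + 0.010

    def test_brush_ramp_peaks_20_to_30_ms_after_onset(self, desk_config):
        t = np.arange(-0.05, 1.0, 1e-4)
        r = sg.response_rate_profile(cond(sg.StimulusType.BRUSH), t, desk_config)
        assert 0.020 <= t[np.argmax(r)] <= 0.030

    def test_proprioceptive_bump_peaks_at_movement_midpoint(self, desk_config):
        t = np.arange(0.0, 7.2, 1e-3)
        r = sg.response_rate_profile(cond(sg.StimulusType.FLEXION), t, desk_config)
        assert t[np.argmax(r)] == pytest.approx(1.2, abs=0.05)

    def test_zero_target_count_gives_zero_profile(self):
        config = sg.GeneratorConfig.desk(
            target_spike_count={s: 0.0 for s in sg.StimulusType}
        )
        t = np.arange(0.0, 4.8, 1e-3)
        r = sg.response_rate_profile(cond(sg.StimulusType.DOWEL), t, config)
        assert np.all(r == 0.0)

    def test_flexion_extension_count_ratio_by_quadrature(self, desk_config):
        # Independent numerical-quadrature oracle over the full trial span.
        t = np.arange(0.0, 7.2, 1e-4)
        rf = sg.response_rate_profile(cond(sg.StimulusType.FLEXION), t, desk_config)
        re = sg.response_rate_profile(cond(sg.StimulusType.EXTENSION), t, desk_config)
        ratio = np.trapezoid(rf, t) / np.trapezoid(re, t)
        assert ratio == pytest.approx(129.1 / 87.9, rel=1e-6)

    def test_baseline_rate_is_zero_outside_stimulus(self, desk_config):
        r = sg.response_rate_profile(
            cond(sg.StimulusType.BRUSH), np.array([-0.5, 4.79]), desk_config
        )
        assert np.all(r < 1e-6)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            sg.GeneratorConfig.desk(noise_sd_uV=-1.0)
        with pytest.raises(ValueError):
            sg.GeneratorConfig.desk(
                target_spike_count={s: -1.0 for s in sg.StimulusType}
            )


class TestGenerateTrial:
    def test_tactile_trial_length_48000_samples_at_10k(self, desk_config, rng):
        trial = sg.generate_trial(cond(sg.StimulusType.DOWEL), desk_config, rng)
        assert trial.n_samples == 48000  # 4.8 s at 10 kHz

    def test_proprioceptive_trial_length_72000_samples_at_10k(self, desk_config, rng):
        trial = sg.generate_trial(cond(sg.StimulusType.EXTENSION), desk_config, rng)
        assert trial.n_samples == 72000  # 7.2 s at 10 kHz

    def test_silent_config_gives_all_zero_trace(self, rng):
        config = sg.GeneratorConfig.desk(
            noise_sd_uV=0.0,
            lf_noise_sd_uV=0.0,
            target_spike_count={s: 0.0 for s in sg.StimulusType},
        )
        trial = sg.generate_trial(cond(sg.StimulusType.DOWEL), config, rng)
        assert np.all(trial.signal == 0.0)

    def test_too_low_fs_for_template_rejected(self, rng):
        config = sg.GeneratorConfig(fs=2000.0)
        with pytest.raises(ValueError, match="template"):
            sg.generate_trial(cond(sg.StimulusType.DOWEL), config, rng)

    def test_pre_onset_padding_shifts_onset_sample(self, rng):
        config = sg.GeneratorConfig.desk(pre_onset_s=0.5, min_post_onset_s=5.0)
        trial = sg.generate_trial(cond(sg.StimulusType.DOWEL), config, rng)
        assert trial.onset_sample == 5000
        assert trial.n_samples == 55000  # 0.5 s pre + 5.0 s post


class TestGenerateAnimal:
    def test_contains_all_16_conditions(self):
        sched = sg.TrialSchedule(trials_per_set=1, sets=1)
        ds = sg.generate_animal(sg.GeneratorConfig.desk(schedule=sched), 0, SEED)
        assert len(ds.trials) == 16
        assert len(ds.conditions()) == 16

    def test_same_seed_bit_identical(self):
        sched = sg.TrialSchedule(trials_per_set=1, sets=1)
        config = sg.GeneratorConfig.desk(schedule=sched)
        a = sg.generate_animal(config, 0, SEED)
        b = sg.generate_animal(config, 0, SEED)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.signal, tb.signal)

    def test_different_animals_differ(self):
        sched = sg.TrialSchedule(trials_per_set=1, sets=1)
        config = sg.GeneratorConfig.desk(schedule=sched)
        a = sg.generate_animal(config, 0, SEED)
        b = sg.generate_animal(config, 1, SEED)
        assert not np.array_equal(a.trials[0].signal, b.trials[0].signal)

    def test_iterator_matches_materialized_dataset(self):
        sched = sg.TrialSchedule(trials_per_set=1, sets=1)
        config = sg.GeneratorConfig.desk(schedule=sched)
        ds = sg.generate_animal(config, 0, SEED)
        for ta, tb in zip(sg.iter_animal_trials(config, 0, SEED), ds.trials):
            assert np.array_equal(ta.signal, tb.signal)


class TestStatisticalStructure:
    WINDOW = ft.FeatureWindow(0.0, 1000.0)

    def _detected(self, config, condition, n_trials, electrode, seed0=0):
        counts, energies = [], []
        for i in range(n_trials):
            trial = sg.generate_trial(
                condition, config, np.random.default_rng((SEED, seed0, i))
            )
            hf = sigproc.hf_bandpass(trial.electrode(electrode))
            ev = ft.detect_spikes(hf, self.WINDOW, onset_sample=trial.onset_sample)
            counts.append(len(ev))
            seg = sigproc.window_slice(hf, self.WINDOW, trial.onset_sample)
            energies.append(float(np.sum(seg**2)))
        return np.asarray(counts), np.asarray(energies)

    def test_detected_count_conserves_target(self, desk_config):
        # Mean detected count on a unit-gain electrode converges to the
        # configured per-condition target within Monte-Carlo error.
        for stim, electrode in [
            (sg.StimulusType.DOWEL, 0),  # e1 for left forelimb
            (sg.StimulusType.EXTENSION, 0),
        ]:
            target = desk_config.target_spike_count[stim]
            counts, _ = self._detected(desk_config, cond(stim), 100, 0)
            se = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - target) <= 3.0 * se, (
                f"{stim}: {counts.mean():.1f} vs {target} (SE {se:.2f})"
            )

    def test_ipsilateral_dominates_contralateral_for_forelimb(self, desk_config):
        # One-sided comparison of HF energy, ipsilateral (e1) vs
        # contralateral (e7), left forelimb, over 50 trials.
        from scipy import stats

        c = cond(sg.StimulusType.FLEXION, sg.Limb.LEFT_FORE)
        _, ipsi = self._detected(desk_config, c, 50, 0, seed0=1)
        _, contra = self._detected(desk_config, c, 50, 6, seed0=1)
        res = stats.ttest_rel(ipsi, contra, alternative="greater")
        assert res.pvalue < 1e-6

    def test_pre_stimulus_window_is_silent(self):
        config = sg.GeneratorConfig.desk(pre_onset_s=1.2)
        pre = ft.FeatureWindow(-1000.0, 800.0)
        total = 0
        for i in range(20):
            trial = sg.generate_trial(
                cond(sg.StimulusType.DOWEL), config, np.random.default_rng((SEED, 9, i))
            )
            hf = sigproc.hf_bandpass(trial.electrode(0))
            total += len(ft.detect_spikes(hf, pre, onset_sample=trial.onset_sample))
        assert total / 20 <= 0.5  # only rare noise crossings


class TestSpikeTemplate:
    def test_negative_leading_biphasic(self):
        w = sg.spike_template(40000.0)
        assert w.min() < 0 < w.max()
        assert np.argmin(w) < np.argmax(w)
        assert w.max() == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            sg.spike_template(2000.0, width_ms=1.0)
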