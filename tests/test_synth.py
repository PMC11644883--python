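"""Generator correctness: waveform construction, truth bookkeeping,
device overlays and seeded determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uef import hr, motor, synth


# --------------------------------------------------------------------------
# flexion trials
# --------------------------------------------------------------------------

class TestFlexionTrial:
    def test_pure_lobes_have_symmetric_constant_range(self, clean_trial):
        trial, truth = clean_trial
        assert truth.values["n_cycles"] == 30
        assert np.allclose(truth.per_cycle["velocity_range"], 600.0)
        assert trial.samples.max() == pytest.approx(300.0, rel=1e-3)
        assert trial.samples.min() == pytest.approx(-300.0, rel=1e-3)

    def test_seeded_determinism(self, clean_params):
        t1, tr1 = synth.gen_flexion_trial(clean_params)
        t2, tr2 = synth.gen_flexion_trial(clean_params)
        assert np.array_equal(t1.samples, t2.samples)
        assert tr1.values == tr2.values

    def test_decline_schedule_matches_window_ratio(self):
        p = synth.MotorSimParams(peak_velocity=300, cycle_frequency=1.5,
                                 decline_pct=-20, cycle_cv=0, noise_sd=0,
                                 drift_amp=0, seed=2)
        _, truth = synth.gen_flexion_trial(p)
        r = truth.per_cycle["velocity_range"]
        c = truth.per_cycle["center_time_s"]
        first = r[c < 5].mean()
        last = r[c >= 15].mean()
        assert last / first == pytest.approx(0.8, abs=1e-9)
        assert truth.values["decline"] == pytest.approx(-20.0, abs=1e-9)

    def test_rom_overrides_cycle_frequency(self):
        p = synth.MotorSimParams(peak_velocity=300, rom=63.662, cycle_cv=0,
                                 noise_sd=0, drift_amp=0, decline_pct=0)
        _, truth = synth.gen_flexion_trial(p)
        assert truth.values["cycle_frequency"] == pytest.approx(1.5, rel=1e-3)
        assert truth.values["flexibility"] == pytest.approx(63.662, rel=1e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration_s": 20.001},                 # non-integral sample count
            {"cycle_frequency": 30.0},              # unresolvable cycles
            {"noise_sd": 400.0},                    # noise above amplitude
            {"peak_velocity": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.gen_flexion_trial(synth.MotorSimParams(**kwargs))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        amp=st.floats(100, 800),
        f=st.floats(0.6, 2.5),
        decline=st.floats(-30, 10),
    )
    def test_truth_speed_is_twice_mean_amplitude(self, amp, f, decline):
        p = synth.MotorSimParams(peak_velocity=amp, cycle_frequency=f,
                                 decline_pct=decline, cycle_cv=4.0,
                                 noise_sd=1.0, drift_amp=0, seed=5)
        _, truth = synth.gen_flexion_trial(p)
        r = truth.per_cycle["velocity_range"]
        assert truth.values["speed"] == pytest.approx(r.mean(), rel=1e-12)
        assert truth.values["flexibility"] == pytest.approx(
            (r / 2).mean() / (math.pi * f), rel=1e-9
        )


class TestApplyDevice:
    def test_identity_model_is_exact(self, clean_trial):
        trial, _ = clean_trial
        out = synth.apply_device(trial, synth.DeviceNoiseModel(), seed=9)
        assert np.array_equal(out.samples, trial.samples)

    def test_input_unmodified(self, clean_trial):
        trial, _ = clean_trial
        before = trial.samples.copy()
        synth.apply_device(
            trial,
            synth.DeviceNoiseModel(gain=1.2, offset=5, extra_noise_sd=3,
                                   timing_jitter_ms=4),
            seed=9,
        )
        assert np.array_equal(trial.samples, before)

    def test_gain_scales_computed_speed_exactly(self, clean_trial):
        trial, _ = clean_trial
        out = synth.apply_device(trial, synth.DeviceNoiseModel(gain=1.1), seed=0)
        speed0 = motor.compute_speed(motor.segment_cycles(trial))
        speed1 = motor.compute_speed(motor.segment_cycles(out))
        assert speed1 == pytest.approx(1.1 * speed0, rel=1e-12)

    def test_dc_offset_removed_by_highpass(self, clean_trial):
        """A 50 deg/s DC offset lies in the high-pass stopband: the computed
        speed with and without the offset agrees within 1% post-filter."""
        trial, _ = clean_trial
        shifted = synth.apply_device(trial, synth.DeviceNoiseModel(offset=50.0),
                                     seed=0)
        f0 = motor.highpass(trial, 2.5)
        f1 = motor.highpass(shifted, 2.5)
        s0 = motor.compute_speed(motor.segment_cycles(f0))
        s1 = motor.compute_speed(motor.segment_cycles(f1))
        assert s1 == pytest.approx(s0, rel=0.01)


# --------------------------------------------------------------------------
# heart-rate profiles and beat series
# --------------------------------------------------------------------------

class TestRRSeries:
    def test_truth_by_construction(self):
        prof = synth.HRProfile(baseline_hr=80, task_increase_pct=25,
                               hrv_sd_ms=0, seed=0)
        _, truth = synth.gen_rr_series(prof)
        assert truth.values["hr_increase"] == pytest.approx(25.0)
        assert truth.values["mean_baseline"] == pytest.approx(80.0)

    def test_constant_profile_rr_750ms(self):
        prof = synth.HRProfile(baseline_hr=80, task_increase_pct=0,
                               hrv_sd_ms=0, seed=0)
        rr, _ = synth.gen_rr_series(prof)
        assert np.allclose(rr.intervals, 0.75, atol=1e-9)

    def test_recovery_decay_closed_form(self):
        """Independent evaluation of the exponential recovery: for b=80,
        +25% task, tau=20 s over a 60 s recovery the minimum recovery HR is
        b + (p-b)exp(-3), giving hr_decrease = -20(1 - e^-3)% = -19.004%."""
        b, pct, tau, rec = 80.0, 25.0, 20.0, 60.0
        p = b * (1 + pct / 100)
        expected = 100.0 * ((b - p) * (1 - math.exp(-rec / tau))) / p
        prof = synth.HRProfile(baseline_hr=b, task_increase_pct=pct,
                               recovery_tau_s=tau, recovery_s=rec,
                               hrv_sd_ms=0, seed=0)
        _, truth = synth.gen_rr_series(prof)
        assert truth.values["hr_decrease"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-19.0043, abs=1e-3)

    def test_tachycardic_profile_rejected(self):
        prof = synth.HRProfile(baseline_hr=180, task_increase_pct=50)
        with pytest.raises(ValueError, match="RR < 250 ms"):
            synth.gen_rr_series(prof)

    def test_seeded_determinism(self):
        prof = synth.HRProfile(seed=11)
        r1, _ = synth.gen_rr_series(prof)
        r2, _ = synth.gen_rr_series(prof)
        assert np.array_equal(r1.beat_times, r2.beat_times)


class TestECGWaveform:
    def test_qrs_peak_at_each_beat(self):
        prof = synth.HRProfile(hrv_sd_ms=5, seed=4)
        rr, _ = synth.gen_rr_series(prof)
        rec = synth.gen_ecg_waveform(rr, wander_mv=0.0, seed=4)
        for beat in rr.beat_times[1:-1]:
            a = int((beat - 0.05) * rec.fs_ecg)
            b = int((beat + 0.05) * rec.fs_ecg)
            peak = (a + np.argmax(rec.ecg[a:b])) / rec.fs_ecg
            assert abs(peak - beat) <= 0.005

    def test_qrs_count_constant_60bpm_10s(self):
        rr = hr.RRSeries(beat_times=np.arange(0.5, 10.0, 1.0), source="synthetic")
        rec = synth.gen_ecg_waveform(rr, wander_mv=0.0, seed=0,
                                     include_accel=False)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(rec.ecg, height=0.5, distance=200)
        assert len(peaks) in (10, 11)

    def test_accel_task_window_rms_ratio(self):
        prof = synth.HRProfile(seed=2)
        rr, _ = synth.gen_rr_series(prof)
        rec = synth.gen_ecg_waveform(rr, seed=2)
        ta = np.arange(rec.accel.shape[0]) / rec.fs_acc
        mag = np.linalg.norm(rec.accel, axis=1)
        inside = mag[(ta >= 60) & (ta < 80)]
        outside = mag[(ta < 60) | (ta >= 80)]
        rms = lambda x: np.sqrt(np.mean(x**2))  # noqa: E731
        assert rms(inside) > 10 * rms(outside)

    def test_empty_rr_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_ecg_waveform(hr.RRSeries(beat_times=np.array([])))


class TestPPGStream:
    def test_identity_settings_reproduce_true_hr(self):
        prof = synth.HRProfile(hrv_sd_ms=0, seed=0)
        rr, _ = synth.gen_rr_series(prof)
        stream = synth.gen_ppg_hr(rr, smooth_window_s=0, lag_s=0, noise_bpm=0)
        mids = (rr.beat_times[:-1] + rr.beat_times[1:]) / 2
        expected = np.interp(stream.times, mids, 60.0 / rr.intervals)
        assert np.allclose(stream.hr, expected)

    def test_smoothing_preserves_constant_hr(self):
        prof = synth.HRProfile(baseline_hr=72, task_increase_pct=0,
                               hrv_sd_ms=0, seed=0)
        rr, _ = synth.gen_rr_series(prof)
        stream = synth.gen_ppg_hr(rr, smooth_window_s=15, lag_s=5, noise_bpm=0)
        assert np.allclose(stream.hr, 72.0, atol=0.2)

    def test_smoothing_attenuates_measured_increase(self):
        """A moving average cannot exceed the task HR extremum; once the
        window outgrows the task plateau the measured increase falls
        strictly below the true 25%."""
        prof = synth.HRProfile(baseline_hr=80, task_increase_pct=25,
                               hrv_sd_ms=0, seed=0)
        rr, truth = synth.gen_rr_series(prof)
        true_inc = truth.values["hr_increase"]
        for smooth in (5.0, 10.0, 20.0):
            stream = synth.gen_ppg_hr(rr, smooth_window_s=smooth, lag_s=5,
                                      noise_bpm=0)
            params = hr.compute_hr_params(stream, rr.windows)
            assert params.hr_increase <= true_inc + 1e-6
            if smooth > 5.0:
                assert params.hr_increase < true_inc - 1.0


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

class TestCohort:
    def test_reproducible_from_seed(self):
        c1 = synth.gen_cohort(n=2, seed=42, n_trials=1)
        c2 = synth.gen_cohort(n=2, seed=42, n_trials=1)
        s1, s2 = c1.subjects[0], c2.subjects[0]
        assert np.array_equal(
            s1.motor["unweighted"][0].watch.samples,
            s2.motor["unweighted"][0].watch.samples,
        )
        assert np.array_equal(s1.ecg.ecg, s2.ecg.ecg)
        assert np.array_equal(s1.watch_hr.hr, s2.watch_hr.hr)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_cohort(n=1)

    def test_degenerate_bounds_rejected(self):
        bad = {k: dict(v) for k, v in synth.DEFAULT_MOTOR_BOUNDS.items()}
        bad["unweighted"]["peak_velocity"] = (400.0, 300.0)
        with pytest.raises(ValueError, match="degenerate bounds"):
            synth.gen_cohort(n=3, motor_bounds=bad)

    def test_identical_devices_give_perfect_icc(self):
        """With both device overlays set to the identity the two sides see
        the same samples and every motor parameter agrees exactly."""
        from uef.agreement import PairedMeasurements, icc

        ident = {"reference": synth.DeviceNoiseModel(),
                 "watch": synth.DeviceNoiseModel()}
        cohort = synth.gen_cohort(n=4, seed=3, n_trials=1,
                                  device_models=ident,
                                  conditions=("unweighted",))
        vals_a, vals_b = [], []
        for subj in cohort.subjects:
            pair = subj.motor["unweighted"][0]
            pa = motor.compute_motor_params(pair.reference, subj.anthro,
                                            highpass_cutoff=None)
            pb = motor.compute_motor_params(pair.watch, subj.anthro,
                                            highpass_cutoff=None)
            vals_a.append(pa.speed)
            vals_b.append(pb.speed)
        pairs = PairedMeasurements(
            subject_id=[s.subject_id for s in cohort.subjects],
            value_a=vals_a, value_b=vals_b, parameter_name="speed",
        )
        assert icc(pairs) == pytest.approx(1.0, abs=1e-12)

    def test_noise_monotonically_degrades_median_icc(self):
        """Median downstream ICC (speed) over seeded replicate cohorts never
        improves as the watch noise SD grows."""
        from uef.agreement import PairedMeasurements, icc

        def median_icc(noise_sd: float) -> float:
            iccs = []
            for rep in range(20):
                cohort = synth.gen_cohort(
                    n=6, seed=1000 + rep, n_trials=1,
                    conditions=("unweighted",),
                    device_models={
                        "reference": synth.DeviceNoiseModel(),
                        "watch": synth.DeviceNoiseModel(extra_noise_sd=noise_sd),
                    },
                )
                a, b, ids = [], [], []
                for subj in cohort.subjects:
                    pair = subj.motor["unweighted"][0]
                    a.append(motor.compute_motor_params(
                        pair.reference, subj.anthro, highpass_cutoff=None).speed)
                    b.append(motor.compute_motor_params(
                        pair.watch, subj.anthro, highpass_cutoff=None).speed)
                    ids.append(subj.subject_id)
                iccs.append(icc(PairedMeasurements(ids, a, b, "speed")))
            return float(np.median(iccs))

        med = [median_icc(s) for s in (0.0, 30.0, 90.0)]
        assert med[0] >= med[1] >= med[2]
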