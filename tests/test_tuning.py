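import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import spearman_bruteforce
from pursuitkit.alignment import AlignedResponse, detect_onset_offset
from pursuitkit.simulate import TuningParams, generate_speed_tuned_spikes, treadmill_speed
from pursuitkit.tuning import (
    LightPulseLog,
    SpikeTrain,
    align_to_events,
    identify_antidromic,
    locomotion_bouts,
    spearman,
    speed_tuning,
)


def make_unit(latency=0.003, jitter=0.0002, template_flip=False, seed=0, duration=60.0):
    time, speed = treadmill_speed(duration, seed=seed + 1000)
    params = TuningParams(
        antidromic_latency=latency,
        latency_jitter_sd=jitter,
        seed=seed,
        antidromic_template=None,
    )
    if template_flip:
        params.antidromic_template = -params.waveform_template
    train, pulses, gt = generate_speed_tuned_spikes(params, time, speed)
    beh = train.spike_times < time[-1]
    loco = SpikeTrain(train.spike_times[beh], train.waveforms[beh], t_stop=float(time[-1]))
    return train, pulses, loco, gt


class TestAntidromic:
    def test_planted_3ms_identified(self):
        train, pulses, loco, _ = make_unit(latency=0.003)
        res = identify_antidromic(train, pulses, loco)
        assert res.identified
        assert res.median_latency == pytest.approx(0.003, abs=0.001)
        assert res.waveform_similarity > 0.9

    def test_planted_6ms_rejected(self):
        train, pulses, loco, _ = make_unit(latency=0.006)
        res = identify_antidromic(train, pulses, loco)
        assert not res.identified

    def test_mismatched_waveform_rejected(self):
        train, pulses, loco, _ = make_unit(template_flip=True)
        res = identify_antidromic(train, pulses, loco)
        assert not res.identified
        # similarity oracle: direct correlation of the mean waveforms
        evoked = train.spike_times >= loco.t_stop
        m1 = train.waveforms[evoked].mean(axis=0)
        m2 = loco.waveforms.mean(axis=0)
        oracle = np.corrcoef(m1, m2)[0, 1]
        assert res.waveform_similarity == pytest.approx(oracle, abs=0.05)
        assert oracle < 0.5

    def test_pulse_locked_spikes_within_5ms(self):
        # jittered antidromic latencies all land within the 5-ms criterion
        train, pulses, loco, _ = make_unit(latency=0.003, jitter=0.0002)
        evoked = train.spike_times[train.spike_times >= pulses.pulse_times[0]]
        for t in evoked:
            lat = t - pulses.pulse_times[pulses.pulse_times <= t][-1]
            assert lat < 0.005

    def test_no_locked_spikes_not_identified(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 100, 500))
        train = SpikeTrain(spikes, np.tile(np.sin(np.arange(32)), (500, 1)), t_stop=200.0)
        pulses = LightPulseLog(150.0 + np.arange(30) * 0.5)
        res = identify_antidromic(train, pulses, train)
        assert not res.identified and res.response_reliability == 0.0

    def test_too_few_pulses_rejected(self):
        train, pulses, loco, _ = make_unit()
        with pytest.raises(ValueError):
            identify_antidromic(train, LightPulseLog(pulses.pulse_times[:5]), loco)


class TestAlignment:
    def test_step_increase_positive_z_after_event(self, rng):
        events = np.arange(10.0, 190.0, 10.0)
        spikes = []
        t = 0.0
        while t < 200.0:
            near = np.any((events <= t) & (t <= events + 1.0))
            rate = 30.0 if near else 5.0
            t += rng.exponential(1 / rate)
            spikes.append(t)
        train = SpikeTrain(np.array(spikes), t_stop=200.0)
        resp = align_to_events(train, events)
        post = resp.zscored[(resp.time > 0.1) & (resp.time < 0.9)]
        assert post.mean() > 3.0

    def test_periodic_train_degenerate_baseline_flagged(self):
        # exactly periodic, spikes centered in the 20-ms PSTH bins
        train = SpikeTrain(np.arange(0.01, 100, 0.02), t_stop=100.0)
        resp = align_to_events(train, np.arange(10.0, 90.0, 10.0))
        assert resp.baseline_degenerate and resp.zscored is None

    def test_z_location_scale_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(5, size=(20, 200)) / 0.02
        t = np.arange(200) * 0.02 - 2.0
        r1 = AlignedResponse(time=t, per_trial=mat, baseline_window=(-2.0, -1.0))
        r2 = AlignedResponse(time=t, per_trial=mat + 100.0, baseline_window=(-2.0, -1.0))
        r3 = AlignedResponse(time=t, per_trial=mat * 7.0, baseline_window=(-2.0, -1.0))
        assert np.allclose(r1.zscored, r2.zscored)
        assert np.allclose(r1.zscored, r3.zscored)

    def test_event_outside_recording_dropped(self):
        train = SpikeTrain(np.arange(0, 10, 0.1), t_stop=10.0)
        with pytest.raises(ValueError):
            align_to_events(train, np.array([0.5]), window=(-2.0, 2.0))


class TestOnsetDetection:
    def ramp_response(self, bin_s=0.02):
        t = np.arange(-0.5, 0.5 + 1e-9, bin_s)
        y = np.clip((t + 0.2) / 0.2, 0, 1)
        return AlignedResponse(time=t, per_trial=y[None, :], baseline_window=(-0.5, -0.3))

    def test_linear_ramp_analytic_onset(self):
        # 15% of a 0->1 ramp over [-0.2, 0]: crossing at -0.17 s
        est = detect_onset_offset(self.ramp_response())
        assert est.onset_time == pytest.approx(-0.17, abs=0.02)

    def test_step_function_onset(self):
        t = np.arange(-0.5, 0.5 + 1e-9, 0.02)
        y = (t >= -0.1).astype(float)
        resp = AlignedResponse(time=t, per_trial=y[None, :], baseline_window=(-0.5, -0.3))
        est = detect_onset_offset(resp)
        assert est.onset_time == pytest.approx(-0.1, abs=0.021)

    def test_translation_equivariance(self):
        # shifting the time base shifts the onset estimate identically
        base = self.ramp_response()
        est0 = detect_onset_offset(base)
        shifted = AlignedResponse(
            time=base.time + 0.3,
            per_trial=base.per_trial,
            baseline_window=(-0.2, 0.0),
        )
        est1 = detect_onset_offset(shifted)
        assert est1.onset_time - est0.onset_time == pytest.approx(0.3, abs=1e-9)

    def test_flat_response_undefined(self):
        t = np.arange(-0.5, 0.5, 0.02)
        resp = AlignedResponse(
            time=t,
            per_trial=np.vstack([np.zeros_like(t), np.ones_like(t)]),
            baseline_window=(-0.5, -0.3),
        )
        est = detect_onset_offset(resp)
        assert est.onset_time is None and est.offset_time is None

    def test_offset_returns_to_baseline(self):
        t = np.arange(-0.5, 1.0 + 1e-9, 0.02)
        y = np.where((t >= 0) & (t <= 0.4), 1.0, 0.0)
        resp = AlignedResponse(time=t, per_trial=y[None, :], baseline_window=(-0.5, -0.1))
        est = detect_onset_offset(resp)
        assert est.offset_time == pytest.approx(0.4, abs=0.05)


class TestSpeedTuning:
    def synth_windows(self, f):
        """Unit whose rate is an exact function of speed, via planted spikes."""
        rngl = np.random.default_rng(5)
        time = np.arange(0, 200, 0.02)
        speed = np.clip(np.abs(np.cumsum(rngl.normal(0, 0.5, len(time)))) % 40, 0, None)
        spikes = []
        for w0 in np.arange(0, 199.5, 0.5):
            m = (time >= w0) & (time < w0 + 0.5)
            v = speed[m].mean()
            n = int(round(f(v) * 0.5))
            spikes.extend(w0 + (np.arange(n) + 0.5) * (0.5 / max(n, 1)))
        train = SpikeTrain(np.array(spikes), t_stop=200.0)
        return train, time, speed

    def test_strictly_increasing_rate_rho_one(self):
        train, time, speed = self.synth_windows(lambda v: 10 + 4 * v)
        curve = speed_tuning(train, time, speed)
        assert curve.spearman_rho == 1.0

    def test_strictly_decreasing_rate_rho_minus_one(self):
        train, time, speed = self.synth_windows(lambda v: max(0.0, 150 - 4 * v))
        curve = speed_tuning(train, time, speed)
        assert curve.spearman_rho == -1.0

    def test_normalization_range(self):
        train, time, speed = self.synth_windows(lambda v: 10 + 4 * v)
        curve = speed_tuning(train, time, speed)
        occ = np.isfinite(curve.normalized_rate)
        assert curve.normalized_rate[occ].min() == 0.0
        assert curve.normalized_rate[occ].max() == 1.0

    def test_too_few_bins_undefined(self):
        train = SpikeTrain(np.arange(0, 10, 0.1), t_stop=10.0)
        time = np.arange(0, 10, 0.02)
        speed = np.full_like(time, 10.0)  # single occupied speed bin
        curve = speed_tuning(train, time, speed)
        assert curve.spearman_rho is None

    @settings(deadline=None, max_examples=60)
    @given(
        n=st.integers(4, 30),
        ties=st.booleans(),
        seed=st.integers(0, 10_000),
    )
    def test_spearman_matches_bruteforce(self, n, ties, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 6, n).astype(float) if ties else r.normal(size=n)
        y = r.integers(0, 6, n).astype(float) if ties else r.normal(size=n)
        oracle = spearman_bruteforce(x, y)
        if np.isnan(oracle):
            return
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # perfectly monotone n=4: p = 2 * 1/4! (both signed extremes)
        rho, p = spearman(np.arange(4.0), np.arange(4.0) ** 2)
        assert rho == 1.0
        assert p == pytest.approx(2 / 24)

    def test_exact_p_matches_enumeration_null(self):
        # untied data: p equals the tail mass of the enumerated |rho| null
        from _oracles import exact_abs_rho_null

        r = np.random.default_rng(11)
        for n in (5, 6, 7):
            x, y = r.normal(size=n), r.normal(size=n)
            rho, p = spearman(x, y)
            null = exact_abs_rho_null(n)
            expected = np.mean(null >= abs(rho) - 1e-12)
            assert p == pytest.approx(expected, abs=1e-12)


class TestBouts:
    def test_always_zero_no_bouts(self):
        t = np.arange(0, 10, 0.02)
        assert locomotion_bouts(t, np.zeros_like(t)) == []

    def test_square_wave_edges(self):
        t = np.arange(0, 30, 0.02)
        speed = np.where((t >= 5) & (t < 10) | (t >= 15) & (t < 22), 20.0, 0.0)
        bouts = locomotion_bouts(t, speed)
        assert len(bouts) == 2
        assert bouts[0][0] == pytest.approx(5.0, abs=0.03)
        assert bouts[0][1] == pytest.approx(10.0, abs=0.03)

    def test_short_bout_discarded(self):
        t = np.arange(0, 10, 0.02)
        speed = np.where((t >= 5) & (t < 5.5), 20.0, 0.0)
        assert locomotion_bouts(t, speed) == []

    def test_planted_bouts_recovered(self):
        time, speed = treadmill_speed(120, seed=3)
        bouts = locomotion_bouts(time, speed)
        # every detected bout overlaps a planted above-threshold period
        assert len(bouts) >= 5
        for b0, b1 in bouts:
            m = (time >= b0) & (time < b1)
            assert speed[m].max() > 3.0
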