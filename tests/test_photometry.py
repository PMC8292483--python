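import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pursuitkit.photometry import (
    FluorescenceTrace,
    compute_dff,
    event_triggered_average,
    evoked_amplitude,
    input_output_curve,
    onset_lead,
    suppression_ratio,
)
from pursuitkit.simulate import (
    PhotometryParams,
    generate_evoked_session,
    generate_photometry,
    saturating_power_map,
)


def flat_trace(value=100.0, duration=60.0, fs=100.0):
    t = np.arange(int(duration * fs)) / fs
    return FluorescenceTrace(time=t, raw=np.full_like(t, value))


class TestDFF:
    def test_constant_trace_zero_dff(self):
        dff = compute_dff(flat_trace())
        assert np.allclose(dff.dff, 0.0)

    def test_plateau_recovers_fraction(self):
        tr = flat_trace(duration=120.0)
        raw = tr.raw.copy()
        raw[6000:6200] *= 1.05  # 2-s plateau, 5% above baseline
        tr = FluorescenceTrace(time=tr.time, raw=raw)
        dff = compute_dff(tr)
        assert np.allclose(dff.dff[6050:6150], 0.05, atol=1e-6)

    @settings(deadline=None, max_examples=20)
    @given(gain=st.floats(0.1, 50.0))
    def test_gain_invariance_exact(self, gain):
        trace, _ = generate_photometry(
            PhotometryParams(seed=11), np.array([10.0, 20.0]), 40.0
        )
        d1 = compute_dff(trace).dff
        d2 = compute_dff(
            FluorescenceTrace(time=trace.time, raw=trace.raw * gain)
        ).dff
        assert np.allclose(d1, d2, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(600) / 100.0
        with pytest.raises(ValueError):
            compute_dff(FluorescenceTrace(time=t, raw=np.full_like(t, -1.0)))

    def test_transient_amplitude_recovery(self):
        # planted noiseless transients recovered within 5%
        p = PhotometryParams(noise_sd=0.0, transient_amplitude=0.08, seed=0)
        onsets = np.arange(10.0, 110.0, 10.0)
        trace, gt = generate_photometry(p, onsets, 120.0)
        dff = compute_dff(trace)
        eta = event_triggered_average(dff, onsets - p.transient_lead, window=(-1, 2))
        assert eta.mean.max() == pytest.approx(0.08, rel=0.05)


class TestEventTriggered:
    def test_flat_zero_average(self):
        dff = compute_dff(flat_trace())
        eta = event_triggered_average(dff, np.array([10.0, 20.0, 30.0]))
        assert np.allclose(eta.mean, 0.0)

    def test_single_transient_average_equals_kernel(self):
        p = PhotometryParams(noise_sd=0.0, transient_lead=0.0, seed=0)
        onsets = np.arange(10.0, 110.0, 10.0)
        trace, _ = generate_photometry(p, onsets, 120.0)
        dff = compute_dff(trace)
        eta = event_triggered_average(dff, onsets, window=(-1, 2))
        post = eta.time >= 0
        peak_t = eta.time[post][np.argmax(eta.mean[post])]
        # dual-exponential kernel peaks at rise * log(1 + decay/rise)
        tp = p.kernel_rise * np.log(1 + p.kernel_decay / p.kernel_rise)
        assert peak_t == pytest.approx(tp, abs=0.03)
        assert eta.mean.max() == pytest.approx(p.transient_amplitude, rel=0.05)

    def test_no_events_in_range_rejected(self):
        dff = compute_dff(flat_trace(duration=10.0))
        with pytest.raises(ValueError):
            event_triggered_average(dff, np.array([100.0]))


class TestOnsetLead:
    def test_noiseless_planted_lead_recovered(self):
        p = PhotometryParams(noise_sd=0.0, transient_lead=0.12, seed=0)
        onsets = np.arange(10.0, 110.0, 10.0)
        trace, _ = generate_photometry(p, onsets, 120.0)
        eta = event_triggered_average(compute_dff(trace), onsets, window=(-1, 2))
        est = onset_lead(eta)
        assert est.onset_time == pytest.approx(-0.12, abs=0.015)

    def test_transient_at_event_onset_near_zero(self):
        p = PhotometryParams(noise_sd=0.0, transient_lead=0.0, seed=0)
        onsets = np.arange(10.0, 110.0, 10.0)
        trace, _ = generate_photometry(p, onsets, 120.0)
        eta = event_triggered_average(compute_dff(trace), onsets, window=(-1, 2))
        est = onset_lead(eta)
        assert est.onset_time == pytest.approx(0.0, abs=0.02)

    def test_sessionwise_lead_recovery(self):
        # several noisy sessions: mean recovered lead within +/- 30 ms
        leads = []
        for seed in range(6):
            p = PhotometryParams(seed=seed)  # default lead 0.125, stated noise
            onsets = np.arange(10.0, 290.0, 8.0)
            trace, gt = generate_photometry(p, onsets, 300.0)
            eta = event_triggered_average(compute_dff(trace), onsets, window=(-1, 2))
            leads.append(onset_lead(eta).onset_time)
        assert np.mean(leads) == pytest.approx(-0.125, abs=0.03)


class TestEvoked:
    def test_zero_power_zero_amplitude(self):
        p = PhotometryParams(seed=0)
        trace, table, _ = generate_evoked_session(p, np.array([0.0, 10.0]))
        dff = compute_dff(trace)
        amp0 = evoked_amplitude(dff, table.query("power_mw == 0")["time"].to_numpy(), 0.0)
        amp10 = evoked_amplitude(dff, table.query("power_mw == 10")["time"].to_numpy(), 10.0)
        assert abs(amp0.amplitude) < 0.01
        assert amp10.amplitude > 5 * abs(amp0.amplitude)

    def test_monotone_map_gives_monotone_curve(self):
        p = PhotometryParams(seed=1)
        powers = np.array([2.0, 5.0, 10.0, 15.0, 20.0])
        trace, table, gt = generate_evoked_session(p, powers)
        dff = compute_dff(trace)
        resp = [
            evoked_amplitude(dff, table.query("power_mw == @pw")["time"].to_numpy(), pw)
            for pw in powers
        ]
        curve = input_output_curve(resp)
        amps = curve["mean_amplitude"].to_numpy()
        assert np.all(np.diff(amps) >= -0.002)  # monotone up to noise floor

    def test_saturating_map_recovered(self):
        # noiseless: fitted amplitudes within 5% of the planted map
        p = PhotometryParams(noise_sd=0.0, seed=2)
        powers = np.array([2.0, 5.0, 10.0, 20.0])
        trace, table, gt = generate_evoked_session(p, powers, n_pulses_per_power=5)
        dff = compute_dff(trace)
        for pw in powers:
            amp = evoked_amplitude(
                dff, table.query("power_mw == @pw")["time"].to_numpy(), pw
            ).amplitude
            assert amp == pytest.approx(gt.evoked_amplitudes[pw], rel=0.05)

    def test_control_channel_flat(self):
        p = PhotometryParams(seed=3)
        trace, table, _ = generate_evoked_session(p, np.array([10.0, 20.0]), channel="control")
        dff = compute_dff(trace)
        for pw in (10.0, 20.0):
            amp = evoked_amplitude(
                dff, table.query("power_mw == @pw")["time"].to_numpy(), pw
            ).amplitude
            assert abs(amp) < 0.01


class TestSuppression:
    def run_ratio(self, factor, seed):
        treated_p = PhotometryParams(suppression_factor=factor, seed=seed)
        control_p = PhotometryParams(suppression_factor=1.0, seed=seed + 5000)
        out = []
        for p in (treated_p, control_p):
            trace, table, _ = generate_evoked_session(p, np.array([10.0]))
            dff = compute_dff(trace)
            out.append(
                [evoked_amplitude(dff, table["time"].to_numpy(), 10.0)]
            )
        return suppression_ratio(out[0], out[1])

    def test_identical_groups_ratio_one(self):
        p = PhotometryParams(seed=4)
        trace, table, _ = generate_evoked_session(p, np.array([10.0]))
        dff = compute_dff(trace)
        r = [evoked_amplitude(dff, table["time"].to_numpy(), 10.0)]
        assert suppression_ratio(r, r) == 1.0

    def test_full_suppression_near_zero(self):
        assert self.run_ratio(0.0, seed=6) == pytest.approx(0.0, abs=0.1)

    def test_quarter_suppression_recovered(self):
        ratios = [self.run_ratio(0.25, seed=s) for s in range(5)]
        assert 0.2 <= np.mean(ratios) <= 0.3
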