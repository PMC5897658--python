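"""Half-amplitude idealization, dead-time censoring, amplitude and P_o."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import channelkit as ck
from channelkit.single_channel import ChannelEvent, EventList, censor_events


def square_trace(openings_ms, amp=-4.5, gap_ms=5.0, fs=25000.0):
    """Deterministic record with square openings of the given durations."""
    dt = 1.0 / fs
    segs = []
    for ms in openings_ms:
        segs.append(np.zeros(int(round(gap_ms * 1e-3 * fs))))
        segs.append(np.full(int(round(ms * 1e-3 * fs)), amp))
    segs.append(np.zeros(int(round(gap_ms * 1e-3 * fs))))
    i = np.concatenate(segs)
    return ck.CurrentTrace(t=np.arange(len(i)) * dt, i=i, sampling_rate=fs)


class TestIdealization:
    def test_flat_trace_has_no_openings(self):
        tr = square_trace([])
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        assert len(events.open_events) == 0

    def test_square_openings_recovered_exactly(self):
        tr = square_trace([1.0, 2.0, 5.0])
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        opens = events.open_events
        assert [round(e.duration * 1e3, 6) for e in opens] == [1.0, 2.0, 5.0]

    def test_sub_dead_time_opening_excluded(self):
        tr = square_trace([0.3, 2.0])  # 0.3 ms < 446 us
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        assert len(events.open_events) == 1
        assert events.open_events[0].duration == pytest.approx(2e-3, rel=1e-6)

    def test_matches_generator_truth_after_censoring(self):
        tr = ck.generate_single_channel_trace(-4.5, 0.002, 0.02, 3.0,
                                              noise=ck.NoiseSpec(sd=0.0, seed=21))
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        truth = censor_events(list(tr.events_truth), events.dead_time)
        assert [(e.state, round(e.duration, 10)) for e in events] == \
               [(e.state, round(e.duration, 10)) for e in truth]

    def test_levels_estimated_from_histogram(self):
        tr = ck.generate_single_channel_trace(-4.5, 0.005, 0.045, 5.0,
                                              noise=ck.NoiseSpec(sd=0.3, seed=3))
        events = ck.idealize_half_threshold(tr)
        assert events.open_level == pytest.approx(-4.5, abs=0.3)
        assert events.baseline == pytest.approx(0.0, abs=0.3)

    def test_equal_levels_rejected(self):
        tr = square_trace([1.0])
        with pytest.raises(ck.ValidationError):
            ck.idealize_half_threshold(tr, baseline=0.0, open_level=0.0)


class TestCensoring:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(durs=st.lists(st.floats(1e-5, 5e-3), min_size=1, max_size=20),
           dead=st.floats(1e-5, 1e-3))
    def test_censoring_never_creates_open_time(self, durs, dead):
        events, t = [], 0.0
        for k, d in enumerate(durs):
            events.append(ChannelEvent(t, d, "open" if k % 2 else "closed"))
            t += d
        total_open = sum(e.duration for e in events if e.state == "open")
        censored = censor_events(events, dead)
        open_after = sum(e.duration for e in censored if e.state == "open")
        assert open_after <= total_open + 1e-12
        assert sum(e.duration for e in censored) == pytest.approx(t, rel=1e-9)
        assert all(e.duration >= dead - 1e-12 for e in censored if e.state == "open")


class TestAmplitude:
    @pytest.mark.parametrize("amp", [-4.5, -2.4])
    def test_amplitude_recovered_within_tenth_pa(self, amp):
        tr = ck.generate_single_channel_trace(amp, 0.005, 0.045, 30.0,
                                              noise=ck.NoiseSpec(sd=0.5, seed=13))
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=amp)
        fit = ck.fit_amplitude_histogram(tr, events)
        assert fit.mean_amp == pytest.approx(amp, abs=0.1)
        assert fit.sd > 0

    def test_noiseless_record_degenerates_to_sample_mean(self):
        tr = square_trace([2.0, 3.0])
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        fit = ck.fit_amplitude_histogram(tr, events)
        assert fit.degenerate and fit.sd == 0.0
        assert fit.mean_amp == pytest.approx(-4.5)

    def test_no_events_rejected(self):
        tr = square_trace([])
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        with pytest.raises(ck.FitError):
            ck.fit_amplitude_histogram(tr, events)


class TestOpenProbability:
    def test_fractional_open_time(self):
        events = EventList(events=[ChannelEvent(0.0, 9.0, "closed"),
                                   ChannelEvent(9.0, 1.0, "open", -4.5)],
                           total_time=10.0)
        assert ck.single_channel_po(events) == pytest.approx(10.0)
        assert ck.single_channel_po(events, n_channels=2) == pytest.approx(5.0)

    def test_renewal_process_long_record(self):
        tr = ck.generate_single_channel_trace(-4.5, 0.005, 0.045, 60.0,
                                              noise=ck.NoiseSpec(sd=0.0, seed=17))
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        assert ck.single_channel_po(events) == pytest.approx(10.0, abs=1.0)

    def test_amplitude_scale_invariance(self):
        tr1 = ck.generate_single_channel_trace(-4.5, 0.005, 0.045, 5.0,
                                               noise=ck.NoiseSpec(sd=0.0, seed=19))
        tr2 = ck.CurrentTrace(t=tr1.t, i=tr1.i * 3.0, sampling_rate=tr1.sampling_rate)
        e1 = ck.idealize_half_threshold(tr1, baseline=0.0, open_level=-4.5)
        e2 = ck.idealize_half_threshold(tr2, baseline=0.0, open_level=-13.5)
        assert ck.single_channel_po(e1) == pytest.approx(ck.single_channel_po(e2), rel=1e-12)

    def test_zero_open_events(self):
        tr = square_trace([])
        events = ck.idealize_half_threshold(tr, baseline=0.0, open_level=-4.5)
        assert ck.single_channel_po(events) == 0.0


class TestBesselFilter:
    def test_dc_gain_unity(self):
        t = np.arange(0, 0.1, 4e-5)
        tr = ck.CurrentTrace(t=t, i=np.full_like(t, -7.0), sampling_rate=25000.0)
        out = ck.filter_trace(tr, 2000.0)
        assert np.allclose(out.i, -7.0, atol=1e-9)

    def test_step_rise_time_matches_analog_prototype(self):
        fs, fc = 25000.0, 2000.0
        t = np.arange(0, 0.05, 1 / fs)
        step = np.where(t >= 0.02, 1.0, 0.0)
        tr = ck.CurrentTrace(t=t, i=step, sampling_rate=fs)
        out = ck.filter_trace(tr, fc)

        def rise_time(tt, y):
            lo = tt[np.nonzero(y >= 0.1)[0][0]]
            hi = tt[np.nonzero(y >= 0.9)[0][0]]
            return hi - lo

        tr_dig = rise_time(t, out.i)
        # independent oracle: step response of the analog prototype
        b, a = signal.bessel(4, 2 * np.pi * fc, btype="low", analog=True, norm="mag")
        tt, yy = signal.step((b, a), T=np.linspace(0, 2e-3, 20000))
        tr_ana = rise_time(tt, yy)
        assert tr_dig == pytest.approx(tr_ana, rel=0.10)

    def test_double_filtering_halves_bandwidth_in_quadrature(self):
        fs, fc = 25000.0, 2000.0
        t = np.arange(0, 0.05, 1 / fs)
        step = np.where(t >= 0.02, 1.0, 0.0)
        tr = ck.CurrentTrace(t=t, i=step, sampling_rate=fs)
        once = ck.filter_trace(tr, fc)
        twice = ck.filter_trace(once, fc)

        def rise_time(y):
            lo = np.nonzero(y >= 0.1)[0][0]
            hi = np.nonzero(y >= 0.9)[0][0]
            return (hi - lo) / fs

        # rise times add in quadrature: doubling the filter ~ sqrt(2) slower
        assert rise_time(twice.i) / rise_time(once.i) == pytest.approx(np.sqrt(2), rel=0.10)

    def test_fc_above_nyquist_rejected(self):
        tr = square_trace([1.0])
        with pytest.raises(ck.ValidationError):
            ck.filter_trace(tr, 20000.0)
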