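"""Cycle segmentation, asymmetry measures, and burst classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ssdkit as sk
from ssdkit.synth import SourceSpec, _pink_noise, simulate_sources

FS = 1000.0


def source_trace(kind, freq, asym=0.0, duration=30.0, seed=0, burst=None):
    spec = SourceSpec(kind=kind, freq=freq, asymmetry=asym, burst=burst)
    s, windows = simulate_sources([spec], duration, FS, seed=seed)
    return s[:, 0], windows[0]


class TestAsymmetryMeasures:
    def test_worked_example_60_40(self):
        """A 100 ms cycle spending 60 ms in the peak and 40 ms in the
        trough has peak-trough asymmetry exactly 0.2."""
        assert sk.peak_trough_asymmetry(0.060, 0.040) == pytest.approx(0.2)

    def test_symmetric_cycle_zero(self):
        assert sk.peak_trough_asymmetry(0.05, 0.05) == 0.0
        assert sk.rise_decay_asymmetry(0.05, 0.05) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(1e-3, 1.0), t=st.floats(1e-3, 1.0))
    def test_bounded_and_antisymmetric(self, p, t):
        v = sk.peak_trough_asymmetry(p, t)
        assert -1 < v < 1
        assert sk.peak_trough_asymmetry(t, p) == pytest.approx(-v)


class TestSegmentCycles:
    def test_sine_is_symmetric(self):
        t = np.arange(0, 30, 1 / FS)
        ct = sk.segment_cycles(np.sin(2 * np.pi * 10 * t), FS, 10.0)
        assert len(ct) > 250
        assert ct["peak_trough_asym"].abs().mean() < 0.02
        assert ct["rise_decay_asym"].abs().mean() < 0.02

    def test_cycle_time_identities(self):
        x, _ = source_trace("arc", 10.0, asym=0.3)
        ct = sk.segment_cycles(x, FS, 10.0)
        assert np.allclose(
            ct["period"], ct["peak_time"] + ct["trough_time"], atol=1.5 / FS
        )
        assert np.allclose(
            ct["period"], ct["rise_time"] + ct["decay_time"], atol=1.5 / FS
        )
        idx = ct[["rise_zc", "peak", "fall_zc", "trough", "next_rise_zc"]].to_numpy()
        assert np.all(np.diff(idx, axis=1) >= 0)
        # contiguous, non-overlapping cycles
        assert np.all(idx[1:, 0] == idx[:-1, -1])

    def test_sawtooth_duty_recovery(self):
        """Rise-decay asymmetry of a fast-rise sawtooth matches the duty
        parameter; band-limiting keeps it accurate at low fundamental."""
        x, _ = source_trace("sawtooth", 5.0, asym=-0.4, duration=40.0)
        ct = sk.segment_cycles(x, FS, 5.0)
        assert ct["rise_decay_asym"].mean() == pytest.approx(-0.4, abs=0.05)
        assert ct["rise_decay_asym"].mean() < -0.3

    def test_fast_rise_sawtooth_strongly_negative_at_10hz(self):
        x, _ = source_trace("sawtooth", 10.0, asym=-0.6, duration=40.0)
        ct = sk.segment_cycles(x, FS, 10.0)
        assert ct["rise_decay_asym"].mean() < -0.3

    def test_arc_duty_recovery(self):
        x, _ = source_trace("arc", 6.0, asym=0.3, duration=40.0)
        ct = sk.segment_cycles(x, FS, 6.0)
        assert ct["peak_trough_asym"].mean() == pytest.approx(0.3, abs=0.05)

    def test_negation_flips_peak_trough_sign(self):
        x, _ = source_trace("arc", 6.0, asym=0.3, duration=40.0)
        a = sk.segment_cycles(x, FS, 6.0)["peak_trough_asym"].mean()
        b = sk.segment_cycles(-x, FS, 6.0)["peak_trough_asym"].mean()
        assert b == pytest.approx(-a, abs=0.02)

    def test_time_reversal_flips_rise_decay(self):
        x, _ = source_trace("sawtooth", 5.0, asym=-0.4, duration=40.0)
        fwd = sk.segment_cycles(x, FS, 5.0)
        rev = sk.segment_cycles(x[::-1].copy(), FS, 5.0)
        assert rev["rise_decay_asym"].mean() == pytest.approx(
            -fwd["rise_decay_asym"].mean(), abs=0.02
        )
        assert abs(rev["peak_trough_asym"]).mean() == pytest.approx(
            abs(fwd["peak_trough_asym"]).mean(), abs=0.02
        )

    def test_too_short_series_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            sk.segment_cycles(np.zeros(200), FS, 10.0)

    def test_narrowband_below_zero_is_error(self):
        with pytest.raises(ValueError, match="half-width"):
            sk.segment_cycles(np.zeros(100_000), FS, 2.0)


class TestBurstMask:
    def test_continuous_oscillation_all_interior_burst(self):
        t = np.arange(0, 20, 1 / FS)
        ct = sk.burst_mask(sk.segment_cycles(np.sin(2 * np.pi * 10 * t), FS, 10.0))
        # the 1 Hz high-pass edge transient suppresses ~1 s at each end
        assert ct["is_burst"].iloc[12:-12].all()

    def test_short_runs_rejected(self):
        """Two isolated strong cycles in noise never form a burst."""
        rng = np.random.default_rng(2)
        x = 0.25 * _pink_noise(30_000, FS, 1.0, rng)
        t = np.arange(x.size) / FS
        for t0 in (8.0, 20.0):
            m = (t >= t0) & (t < t0 + 0.2)  # two cycles at 10 Hz
            x[m] += 3.0 * np.sin(2 * np.pi * 10 * (t[m] - t0))
        ct = sk.burst_mask(sk.segment_cycles(x, FS, 10.0))
        assert not ct["is_burst"].any()

    def test_ground_truth_hit_and_false_positive_rates(self):
        """Detected burst cycles overlap the generator's plateau windows."""
        rng = np.random.default_rng(103)
        x, windows = source_trace(
            "sinusoid", 10.0, duration=120.0, seed=3, burst=(0.12, 1.5)
        )
        x = x + 0.2 * _pink_noise(x.size, FS, 2.0, rng)
        ct = sk.burst_mask(sk.segment_cycles(x, FS, 10.0))
        t = ct["time_s"].to_numpy()
        in_win = np.zeros(len(ct), dtype=bool)
        for a, b in windows:
            in_win |= (t >= a) & (t <= b)
        hit_rate = ct["is_burst"][in_win].mean()
        fp_rate = ct["is_burst"][~in_win].mean()
        assert hit_rate >= 0.8
        assert fp_rate <= 0.1

    def test_amplitude_threshold_monotone(self):
        x, _ = source_trace("sinusoid", 10.0, duration=60.0, burst=(0.2, 1.5))
        rng = np.random.default_rng(4)
        ct = sk.segment_cycles(x + 0.2 * _pink_noise(x.size, FS, 2.0, rng), FS, 10.0)
        counts = [
            sk.burst_mask(ct, amp_fraction_threshold=f)["is_burst"].sum()
            for f in np.linspace(0.1, 0.95, 10)
        ]
        assert np.all(np.diff(counts) <= 0)


class TestSummarizeBursts:
    def test_means_over_burst_cycles_only(self):
        t = np.arange(0, 20, 1 / FS)
        ct = sk.burst_mask(sk.segment_cycles(np.sin(2 * np.pi * 10 * t), FS, 10.0))
        out = sk.summarize_bursts(ct)
        assert out["n_burst_cycles"] > 0
        assert out["frequency_hz"] == pytest.approx(10.0, abs=0.1)
        assert out["amplitude"] == pytest.approx(2.0, abs=0.1)

    def test_no_bursts_flagged_absent(self):
        rng = np.random.default_rng(6)
        x = 0.2 * _pink_noise(30_000, FS, 1.0, rng)
        ct = sk.burst_mask(sk.segment_cycles(x, FS, 10.0), min_n_cycles=50)
        out = sk.summarize_bursts(ct)
        assert out["n_burst_cycles"] == 0 and np.isnan(out["amplitude"])

    def test_arc_rhythm_asymmetry_recovery(self):
        """Mean peak-trough asymmetry over burst cycles of a bursty
        arc-shaped rhythm recovers the generator's duty parameter."""
        rng = np.random.default_rng(9)
        x, _ = source_trace("arc", 6.0, asym=0.3, duration=120.0, seed=5,
                            burst=(0.12, 2.0))
        x = x + 0.1 * _pink_noise(x.size, FS, 2.0, rng)
        ct = sk.burst_mask(sk.segment_cycles(x, FS, 6.0))
        out = sk.summarize_bursts(ct)
        assert out["peak_trough_asym"] == pytest.approx(0.3, abs=0.05)
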