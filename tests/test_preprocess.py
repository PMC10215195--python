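"""Preprocessing: zero-phase high-pass, phase->time-of-flight, optical density."""

import numpy as np
import pytest

from fosdecode import (
    BlockRecording,
    InstrumentConfig,
    dc_to_optical_density,
    highpass_zero_phase,
    phase_to_tof,
    preprocess_block,
)
from fosdecode.preprocess import design_highpass
from fosdecode.errors import ConfigurationError, DataError

FS = 39.0625


class TestHighpass:
    def test_constant_input_rejected_to_zero(self):
        c = np.full(int(FS * 60), 5.0)
        y = highpass_zero_phase(c, FS)
        assert np.abs(y).max() < 1e-6 * 5.0

    def test_slow_drift_attenuated_40db(self):
        t = np.arange(int(FS * 300)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        y = highpass_zero_phase(x, FS)
        core = slice(2000, -2000)  # steady state
        atten_db = 20 * np.log10(y[core].std() / x[core].std())
        assert atten_db <= -40.0

    def test_passband_tone_unity_gain_zero_lag(self):
        t = np.arange(int(FS * 60)) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        y = highpass_zero_phase(x, FS)
        core = slice(500, -500)
        gain = y[core].std() / x[core].std()
        assert gain == pytest.approx(1.0, abs=0.05)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (len(x[core]) - 1)
        assert lag == 0

    def test_too_short_signal_raises(self):
        with pytest.raises(DataError, match="too short"):
            highpass_zero_phase(np.random.default_rng(0).standard_normal(50), FS)

    def test_linearity(self):
        r = np.random.default_rng(1)
        x = r.standard_normal(2000)
        np.testing.assert_allclose(
            highpass_zero_phase(3.5 * x, FS),
            3.5 * highpass_zero_phase(x, FS),
            rtol=1e-10,
        )

    def test_dc_response_exactly_zero(self):
        taps = design_highpass(FS)
        assert abs(taps.sum()) < 1e-15


class TestPhaseToTof:
    def test_zero_phase_zero_time(self):
        assert phase_to_tof(0.0, 110e6) == 0.0

    def test_full_cycle_equals_modulation_period(self):
        assert phase_to_tof(360.0, 110e6) == pytest.approx(1.0 / 110e6)
        assert phase_to_tof(360.0, 110e6) == pytest.approx(9.0909e-9, rel=1e-4)

    def test_one_degree(self):
        assert phase_to_tof(1.0, 110e6) == pytest.approx(2.5253e-11, rel=1e-4)

    def test_elementwise_linear(self):
        ph = np.array([[0.0, 1.0], [2.0, -3.0]])
        np.testing.assert_allclose(phase_to_tof(ph, 110e6), ph / (360.0 * 110e6))

    def test_invalid_modulation_frequency(self):
        with pytest.raises(ConfigurationError):
            phase_to_tof(1.0, 0.0)


class TestOpticalDensity:
    def test_constant_at_block_mean_is_zero(self):
        dc = np.full(100, 3.7)
        np.testing.assert_allclose(dc_to_optical_density(dc), 0.0, atol=1e-15)

    def test_decade_up_is_plus_one(self):
        dc = np.ones(10)
        assert dc_to_optical_density(dc, block_mean=0.1)[0] == pytest.approx(1.0)

    def test_decade_down_is_minus_one(self):
        dc = np.ones(10)
        assert dc_to_optical_density(dc, block_mean=10.0)[0] == pytest.approx(-1.0)

    def test_non_positive_sample_identified(self):
        dc = np.ones((2, 5))
        dc[1, 3] = 0.0
        with pytest.raises(DataError, match=r"\(1, 3\)"):
            dc_to_optical_density(dc)


def _make_block(dc, ph, fs=FS):
    return BlockRecording(
        subject_id="s0",
        block_id="b0",
        dc=dc,
        ph=ph,
        instrument=InstrumentConfig(sampling_rate=fs),
    )


class TestPreprocessBlock:
    def test_shape_preserved(self):
        r = np.random.default_rng(0)
        n = int(FS * 30)
        dc = 1e6 * np.exp(1e-3 * r.standard_normal((3, n)))
        ph = 40.0 + 0.1 * r.standard_normal((3, n))
        fos = preprocess_block(_make_block(dc, ph))
        assert fos.fos_dc.shape == (3, n)
        assert fos.fos_tof.shape == (3, n)

    def test_drift_block_mostly_removed(self):
        t = np.arange(int(FS * 120)) / FS
        od_drift = 5e-3 * np.sin(2 * np.pi * 0.05 * t)
        dc = 1e6 * 10.0**od_drift
        fos = preprocess_block(_make_block(dc[None, :], np.zeros_like(dc)[None, :] + 30))
        od = np.log10(dc / dc.mean())
        assert fos.fos_dc.std() < 0.05 * od.std()

    def test_planted_phase_tone_amplitude(self):
        # 5 Hz, 0.1 deg amplitude -> time-of-flight tone of 0.1/(360*110e6) s
        t = np.arange(int(FS * 60)) / FS
        ph = 25.0 + 0.1 * np.sin(2 * np.pi * 5.0 * t)
        dc = np.full_like(ph, 1e6)
        fos = preprocess_block(_make_block(dc[None, :], ph[None, :]))
        core = slice(500, -500)
        amp = np.sqrt(2.0) * fos.fos_tof[0, core].std()
        assert amp == pytest.approx(0.1 / (360 * 110e6), rel=0.05)
        assert amp == pytest.approx(2.525e-12, rel=0.05)

    def test_filtered_means_near_zero(self):
        r = np.random.default_rng(2)
        n = int(FS * 60)
        dc = 1e6 * np.exp(2e-3 * r.standard_normal((4, n)).cumsum(axis=1) / np.sqrt(n))
        ph = 10.0 + 0.5 * r.standard_normal((4, n))
        fos = preprocess_block(_make_block(dc, ph))
        for x in (fos.fos_dc, fos.fos_tof):
            m = np.abs(x.mean(axis=1))
            assert np.all(m < 1e-6 * x.std(axis=1))

    def test_filter_after_log_equals_direct_filtering(self):
        # the DC pathway is literally highpass(log10(dc/mean)); assert it
        r = np.random.default_rng(3)
        n = int(FS * 30)
        dc = 1e6 * np.exp(1e-3 * r.standard_normal((2, n)))
        block = _make_block(dc, np.zeros_like(dc) + 5.0)
        fos = preprocess_block(block)
        od = np.log10(dc / dc.mean(axis=1, keepdims=True))
        np.testing.assert_array_equal(fos.fos_dc, highpass_zero_phase(od, FS))

    def test_non_positive_dc_rejected_at_construction(self):
        dc = np.ones((2, 100))
        dc[0, 7] = -1.0
        with pytest.raises(DataError, match="non-positive DC"):
            _make_block(dc, np.zeros_like(dc))
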