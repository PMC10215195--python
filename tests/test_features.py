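"""Wavelet-coherence features: contracts and Monte-Carlo properties."""

import numpy as np
import pytest

from fosdecode import (
    CoherenceMap,
    StimulusProtocol,
    WaveletSpec,
    channel_average_reference,
    wavelet_coherence,
    window_feature,
)
from fosdecode.features import _coherence_batch, extract_features
from fosdecode.errors import FeatureError

FS = 39.0625


def tone(freq, n=20, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestReference:
    def test_identical_channels_give_any_channel(self):
        x = np.tile(tone(10), (5, 1))
        np.testing.assert_allclose(channel_average_reference(x), x[0])

    def test_opposite_channels_cancel(self):
        x = tone(8)
        np.testing.assert_allclose(
            channel_average_reference(np.vstack([x, -x])), 0.0, atol=1e-15
        )

    def test_variance_shrinks_as_one_over_c(self):
        r = np.random.default_rng(0)
        c = 64
        x = r.standard_normal((c, 5000))
        x = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        v = channel_average_reference(x).var()
        assert v == pytest.approx(1.0 / c, rel=0.15)

    def test_single_channel_rejected(self):
        with pytest.raises(FeatureError, match="at least 2"):
            channel_average_reference(tone(5)[None, :])


class TestWaveletCoherence:
    def test_self_coherence_is_one_in_coi(self):
        x = np.random.default_rng(1).standard_normal(20)
        c = wavelet_coherence(x, x, sampling_rate=FS)
        assert c.values[c.coi].min() >= 0.99

    def test_values_bounded(self):
        r = np.random.default_rng(2)
        for _ in range(20):
            c = wavelet_coherence(
                r.standard_normal(20), r.standard_normal(20), sampling_rate=FS
            )
            assert np.all(c.values >= 0.0) and np.all(c.values <= 1.0)

    def test_delay_does_not_destroy_tone_coherence(self):
        # on a longer window, where 5 Hz lies inside the COI, a 2-sample
        # delay shifts phase but not coherence magnitude
        n = 64
        full = tone(5.0, n + 2)
        r = np.random.default_rng(3)
        c = wavelet_coherence(
            full[:n] + 0.01 * r.standard_normal(n),
            full[2 : n + 2] + 0.01 * r.standard_normal(n),
            sampling_rate=FS,
        )
        j = np.argmin(np.abs(c.frequencies - 5.0))
        assert c.coi[j].any()
        assert c.values[j][c.coi[j]].mean() >= 0.9

    def test_independent_noise_within_monte_carlo_null_band(self):
        # the observed mean in-COI coherence of one noise pair must sit
        # inside the 95% band of its own 1000-draw null distribution
        r = np.random.default_rng(4)
        null = np.array(
            [
                window_feature(
                    wavelet_coherence(
                        r.standard_normal(20), r.standard_normal(20), sampling_rate=FS
                    )
                )
                for _ in range(1000)
            ]
        )
        obs = window_feature(
            wavelet_coherence(
                np.random.default_rng(99).standard_normal(20),
                np.random.default_rng(100).standard_normal(20),
                sampling_rate=FS,
            )
        )
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= obs <= hi
        assert null.mean() < 0.95  # well below perfect coherence

    def test_zero_variance_input_rejected(self):
        with pytest.raises(FeatureError, match="zero-variance"):
            wavelet_coherence(np.ones(20), tone(10), sampling_rate=FS)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(FeatureError):
            wavelet_coherence(tone(10, 20), tone(10, 21), sampling_rate=FS)


class TestWindowFeature:
    def _map(self, values):
        v = np.asarray(values, dtype=float)
        return CoherenceMap(
            values=v, coi=np.ones_like(v, bool), frequencies=np.ones(v.shape[0])
        )

    def test_constant_one_gives_one(self):
        assert window_feature(self._map(np.ones((3, 5)))) == 1.0

    def test_constant_zero_gives_zero(self):
        assert window_feature(self._map(np.zeros((3, 5)))) == 0.0

    def test_half_half_gives_half(self):
        v = np.zeros((2, 4))
        v[0] = 1.0
        assert window_feature(self._map(v)) == 0.5

    def test_empty_coi_raises_with_advice(self):
        m = self._map(np.ones((2, 4)))
        m.coi[:] = False
        with pytest.raises(FeatureError, match="finer scales"):
            window_feature(m)


class TestBatchProperties:
    def test_shared_tone_all_features_high(self):
        r = np.random.default_rng(5)
        data = np.vstack([tone(10.0) + 0.01 * r.standard_normal(20) for _ in range(7)])
        coh, coi = _coherence_batch(
            data, channel_average_reference(data), WaveletSpec(), FS
        )
        assert coh[:, coi].mean(axis=1).min() >= 0.9

    def test_noise_channel_is_row_minimum(self):
        # 200-window Monte-Carlo: an independent-noise channel among
        # tone-locked channels has the smallest feature >= 95% of the time
        r = np.random.default_rng(42)
        spec = WaveletSpec()
        hits = 0
        for _ in range(200):
            data = np.vstack(
                [tone(10.0) + 0.05 * r.standard_normal(20) for _ in range(7)]
                + [r.standard_normal(20)]
            )
            coh, coi = _coherence_batch(data, channel_average_reference(data), spec, FS)
            hits += coh[:, coi].mean(axis=1).argmin() == 7
        assert hits / 200 >= 0.95

    def test_amplitude_invariance(self):
        r = np.random.default_rng(6)
        spec = WaveletSpec()
        data = np.vstack([tone(10.0) + 0.05 * r.standard_normal(20) for _ in range(6)])
        coh, coi = _coherence_batch(data, channel_average_reference(data), spec, FS)
        f0 = coh[0][coi].mean()
        scaled = data.copy()
        scaled[0] *= 7.0
        coh2, _ = _coherence_batch(scaled, channel_average_reference(scaled), spec, FS)
        assert abs(coh2[0][coi].mean() - f0) < 0.05

    def test_synchronization_monotone_in_mixing_weight(self):
        # mean feature of a channel subset sharing a waveform at weight w
        # is nondecreasing in w (100 windows per w)
        spec = WaveletSpec()
        means = []
        for w in (0.0, 0.25, 0.5, 1.0):
            r = np.random.default_rng(7)
            feats = []
            for _ in range(100):
                common = r.standard_normal(20)
                noise = r.standard_normal((6, 20))
                data = w * common + (1.0 - w) * noise
                if w == 1.0:
                    data = np.tile(common, (6, 1)) + 1e-9 * noise
                coh, coi = _coherence_batch(
                    data, channel_average_reference(data), spec, FS
                )
                feats.append(coh[:, coi].mean())
            means.append(np.mean(feats))
        assert all(b >= a - 0.01 for a, b in zip(means[:-1], means[1:]))
        assert means[-1] > means[0]


class TestExtractFeatures:
    def test_output_shape_and_bounds(self, tiny_cohort, default_montage):
        from fosdecode import attach_windows, preprocess_block, segment_trials

        cfg, proto, recs = tiny_cohort
        fos = preprocess_block(recs[0])
        trials = segment_trials(fos, proto)
        attach_windows(trials, fos.sampling_rate, fos.t0_offset, fos.n_samples)
        idx = default_montage.channel_indices(830)
        fm = extract_features(trials[:10], fos, channel_indices=idx)
        assert fm.values.shape == (10, 128)
        assert np.all(fm.values >= 0.0) and np.all(fm.values <= 1.0)

    def test_unattached_window_rejected(self, tiny_cohort):
        from fosdecode import preprocess_block, segment_trials

        cfg, proto, recs = tiny_cohort
        fos = preprocess_block(recs[0])
        trials = segment_trials(fos, proto)
        with pytest.raises(FeatureError, match="no attached window"):
            extract_features(trials[:2], fos)
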