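"""Wavelet-coherence features: per trial window, per channel.

The classifier input for one trial is, for every optical channel, the
average modulus of the wavelet coherence between that channel and the
average signal over all channels, computed inside the trial's 20-sample
(512 ms) window.

The continuous wavelet transform uses the analytic Morlet wavelet
(center frequency omega0 = 6) evaluated in the frequency domain on a
zero-padded FFT grid — the standard Torrence-Compo construction. The
coherence of signals x and y at scale s and time t is

    C^2 = |S(W_x W_y* / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where S is a smoothing operator over time (boxcar of about one scale
length) and scale (boxcar over adjacent scales). Smoothing is essential:
without it the ratio is identically 1. The reported "modulus" feature is
C (the coherency magnitude, in [0, 1]); a config switch selects C^2.

Averaging is restricted to points inside the cone of influence (COI) —
closer to the window edges than the wavelet e-folding time sqrt(2)*s,
estimates are dominated by edge effects and are excluded. On a 20-sample
window only scales with pseudo-frequency above roughly 5.5 Hz have any
in-COI points; coarser scales simply do not contribute to the average
(the 512 ms window is the shortest for which the COI covers a useful part
of two concatenated 400 ms trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import FeatureError
from .preprocess import FosBlock
from .segmentation import TrialWindow

__all__ = [
    "WaveletSpec",
    "CoherenceMap",
    "FeatureMatrix",
    "channel_average_reference",
    "wavelet_coherence",
    "window_feature",
    "extract_features",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet wavelet and smoothing parameters for coherence estimation.

    ``n_scales`` pseudo-frequencies are log-spaced over
    [``freq_min``, ``freq_max``] Hz; the band must sit between the
    high-pass cutoff and the Nyquist frequency. ``scale_smooth_width`` is
    the boxcar length (in scales) of the scale-axis smoothing;
    ``squared`` selects magnitude-squared coherence instead of the
    magnitude; ``coi_only=False`` averages over the full map.
    """

    omega0: float = 6.0
    n_scales: int = 12
    freq_min: float = 2.0
    freq_max: float = 19.0
    scale_smooth_width: int = 3
    squared: bool = False
    coi_only: bool = True

    def __post_init__(self) -> None:
        if self.n_scales < 4:
            raise FeatureError("need at least 4 scales")
        if not 0 < self.freq_min < self.freq_max:
            raise FeatureError("need 0 < freq_min < freq_max")

    @property
    def fourier_factor(self) -> float:
        """Pseudo-frequency = fourier_factor / scale (scale in seconds)."""
        return (self.omega0 + np.sqrt(2.0 + self.omega0**2)) / (4.0 * np.pi)

    def frequencies(self) -> np.ndarray:
        """Pseudo-frequencies in Hz, descending (coarse scales last)."""
        return np.geomspace(self.freq_max, self.freq_min, self.n_scales)

    def scales(self, sampling_rate: float) -> np.ndarray:
        """Wavelet scales in seconds, ascending, matching :meth:`frequencies`."""
        if self.freq_max > sampling_rate / 2.0:
            raise FeatureError("freq_max exceeds the Nyquist frequency")
        return self.fourier_factor / self.frequencies()


@dataclass
class CoherenceMap:
    """Wavelet coherence of one signal pair on one window.

    ``values``: (n_scales, n_times) coherence in [0, 1];
    ``coi``: boolean mask of points inside the cone of influence;
    ``frequencies``: pseudo-frequency per scale row, Hz.
    """

    values: np.ndarray
    coi: np.ndarray
    frequencies: np.ndarray


@dataclass
class FeatureMatrix:
    """Trials x channels coherence features with labels and subject ids."""

    values: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.values, columns=[f"ch{c}" for c in range(self.n_channels)]
        )
        df.insert(0, "subject", self.subjects)
        df.insert(1, "label", self.labels)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def channel_average_reference(window_data: np.ndarray) -> np.ndarray:
    """Unweighted mean over channels at each sample (the common reference)."""
    window_data = np.asarray(window_data, dtype=float)
    if window_data.ndim != 2 or window_data.shape[0] < 2:
        raise FeatureError("need at least 2 channels to form a reference")
    return window_data.mean(axis=0)


def _morlet_cwt(x: np.ndarray, dt: float, scales: np.ndarray, omega0: float) -> np.ndarray:
    """Batched analytic-Morlet CWT, frequency-domain implementation.

    ``x``: (..., n) real signals (mean-removed internally);
    returns complex coefficients of shape (..., n_scales, n).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    xh = np.fft.fft(x - x.mean(axis=-1, keepdims=True), nfft, axis=-1)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, dt)
    # analytic Morlet: support on positive frequencies only
    som = scales[:, None] * omega[None, :]
    psi = (np.pi**-0.25) * np.exp(-0.5 * (som - omega0) ** 2) * (omega[None, :] > 0)
    norm = np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    W = np.fft.ifft(xh[..., None, :] * (norm * psi), axis=-1)
    return W[..., :n]


def _smooth(P: np.ndarray, scales: np.ndarray, dt: float, scale_width: int) -> np.ndarray:
    """Smoothing operator S: per-scale time boxcar (~one scale length,
    minimum 3 samples) then a boxcar across adjacent scales."""
    out = np.empty_like(P)
    for j, s in enumerate(scales):
        size = max(3, int(round(s / dt)) | 1)
        out[..., j, :] = uniform_filter1d(P[..., j, :], size=size, axis=-1, mode="nearest")
    if scale_width > 1:
        out = uniform_filter1d(out, size=scale_width, axis=-2, mode="nearest")
    return out


def _coi_mask(n: int, dt: float, scales: np.ndarray) -> np.ndarray:
    """(n_scales, n) mask: True where the point is farther from both window
    edges than the wavelet e-folding time sqrt(2) * scale."""
    i = np.arange(n)
    dist = np.minimum(i, n - 1 - i) * dt
    return dist[None, :] >= (np.sqrt(2.0) * scales)[:, None]


def _coherence_batch(
    data: np.ndarray, ref: np.ndarray, spec: WaveletSpec, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence of each row of ``data`` (C, n) against ``ref`` (n,).

    Returns (values, coi): values (C, n_scales, n) in [0, 1].
    """
    dt = 1.0 / sampling_rate
    scales = spec.scales(sampling_rate)
    stacked = np.vstack([data, ref[None, :]])
    W = _morlet_cwt(stacked, dt, scales, spec.omega0)  # (C+1, S, n)
    Wx, Wy = W[:-1], W[-1]
    inv_s = 1.0 / scales[None, :, None]
    Sxy = _smooth(Wx * np.conj(Wy)[None] * inv_s, scales, dt, spec.scale_smooth_width)
    Sxx = _smooth((np.abs(Wx) ** 2) * inv_s, scales, dt, spec.scale_smooth_width)
    Syy = _smooth((np.abs(Wy)[None] ** 2) * inv_s, scales, dt, spec.scale_smooth_width)
    denom = Sxx * Syy
    if np.any(denom <= 0):
        raise FeatureError("zero-variance input: wavelet coherence is undefined")
    coh2 = np.abs(Sxy) ** 2 / denom
    np.clip(coh2, 0.0, 1.0, out=coh2)
    values = coh2 if spec.squared else np.sqrt(coh2)
    return values, _coi_mask(data.shape[-1], dt, scales)


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    spec: WaveletSpec | None = None,
    sampling_rate: float = 39.0625,
) -> CoherenceMap:
    """Wavelet coherence map of two equal-length 1-D signals.

    Raises :class:`FeatureError` for zero-variance inputs (coherence is
    undefined there).
    """
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FeatureError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FeatureError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FeatureError("zero-variance input: wavelet coherence is undefined")
    values, coi = _coherence_batch(x[None, :], y, spec, sampling_rate)
    return CoherenceMap(values=values[0], coi=coi, frequencies=spec.frequencies())


def window_feature(coh: CoherenceMap, coi_only: bool = True) -> float:
    """Mean coherence modulus over the (in-COI) time-frequency points."""
    mask = coh.coi if coi_only else np.ones_like(coh.coi, dtype=bool)
    if not mask.any():
        raise FeatureError(
            "cone of influence is empty for this window; use finer scales "
            "(higher pseudo-frequencies) or a longer window"
        )
    return float(coh.values[mask].mean())


def extract_features(
    windows: Sequence[TrialWindow],
    fos: FosBlock,
    spec: WaveletSpec | None = None,
    signal: str = "DC",
    channel_indices: np.ndarray | None = None,
    label_map: dict | None = None,
) -> FeatureMatrix:
    """One feature row per trial window, one column per channel.

    Entry (i, c) is the mean in-COI coherence modulus between channel c and
    the all-channel average, both restricted to window i. The reference is
    recomputed per window and includes channel c itself.

    ``signal`` selects the DC (optical density) or PH (time-of-flight)
    pathway; ``channel_indices`` restricts the channels (e.g. to one
    wavelength); ``label_map`` maps :class:`Quadrant` to {0, 1} class
    labels (rows with labels outside the map are an error — filter the
    windows first).
    """
    spec = spec or WaveletSpec()
    sig = {"DC": fos.fos_dc, "PH": fos.fos_tof}.get(signal.upper())
    if sig is None:
        raise FeatureError(f"unknown signal type {signal!r} (use 'DC' or 'PH')")
    if channel_indices is not None:
        sig = sig[np.asarray(channel_indices)]
    n_ch = sig.shape[0]

    values = np.empty((len(windows), n_ch))
    labels = np.empty(len(windows), dtype=int)
    subjects = np.empty(len(windows), dtype=object)
    for i, tr in enumerate(windows):
        if tr.window_start is None:
            raise FeatureError(f"trial {tr.trial_index} has no attached window")
        data = sig[:, tr.window_start : tr.window_stop]
        try:
            ref = channel_average_reference(data)
            coh, coi = _coherence_batch(data, ref, spec, fos.sampling_rate)
        except FeatureError as exc:
            raise FeatureError(
                f"window {i} (trial {tr.trial_index}): {exc}"
            ) from exc
        mask = coi if spec.coi_only else np.ones_like(coi, dtype=bool)
        if not mask.any():
            raise FeatureError(
                f"window {i}: cone of influence empty; use finer scales"
            )
        values[i] = coh[:, mask].mean(axis=1)
        if label_map is not None:
            if tr.label not in label_map:
                raise FeatureError(
                    f"trial {tr.trial_index} label {tr.label.value!r} not in contrast"
                )
            labels[i] = label_map[tr.label]
        else:
            labels[i] = -1
        subjects[i] = tr.subject_id
    return FeatureMatrix(
        values=values,
        labels=labels,
        subjects=subjects,
        meta={"signal": signal, "spec": spec},
    )
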