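"""Raw frequency-domain optical signals -> fast-optical-signal time courses.

Three transformations:

* a zero-phase FIR high-pass at 2 Hz (windowed-sinc, applied
  forward-backward) removing drifts, hemodynamics and most cardiac power;
* phase-to-time-of-flight conversion: a phase change of dPH degrees at
  modulation frequency f corresponds to a mean photon time-of-flight change
  of ``dt = dPH / (360 * f)`` seconds;
* intensity-to-optical-density conversion: ``log10(DC / DC_block_mean)``,
  the log-ratio of detected intensity to its whole-block average (positive
  values = intensity increase; the sign is kept as printed, not negated
  into conventional delta-OD).

The optical-density conversion uses the *unfiltered* block-mean DC and the
high-pass is applied to the log-ratio trace. Because both the log-ratio map
(given a fixed block mean) and the filter are applied samplewise /
linearly, this equals filtering the log-ratio signal directly; the
alternative order (filter raw DC first) differs only in the zero-frequency
term the filter removes anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, DataError
from .protocol import InstrumentConfig

__all__ = [
    "BlockRecording",
    "FosBlock",
    "design_highpass",
    "highpass_zero_phase",
    "phase_to_tof",
    "dc_to_optical_density",
    "preprocess_block",
]

DEFAULT_CUTOFF_HZ = 2.0
#: transition-band width targeted by the windowed-sinc design, Hz
TRANSITION_HZ = 1.0


@dataclass
class BlockRecording:
    """One continuous recording block for one subject.

    ``dc``/``ac``/``ph`` are ``(n_channels, n_samples)`` arrays: detected
    mean intensity (arbitrary detector counts, strictly positive), modulated
    amplitude (optional, never analyzed downstream) and phase delay in
    degrees. ``t0_offset`` is the stimulus onset relative to the start of
    the recording (the block begins 1 s before stimulation by default).
    ``channels`` optionally carries the montage channel table aligned with
    the array rows.
    """

    subject_id: str
    block_id: str
    dc: np.ndarray
    ph: np.ndarray
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    ac: Optional[np.ndarray] = None
    t0_offset: float = 1.0
    channels: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.dc = np.asarray(self.dc, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.dc.ndim != 2 or self.ph.shape != self.dc.shape:
            raise DataError("dc and ph must be 2-D arrays of identical shape")
        if self.ac is not None:
            self.ac = np.asarray(self.ac, dtype=float)
            if self.ac.shape != self.dc.shape:
                raise DataError("ac must match dc/ph shape")
        if not np.all(self.dc > 0):
            ch, ix = np.argwhere(self.dc <= 0)[0]
            raise DataError(
                f"non-positive DC intensity at channel {ch}, sample {ix}; "
                "optical-density conversion requires DC > 0"
            )

    @property
    def n_channels(self) -> int:
        return self.dc.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dc.shape[1]


@dataclass
class FosBlock:
    """High-passed fast-optical-signal time courses for one block.

    ``fos_dc`` is in optical-density units (log10 ratio), ``fos_tof`` in
    seconds of mean photon time-of-flight change. Shapes match the source
    :class:`BlockRecording`.
    """

    subject_id: str
    block_id: str
    fos_dc: np.ndarray
    fos_tof: np.ndarray
    sampling_rate: float
    t0_offset: float = 1.0
    channels: Optional[pd.DataFrame] = None

    @property
    def n_channels(self) -> int:
        return self.fos_dc.shape[0]

    @property
    def n_samples(self) -> int:
        return self.fos_dc.shape[1]


@lru_cache(maxsize=8)
def design_highpass(
    sampling_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    transition: float = TRANSITION_HZ,
) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR high-pass taps.

    The order targets a ~``transition``-Hz transition band at the given
    sampling rate. The taps are mean-corrected so the response at DC is
    exactly zero, making constant inputs map to (numerically) zero output.
    """
    if sampling_rate <= 2 * cutoff:
        raise ConfigurationError("sampling_rate must exceed twice the cutoff")
    numtaps = int(np.ceil(3.3 * sampling_rate / transition))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    taps = sps.firwin(numtaps, cutoff, fs=sampling_rate, pass_zero=False, window="hamming")
    return taps - taps.mean()


def highpass_zero_phase(
    x: np.ndarray,
    sampling_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase high-pass: the FIR filter run forward then backward.

    Forward-backward application cancels the (linear) phase of the FIR, so
    passband components come out with zero group delay; the amplitude
    response is squared. Edges are handled with even reflection padding.
    """
    x = np.asarray(x, dtype=float)
    taps = design_highpass(sampling_rate, cutoff)
    n = x.shape[axis]
    if n <= 3 * len(taps):
        raise DataError(
            f"signal length {n} too short for zero-phase filtering "
            f"(need > {3 * len(taps)} samples at order {len(taps) - 1})"
        )
    y = sps.filtfilt(taps, [1.0], x, axis=axis, padtype="even")
    # the designed filter is exactly DC-blocking; remove the tiny residual
    # mean that reflect-padding leaks in at the block edges
    return y - y.mean(axis=axis, keepdims=True)


def phase_to_tof(delta_ph, modulation_frequency: float):
    """Phase change (degrees) -> mean photon time-of-flight change (seconds).

    One full modulation cycle of phase (360 deg) equals one modulation
    period, so ``dt = dPH / (360 * f_mod)``, elementwise and linear.
    """
    if modulation_frequency <= 0:
        raise ConfigurationError("modulation_frequency must be positive")
    return np.asarray(delta_ph, dtype=float) / (360.0 * modulation_frequency)


def dc_to_optical_density(dc, block_mean: float | np.ndarray | None = None):
    """Intensity -> optical density: ``log10(dc / block_mean)``.

    ``block_mean`` defaults to the mean of ``dc`` over its last axis (the
    whole-block average); it must be the mean of the *unfiltered* DC.
    Zero where ``dc`` equals the block mean; base 10 by the optical-density
    convention.
    """
    dc = np.asarray(dc, dtype=float)
    if np.any(dc <= 0):
        idx = tuple(int(i) for i in np.argwhere(dc <= 0)[0])
        raise DataError(f"non-positive DC sample at index {idx}")
    if block_mean is None:
        block_mean = dc.mean(axis=-1, keepdims=True)
    block_mean = np.asarray(block_mean, dtype=float)
    if np.any(block_mean <= 0):
        raise DataError("block_mean must be positive")
    return np.log10(dc / block_mean)


def preprocess_block(rec: BlockRecording, cutoff: float = DEFAULT_CUTOFF_HZ) -> FosBlock:
    """Full preprocessing of one block: OD conversion + filtering + Eq. of phase.

    ``fos_dc``: per-channel optical density (against the unfiltered
    per-channel block-mean DC), then zero-phase high-passed.
    ``fos_tof``: phase high-passed, then converted to seconds.
    Channel order and array shapes are preserved.
    """
    fs = rec.instrument.sampling_rate
    od = dc_to_optical_density(rec.dc)
    fos_dc = highpass_zero_phase(od, fs, cutoff, axis=-1)
    ph_hp = highpass_zero_phase(rec.ph, fs, cutoff, axis=-1)
    fos_tof = phase_to_tof(ph_hp, rec.instrument.modulation_frequency)
    return FosBlock(
        subject_id=rec.subject_id,
        block_id=rec.block_id,
        fos_dc=fos_dc,
        fos_tof=fos_tof,
        sampling_rate=fs,
        t0_offset=rec.t0_offset,
        channels=rec.channels,
    )
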