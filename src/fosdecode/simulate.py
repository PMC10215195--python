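"""Synthetic frequency-domain optical recordings with planted retinotopy.

The generator emits block recordings with the statistical structure the
analysis assumes, so the whole pipeline is testable without instrument
data:

* slow multiplicative drifts (sub-0.5 Hz sinusoids),
* a cardiac oscillation (~1.2 Hz, below the 2 Hz analysis band),
* per-channel white sensor noise,
* and the decodable effect: every checkerboard reversal (2 x flicker
  rate per second) evokes a brief biphasic response shared across
  channels, weighted per channel by the montage's gain for the currently
  stimulated quadrant. The shared waveform raises inter-channel
  synchronization among quadrant-sensitive channels — exactly the
  quantity the wavelet-coherence feature measures — rather than a raw
  amplitude cue.

DC is modeled multiplicatively, ``DC = baseline * exp(x)``, so the
optical-density conversion linearizes the planted components exactly;
phase is additive in degrees so the time-of-flight conversion is exact.
The 830 nm channels carry a larger effect than 690 nm ones
(``wavelength_gain``), reproducing the qualitative sensitivity ordering
of longer NIR wavelengths. Default amplitudes put the single-trial SNR
well below one — fast optical signals are a low-SNR phenomenon — so
tests that need reliable decoding amplify the effect explicitly.

Everything is reproducible from ``(seed, subject_index)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .montage import Montage, MontageConfig, QUADRANT_ORDER, build_montage
from .preprocess import BlockRecording
from .protocol import InstrumentConfig, StimulusProtocol, label_from_angle, wedge_angle_at
from .segmentation import design_geometry, segment_trials

__all__ = ["GeneratorConfig", "GroundTruth", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Forward-model parameters for the synthetic cohort.

    Amplitudes: ``effect_amplitude_dc`` is the per-event peak deflection in
    natural-log intensity units (order 1e-4, i.e. ~0.01% intensity);
    ``effect_amplitude_ph`` in degrees of phase (order 1e-2). Noise terms
    are per-sample white SDs and drift/cardiac amplitudes in the same
    units; all physiological components sit below the 2 Hz cutoff so the
    high-pass removes them.
    """

    montage: MontageConfig = field(default_factory=MontageConfig)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    n_subjects: int = 6

    effect_amplitude_dc: float = 1e-4
    effect_amplitude_ph: float = 1e-2
    response_latency: float = 0.08
    response_duration: float = 0.1
    wavelength_gain: float = 1.5  # 830 nm effect multiplier vs 690 nm

    noise_dc_sd: float = 3e-4
    noise_ph_sd: float = 3e-2
    drift_amplitude_dc: float = 2e-3
    drift_amplitude_ph: float = 0.2
    drift_corner: float = 0.3
    cardiac_frequency: float = 1.2
    cardiac_amplitude_dc: float = 5e-4
    cardiac_amplitude_ph: float = 5e-2
    subject_gain_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "effect_amplitude_dc",
            "effect_amplitude_ph",
            "noise_dc_sd",
            "noise_ph_sd",
            "drift_amplitude_dc",
            "drift_amplitude_ph",
            "cardiac_amplitude_dc",
            "cardiac_amplitude_ph",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.wavelength_gain <= 0:
            raise ConfigurationError("wavelength_gain must be positive")
        if not 0 < self.drift_corner < 2.0:
            raise ConfigurationError("drift_corner must lie below the 2 Hz cutoff")
        if not 0 < self.cardiac_frequency < 2.0:
            raise ConfigurationError("cardiac_frequency must lie below the 2 Hz cutoff")

    def scaled_effect(self, factor: float) -> "GeneratorConfig":
        """Copy with both effect amplitudes multiplied by ``factor``."""
        return replace(
            self,
            effect_amplitude_dc=self.effect_amplitude_dc * factor,
            effect_amplitude_ph=self.effect_amplitude_ph * factor,
        )


@dataclass
class GroundTruth:
    """What was planted: trial labels, channel gains, event times."""

    trial_labels: list[str]
    quadrant_gain: np.ndarray
    event_times: np.ndarray
    event_quadrants: list[str]


def _response_template(fs: float, duration: float) -> np.ndarray:
    """Smooth biphasic pulse: one sine cycle under a raised-cosine window.

    A parametric stand-in for a fast event-locked optical response; peak
    amplitude normalized to 1.
    """
    n = max(int(round(duration * fs)), 4)
    tau = np.arange(n) / fs
    pulse = np.sin(2.0 * np.pi * tau / duration) * (
        0.5 - 0.5 * np.cos(2.0 * np.pi * tau / duration)
    )
    return pulse / np.abs(pulse).max()


def _event_schedule(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Reversal event times (stimulus clock) and active-quadrant indices."""
    proto = cfg.protocol
    dt_ev = 1.0 / (2.0 * proto.flicker_rate)
    times = np.arange(0.0, proto.stimulus_duration - 1e-9, dt_ev)
    angles = wedge_angle_at(times, proto)
    labels = label_from_angle(angles)
    qidx = np.array([QUADRANT_ORDER.index(l.value) for l in labels])
    return times, qidx


def generate_subject(
    config: GeneratorConfig,
    subject_index: int,
    montage: Montage | None = None,
) -> tuple[BlockRecording, GroundTruth]:
    """One subject's block recording (all 256 channels, DC+AC+PH) + truth.

    Bit-reproducible from ``(config.seed, subject_index)``; the montage is
    shared across the cohort (seeded by ``config.seed`` alone).
    """
    mont = montage or build_montage(config.montage, seed=config.seed)
    proto = config.protocol
    fs = config.instrument.sampling_rate
    n_samples = int(round(proto.total_duration * fs))
    n_ch = mont.n_channels
    rng = np.random.default_rng([config.seed, subject_index])

    t = np.arange(n_samples) / fs

    # -- planted quadrant-locked effect ----------------------------------
    ev_times, ev_quad = _event_schedule(config)
    template = _response_template(fs, config.response_duration)
    impulses = np.zeros((4, n_samples))
    ev_samples = np.round((ev_times + proto.pre_roll + config.response_latency) * fs)
    ev_samples = ev_samples.astype(int)
    keep = ev_samples < n_samples
    np.add.at(impulses, (ev_quad[keep], ev_samples[keep]), 1.0)
    quad_sig = np.apply_along_axis(
        lambda r: np.convolve(r, template)[:n_samples], 1, impulses
    )

    subj_gain = max(0.1, 1.0 + config.subject_gain_sd * rng.standard_normal())
    wl_gain = np.where(
        mont.channels["wavelength"].to_numpy() == 830, config.wavelength_gain, 1.0
    )
    chan_weight = subj_gain * wl_gain[:, None] * mont.quadrant_gain  # (C, 4)
    effect = chan_weight @ quad_sig  # shared waveform, gain-weighted

    # -- nuisance components ---------------------------------------------
    def drifts(amplitude: float) -> np.ndarray:
        freqs = rng.uniform(0.01, config.drift_corner, size=(n_ch, 3))
        phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 3))
        amps = amplitude * rng.uniform(0.3, 1.0, size=(n_ch, 3))
        return np.einsum(
            "cj,cjt->ct", amps, np.sin(2 * np.pi * freqs[..., None] * t + phases[..., None])
        )

    cardiac_f = config.cardiac_frequency * (1.0 + 0.05 * rng.standard_normal())
    cardiac_phase = rng.uniform(0, 2 * np.pi)
    cardiac_wave = np.sin(2 * np.pi * cardiac_f * t + cardiac_phase)

    def cardiac(amplitude: float) -> np.ndarray:
        amps = amplitude * rng.uniform(0.5, 1.5, size=(n_ch, 1))
        return amps * cardiac_wave[None, :]

    x_dc = (
        drifts(config.drift_amplitude_dc)
        + cardiac(config.cardiac_amplitude_dc)
        + config.noise_dc_sd * rng.standard_normal((n_ch, n_samples))
        + config.effect_amplitude_dc * effect
    )
    baseline = 10.0**6 * rng.uniform(0.5, 1.5, size=(n_ch, 1))
    dc = baseline * np.exp(x_dc)

    ph = (
        rng.uniform(0.0, 360.0, size=(n_ch, 1))
        + drifts(config.drift_amplitude_ph)
        + cardiac(config.cardiac_amplitude_ph)
        + config.noise_ph_sd * rng.standard_normal((n_ch, n_samples))
        + config.effect_amplitude_ph * effect
    )

    rec = BlockRecording(
        subject_id=f"sub-{subject_index:02d}",
        block_id="block-01",
        dc=dc,
        ph=ph,
        ac=0.4 * dc,  # carried but never analyzed
        instrument=config.instrument,
        t0_offset=proto.pre_roll,
        channels=mont.channels,
    )
    trials = segment_trials(None, proto, rec.subject_id)
    truth = GroundTruth(
        trial_labels=[tr.label.value for tr in trials],
        quadrant_gain=mont.quadrant_gain,
        event_times=ev_times,
        event_quadrants=[QUADRANT_ORDER[q] for q in ev_quad],
    )
    return rec, truth


def generate_cohort(config: GeneratorConfig, path) -> Path:
    """Write a full synthetic dataset directory.

    Layout: per-subject HDF5 blocks, the montage (TSV + JSON), the config
    echo (YAML) and a ground-truth manifest (JSON) including the
    design-geometry accounting per binary contrast. Deterministic given
    the config seed.
    """
    from .io import write_block

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    mont = build_montage(config.montage, seed=config.seed)
    mont.write_tsv(out / "montage.tsv")
    mont.write_json(out / "montage.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh)

    subjects = []
    truth_common = None
    for s in range(config.n_subjects):
        rec, truth = generate_subject(config, s, montage=mont)
        write_block(out / f"{rec.subject_id}.h5", rec)
        subjects.append(rec.subject_id)
        truth_common = truth

    geom = design_geometry(
        config.protocol,
        config.n_subjects,
        n_channels=config.montage.n_channels_per_wavelength,
    )
    manifest = {
        "subjects": subjects,
        "trial_labels": truth_common.trial_labels if truth_common else [],
        "n_trials_per_subject": len(truth_common.trial_labels) if truth_common else 0,
        "n_trials_total": config.n_subjects
        * (len(truth_common.trial_labels) if truth_common else 0),
        "rows_per_binary_contrast": geom.rows,
        "trials_per_quadrant_pass": geom.trials_per_quadrant_pass,
        "event_times": truth_common.event_times.tolist() if truth_common else [],
        "event_quadrants": truth_common.event_quadrants if truth_common else [],
        "seed": config.seed,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh)
    return out


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = {}
    for k, v in config.__dict__.items():
        if hasattr(v, "__dict__") and not isinstance(v, (int, float, str)):
            d[k] = {
                kk: (vv.value if hasattr(vv, "value") else list(vv) if isinstance(vv, tuple) else vv)
                for kk, vv in v.__dict__.items()
            }
        else:
            d[k] = v
    return d
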