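"""End-to-end decoding runs: preprocess -> segment -> features -> decode -> evaluate.

A run is specified by a :class:`RunConfig`: which binary quadrant contrast
to decode (top vs. bottom or left vs. right), which signal pathway (DC
optical density or PH time of flight) and which wavelength's 128 channels
feed the classifier. :func:`run_pipeline` reads a dataset directory
written by :func:`fosdecode.simulate.generate_cohort` (or any directory of
compatible block files + montage) and writes the feature matrix,
out-of-fold predictions, ROC points and the JSON result;
:func:`decode_recordings` is the in-memory equivalent used by tests and
simulation studies.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decode import ClassifierConfig, cross_validate
from .errors import ConfigurationError
from .evaluate import DecodingResult, evaluate_predictions, per_subject_accuracy
from .features import FeatureMatrix, WaveletSpec, extract_features
from .montage import Montage
from .preprocess import BlockRecording, preprocess_block
from .protocol import Quadrant, StimulusProtocol
from .segmentation import attach_windows, segment_trials

__all__ = ["RunConfig", "CONTRASTS", "run_pipeline", "decode_recordings"]

logger = logging.getLogger(__name__)

#: class-1 quadrant listed first, class-0 second
CONTRASTS = {
    "top_vs_bottom": (Quadrant.TOP, Quadrant.BOTTOM),
    "left_vs_right": (Quadrant.LEFT, Quadrant.RIGHT),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one decoding run depends on."""

    dataset: str = "."
    output: str = "results"
    contrast: str = "top_vs_bottom"
    signal: str = "DC"
    wavelength: int = 830
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_permutations: int = 10_000
    response_time: float = 0.512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ConfigurationError(
                f"contrast must be one of {sorted(CONTRASTS)}, got {self.contrast!r}"
            )
        if self.signal.upper() not in ("DC", "PH"):
            raise ConfigurationError("signal must be 'DC' or 'PH'")
        if self.wavelength not in (690, 830):
            raise ConfigurationError("wavelength must be 690 or 830")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["wavelet"] = dict(self.wavelet.__dict__)
        d["classifier"] = dict(self.classifier.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("wavelet"), dict):
            d["wavelet"] = WaveletSpec(**d["wavelet"])
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def read_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_feature_matrix(
    recordings: list[BlockRecording],
    montage: Montage,
    protocol: StimulusProtocol,
    config: RunConfig,
) -> FeatureMatrix:
    """Preprocess, segment and featurize every subject, then stack rows."""
    pos, neg = CONTRASTS[config.contrast]
    label_map = {pos: 1, neg: 0}
    ch_idx = montage.channel_indices(config.wavelength)
    parts = []
    for rec in recordings:
        fos = preprocess_block(rec)
        trials = segment_trials(fos, protocol)
        attach_windows(trials, fos.sampling_rate, fos.t0_offset, fos.n_samples)
        selected = [tr for tr in trials if tr.label in label_map]
        fm = extract_features(
            selected,
            fos,
            config.wavelet,
            signal=config.signal,
            channel_indices=ch_idx,
            label_map=label_map,
        )
        parts.append(fm)
    return FeatureMatrix(
        values=np.vstack([p.values for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subjects=np.concatenate([p.subjects for p in parts]),
        meta={
            "contrast": config.contrast,
            "signal": config.signal,
            "wavelength": config.wavelength,
        },
    )


def decode_recordings(
    recordings: list[BlockRecording],
    montage: Montage,
    protocol: StimulusProtocol,
    config: RunConfig,
) -> tuple[DecodingResult, FeatureMatrix]:
    """In-memory pipeline run; returns the evaluation and the features."""
    t0 = time.perf_counter()
    fm = build_feature_matrix(recordings, montage, protocol, config)
    logger.info(
        "feature matrix %d x %d (%s, %s, %d nm) in %.1f s",
        fm.n_rows, fm.n_channels, config.contrast, config.signal,
        config.wavelength, time.perf_counter() - t0,
    )
    preds = cross_validate(fm, config.classifier)
    result = evaluate_predictions(
        preds,
        n_permutations=config.n_permutations,
        seed=config.seed,
        response_time=config.response_time,
        meta={**fm.meta, "n_rows": fm.n_rows, "n_channels": fm.n_channels},
    )
    result.meta["per_subject_accuracy"] = {
        str(k): float(v) for k, v in per_subject_accuracy(preds).items()
    }
    result.meta["predictions"] = preds
    return result, fm


def run_pipeline(config: RunConfig) -> DecodingResult:
    """Run one decoding configuration on a dataset directory.

    Expects ``montage.json``, ``config.yaml`` (generator echo, used for the
    protocol) and ``sub-*.h5`` block files as written by
    :func:`fosdecode.simulate.generate_cohort`. Writes ``features.tsv``,
    ``predictions.tsv``, ``roc.tsv``, ``result.json`` and ``run_config.yaml``
    into ``config.output``.
    """
    from .io import read_block

    ds = Path(config.dataset)
    if not ds.is_dir():
        raise ConfigurationError(f"dataset directory {ds} does not exist")
    montage = Montage.read_json(ds / "montage.json")
    with open(ds / "config.yaml") as fh:
        gen_cfg = yaml.safe_load(fh)
    protocol = StimulusProtocol(**gen_cfg["protocol"])
    recordings = [read_block(p) for p in sorted(ds.glob("sub-*.h5"))]
    if not recordings:
        raise ConfigurationError(f"no sub-*.h5 block files under {ds}")

    result, fm = decode_recordings(recordings, montage, protocol, config)

    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    fm.write_tsv(out / "features.tsv")
    preds = result.meta.pop("predictions")
    preds.write_tsv(out / "predictions.tsv")
    result.write_roc_tsv(out / "roc.tsv")
    result.write_json(out / "result.json")
    config.write_yaml(out / "run_config.yaml")
    logger.info(
        "run complete: accuracy %.3f, AUC %.3f (p=%.4g), ITR %.2f bpm",
        result.accuracy, result.auc, result.auc_p, result.itr_bpm,
    )
    return result
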