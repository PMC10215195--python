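"""Cut preprocessed blocks into labeled 400 ms trials with 512 ms windows.

Each quadrant pass (the interval while the wedge center stays inside one
90-degree arc) is tiled from its onset with consecutive 400 ms trials;
the trial label is the quadrant at the trial midpoint, so all trials of a
pass share one label and no trial straddles an arc boundary. Trials live
on the continuous time grid (400 ms is 15.625 samples at 39.0625 Hz) and
are snapped to samples only when the analysis window is extracted,
avoiding cumulative rounding drift.

The classifier operates not on the bare 400 ms trial but on a 512 ms
(20-sample) window covering the concatenated responses of two neighboring
trials: trial i's window is centered on the boundary between trials i and
i+1 of the same pass (the last trial of a pass reuses the boundary with
its predecessor). One window per trial keeps the row count equal to the
trial count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import SegmentationError
from .preprocess import FosBlock
from .protocol import Quadrant, StimulusProtocol, quadrant_passes

__all__ = [
    "TrialWindow",
    "DesignGeometry",
    "TRIAL_SECONDS",
    "WINDOW_SECONDS",
    "window_length",
    "segment_trials",
    "attach_windows",
    "design_geometry",
    "trials_to_frame",
]

TRIAL_SECONDS = 0.4
WINDOW_SECONDS = 0.512


def window_length(sampling_rate: float) -> int:
    """Samples per analysis window: 512 ms at 39.0625 Hz -> exactly 20."""
    return int(round(WINDOW_SECONDS * sampling_rate))


@dataclass
class TrialWindow:
    """One 400 ms labeled trial plus its 20-sample analysis window.

    ``t_start``/``t_end`` are in stimulus time (seconds from stimulus
    onset); ``window_start``/``window_stop`` are sample indices into the
    recording array (half-open), set by :func:`attach_windows`.
    """

    subject_id: str
    trial_index: int
    label: Quadrant
    t_start: float
    t_end: float
    wedge_angle_at_center: float
    pass_index: int
    window_start: Optional[int] = None
    window_stop: Optional[int] = None


def segment_trials(
    block: FosBlock | None, protocol: StimulusProtocol, subject_id: str | None = None
) -> list[TrialWindow]:
    """Tile every quadrant pass with consecutive 400 ms labeled trials.

    ``block`` may be None when only trial timing/labels are needed (e.g.
    ground-truth manifests); when given, the recording must cover the
    protocol duration.
    """
    from .protocol import wedge_angle_at

    if block is not None:
        subject_id = subject_id or block.subject_id
        available = block.n_samples / block.sampling_rate
        needed = block.t0_offset + protocol.stimulus_duration
        if available + 1e-9 < needed:
            raise SegmentationError(
                f"recording covers {available:.2f} s but protocol needs "
                f"{needed:.2f} s (incl. {block.t0_offset} s onset offset)"
            )
    subject_id = subject_id or ""

    trials: list[TrialWindow] = []
    idx = 0
    for pass_index, (p0, p1, label) in enumerate(quadrant_passes(protocol)):
        n = int(math.floor((p1 - p0) / TRIAL_SECONDS + 1e-9))
        for k in range(n):
            t0 = p0 + k * TRIAL_SECONDS
            t1 = t0 + TRIAL_SECONDS
            mid = 0.5 * (t0 + t1)
            trials.append(
                TrialWindow(
                    subject_id=subject_id,
                    trial_index=idx,
                    label=label,
                    t_start=t0,
                    t_end=t1,
                    wedge_angle_at_center=wedge_angle_at(mid, protocol),
                    pass_index=pass_index,
                )
            )
            idx += 1
    return trials


def attach_windows(
    trials: list[TrialWindow],
    sampling_rate: float,
    t0_offset: float = 1.0,
    n_samples: Optional[int] = None,
) -> list[TrialWindow]:
    """Assign each trial its 20-sample analysis window (in place).

    The window is centered on the time boundary between the trial and its
    within-pass neighbor (successor; the last trial of a pass uses its
    predecessor), covering the concatenated responses of the two 400 ms
    trials. Windows of neighboring trials therefore overlap; each trial
    still contributes exactly one window/row.
    """
    n_win = window_length(sampling_rate)
    by_pass: dict[tuple[str, int], list[TrialWindow]] = {}
    for tr in trials:
        by_pass.setdefault((tr.subject_id, tr.pass_index), []).append(tr)

    for key, group in by_pass.items():
        group.sort(key=lambda tr: tr.t_start)
        if len(group) < 2:
            raise SegmentationError(
                f"pass {key[1]} has a single trial; cannot form a two-trial window"
            )
        for i, tr in enumerate(group):
            center = tr.t_end if i < len(group) - 1 else tr.t_start
            c = int(round((center + t0_offset) * sampling_rate))
            start = c - n_win // 2
            stop = start + n_win
            if start < 0 or (n_samples is not None and stop > n_samples):
                raise SegmentationError(
                    f"window [{start}, {stop}) of trial {tr.trial_index} falls "
                    "outside the recorded block"
                )
            tr.window_start, tr.window_stop = start, stop
    return trials


@dataclass(frozen=True)
class DesignGeometry:
    """Row/column accounting of the classifier input matrix."""

    n_subjects: int
    n_revolutions: int
    trials_per_quadrant_pass: int
    rows: int
    cols: int


def design_geometry(
    protocol: StimulusProtocol,
    n_subjects: int,
    n_channels: int = 128,
    n_revolutions: Optional[int] = None,
) -> DesignGeometry:
    """Design-matrix geometry implied by the protocol and cohort counts.

    For a binary quadrant contrast: rows = subjects x revolutions x
    trials-per-quadrant-pass x 2 classes. With the 48 s revolution and
    400 ms trials, a quadrant pass (12 s) holds 30 trials, so the reference
    cohort (41 subjects, 8 revolutions) gives 19,680 rows x 128 channels.
    """
    if n_revolutions is None:
        n_revolutions = protocol.n_revolutions
    if n_subjects < 0 or n_revolutions < 0:
        raise SegmentationError("counts must be non-negative")
    per_pass = int(math.floor(protocol.revolution_period / 4.0 / TRIAL_SECONDS + 1e-9))
    rows = n_subjects * n_revolutions * per_pass * 2
    return DesignGeometry(
        n_subjects=n_subjects,
        n_revolutions=n_revolutions,
        trials_per_quadrant_pass=per_pass,
        rows=rows,
        cols=n_channels,
    )


def trials_to_frame(trials: list[TrialWindow]) -> pd.DataFrame:
    """Trial/window table for export (TSV-friendly)."""
    return pd.DataFrame(
        {
            "subject": [tr.subject_id for tr in trials],
            "trial": [tr.trial_index for tr in trials],
            "label": [tr.label.value for tr in trials],
            "t_start": [tr.t_start for tr in trials],
            "t_end": [tr.t_end for tr in trials],
            "window_start": [tr.window_start for tr in trials],
            "window_stop": [tr.window_stop for tr in trials],
            "angle_deg": [tr.wedge_angle_at_center for tr in trials],
            "pass_index": [tr.pass_index for tr in trials],
        }
    )
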