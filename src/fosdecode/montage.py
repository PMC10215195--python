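"""Synthetic occipital optode montage and per-quadrant channel gains.

The instrument couples 16 source fibers (each carrying a 690 nm and an
830 nm laser) and 16 detectors over the occipital scalp, centered on a
nominal Oz origin. Sources and detectors are laid out on interleaved
regular grids with a small seeded jitter; every source-detector pair whose
separation falls in the accepted distance band is an eligible channel, and
a seeded subset of the eligible pairs is retained so that each wavelength
has exactly the configured channel count. The same source-detector pairs
are used at both wavelengths (paired lasers share a fiber).

Positions are synthetic: only the optode counts and the 20-70 mm distance
band are physically constrained; coordinates are package plumbing.

Each channel also carries a ``quadrant_gain`` row: the relative amplitude
with which activation evoked by each visual-field quadrant appears in that
channel. Gains fall off as a Gaussian of the distance between the channel
midpoint and four region centroids laid out on the sensor plane (top /
bottom along y, left / right along x, with the left-right cortical mapping
mirrored as in retinotopy). This is a parametric proxy for a
photon-transport sensitivity map, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["MontageConfig", "Montage", "build_montage", "QUADRANT_ORDER"]

#: Column order of ``Montage.quadrant_gain``.
QUADRANT_ORDER = ("top", "right", "bottom", "left")

WAVELENGTHS = (690, 830)


@dataclass(frozen=True)
class MontageConfig:
    """Geometry parameters for :func:`build_montage`.

    Distances in millimetres. The default grid spans roughly 105 x 75 mm of
    occipital scalp and yields comfortably more than 128 eligible pairs in
    the 20-70 mm band, from which exactly ``n_channels_per_wavelength`` are
    kept.
    """

    n_sources: int = 16
    n_detectors: int = 16
    n_channels_per_wavelength: int = 128
    min_distance: float = 20.0
    max_distance: float = 70.0
    grid_shape: tuple[int, int] = (4, 4)  # (columns, rows) for each optode type
    source_spacing: tuple[float, float] = (35.0, 25.0)  # mm (dx, dy)
    detector_offset: tuple[float, float] = (17.5, 12.5)  # detector grid shift, mm
    position_jitter: float = 1.5  # uniform +/- jitter, mm
    gain_sigma: float = 35.0  # mm falloff of the quadrant-gain proxy

    def __post_init__(self) -> None:
        if self.grid_shape[0] * self.grid_shape[1] != self.n_sources:
            raise ConfigurationError("grid_shape must tile n_sources")
        if self.grid_shape[0] * self.grid_shape[1] != self.n_detectors:
            raise ConfigurationError("grid_shape must tile n_detectors")
        if not 0 < self.min_distance < self.max_distance:
            raise ConfigurationError("need 0 < min_distance < max_distance")
        if self.n_channels_per_wavelength < 1:
            raise ConfigurationError("n_channels_per_wavelength must be >= 1")


@dataclass
class Montage:
    """Optode positions, channel table and per-quadrant channel gains.

    Attributes
    ----------
    sources, detectors:
        DataFrames with columns ``id, x, y`` (mm).
    channels:
        DataFrame with one row per channel: ``channel, source, detector,
        wavelength, distance, x, y`` where ``x, y`` is the source-detector
        midpoint. Both wavelengths share the channel geometry, so the table
        has ``2 * n_channels_per_wavelength`` rows.
    quadrant_gain:
        ``(n_channels, 4)`` array of response gains in [0, 1], columns in
        :data:`QUADRANT_ORDER`, aligned with ``channels`` rows.
    """

    sources: pd.DataFrame
    detectors: pd.DataFrame
    channels: pd.DataFrame
    quadrant_gain: np.ndarray
    config: MontageConfig = field(default_factory=MontageConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.channels["distance"].to_numpy()
        if np.any(d < self.config.min_distance - 1e-9) or np.any(
            d > self.config.max_distance + 1e-9
        ):
            raise ConfigurationError("channel distance outside accepted band")
        if np.any(self.quadrant_gain < 0):
            raise ConfigurationError("quadrant_gain must be non-negative")
        if self.quadrant_gain.shape != (len(self.channels), len(QUADRANT_ORDER)):
            raise ConfigurationError("quadrant_gain shape mismatch")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_indices(self, wavelength: int) -> np.ndarray:
        """Row indices of the channels at one wavelength, in table order."""
        if wavelength not in WAVELENGTHS:
            raise ConfigurationError(f"unknown wavelength {wavelength}")
        return np.flatnonzero(self.channels["wavelength"].to_numpy() == wavelength)

    # -- serialization -----------------------------------------------------

    def write_tsv(self, path) -> None:
        self.channels.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": {
                **{
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in self.config.__dict__.items()
                }
            },
            "sources": self.sources.to_dict(orient="list"),
            "detectors": self.detectors.to_dict(orient="list"),
            "channels": self.channels.to_dict(orient="list"),
            "quadrant_gain": self.quadrant_gain.tolist(),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        cfg = dict(d["config"])
        for k in ("grid_shape", "source_spacing", "detector_offset"):
            cfg[k] = tuple(cfg[k])
        return cls(
            sources=pd.DataFrame(d["sources"]),
            detectors=pd.DataFrame(d["detectors"]),
            channels=pd.DataFrame(d["channels"]),
            quadrant_gain=np.asarray(d["quadrant_gain"], dtype=float),
            config=MontageConfig(**cfg),
            seed=d["seed"],
        )

    @classmethod
    def read_json(cls, path) -> "Montage":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _grid(cfg: MontageConfig, origin: tuple[float, float]) -> np.ndarray:
    ncol, nrow = cfg.grid_shape
    dx, dy = cfg.source_spacing
    xs = (np.arange(ncol) - (ncol - 1) / 2.0) * dx + origin[0]
    ys = (np.arange(nrow) - (nrow - 1) / 2.0) * dy + origin[1]
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def build_montage(config: MontageConfig | None = None, seed: int = 0) -> Montage:
    """Construct a deterministic synthetic montage for a given seed.

    Raises :class:`ConfigurationError` when the grid geometry cannot supply
    the requested number of channels inside the distance band.
    """
    cfg = config or MontageConfig()
    rng = np.random.default_rng(seed)

    src = _grid(cfg, (0.0, 0.0))
    det = _grid(cfg, cfg.detector_offset)
    src = src + rng.uniform(-cfg.position_jitter, cfg.position_jitter, src.shape)
    det = det + rng.uniform(-cfg.position_jitter, cfg.position_jitter, det.shape)

    # all source-detector pairs inside the accepted distance band
    diffs = src[:, None, :] - det[None, :, :]
    dist = np.hypot(diffs[..., 0], diffs[..., 1])
    eligible = np.argwhere((dist >= cfg.min_distance) & (dist <= cfg.max_distance))
    if len(eligible) < cfg.n_channels_per_wavelength:
        raise ConfigurationError(
            f"only {len(eligible)} source-detector pairs fall in "
            f"[{cfg.min_distance}, {cfg.max_distance}] mm; "
            f"{cfg.n_channels_per_wavelength} channels requested"
        )
    keep = rng.choice(len(eligible), size=cfg.n_channels_per_wavelength, replace=False)
    keep.sort()
    pairs = eligible[keep]

    rows = []
    for wl in WAVELENGTHS:
        for k, (i, j) in enumerate(pairs):
            mid = 0.5 * (src[i] + det[j])
            rows.append(
                {
                    "channel": f"S{i + 1}-D{j + 1}-{wl}",
                    "source": i + 1,
                    "detector": j + 1,
                    "wavelength": wl,
                    "distance": float(dist[i, j]),
                    "x": float(mid[0]),
                    "y": float(mid[1]),
                }
            )
    channels = pd.DataFrame(rows)

    # quadrant-gain proxy: Gaussian falloff around four region centroids.
    # Top/bottom visual field maps below/above the calcarine -> vertical
    # contrast; left/right hemifields map to the contralateral hemisphere ->
    # mirrored horizontal contrast.
    extent_x = (cfg.grid_shape[0] - 1) / 2.0 * cfg.source_spacing[0]
    extent_y = (cfg.grid_shape[1] - 1) / 2.0 * cfg.source_spacing[1]
    centroids = {
        "top": (0.0, -0.8 * extent_y),
        "bottom": (0.0, 0.8 * extent_y),
        "left": (0.8 * extent_x, 0.0),
        "right": (-0.8 * extent_x, 0.0),
    }
    mids = channels[["x", "y"]].to_numpy()
    gain = np.empty((len(channels), len(QUADRANT_ORDER)))
    for q, name in enumerate(QUADRANT_ORDER):
        cx, cy = centroids[name]
        d2 = (mids[:, 0] - cx) ** 2 + (mids[:, 1] - cy) ** 2
        gain[:, q] = np.exp(-d2 / (2.0 * cfg.gain_sigma**2))

    return Montage(
        sources=pd.DataFrame(
            {"id": np.arange(1, cfg.n_sources + 1), "x": src[:, 0], "y": src[:, 1]}
        ),
        detectors=pd.DataFrame(
            {"id": np.arange(1, cfg.n_detectors + 1), "x": det[:, 0], "y": det[:, 1]}
        ),
        channels=channels,
        quadrant_gain=gain,
        config=cfg,
        seed=seed,
    )
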