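"""Recording containers: HDF5 (SNIRF-compatible naming) and NPZ fallback.

``write_block``/``read_block`` round-trip a :class:`BlockRecording`
bit-exactly. The native container stores ``dc``/``ac``/``ph`` as separate
channel-major datasets with instrument metadata as attributes and the
channel table (source, detector, wavelength, distance) alongside —
mirroring how SNIRF separates data blocks by measurement type.
``read_snirf_like`` additionally parses a minimal SNIRF-layout file
(``/nirs/data1/dataTimeSeries`` + ``measurementList<N>`` groups with
``dataTypeLabel`` 'DC'/'AC'/'PH') into a BlockRecording with phase in
degrees.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import BlockIOError
from .preprocess import BlockRecording
from .protocol import InstrumentConfig

__all__ = ["write_block", "read_block", "read_snirf_like"]

_FORMAT_VERSION = 1
_CHANNEL_COLS = ("channel", "source", "detector", "wavelength", "distance", "x", "y")


def write_block(path, rec: BlockRecording) -> None:
    """Write a block recording; format chosen by extension (.h5/.hdf5/.npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        _write_npz(path, rec)
        return
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["block_id"] = rec.block_id
        f.attrs["sampling_rate"] = rec.instrument.sampling_rate
        f.attrs["modulation_frequency"] = rec.instrument.modulation_frequency
        f.attrs["t0_offset"] = rec.t0_offset
        f.attrs["array_order"] = "channel-major"
        f.create_dataset("dc", data=rec.dc)
        f.create_dataset("ph", data=rec.ph)
        if rec.ac is not None:
            f.create_dataset("ac", data=rec.ac)
        if rec.channels is not None:
            g = f.create_group("channels")
            for col in _CHANNEL_COLS:
                if col in rec.channels:
                    data = rec.channels[col].to_numpy()
                    if data.dtype == object:
                        data = data.astype("S")
                    g.create_dataset(col, data=data)


def read_block(path) -> BlockRecording:
    """Read a block recording written by :func:`write_block`."""
    path = Path(path)
    if path.suffix == ".npz":
        return _read_npz(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != _FORMAT_VERSION:
            raise BlockIOError(f"unknown container version {version!r} in {path}")
        for name in ("dc", "ph"):
            if name not in f:
                raise BlockIOError(f"container {path} is missing the '{name}' array")
        for attr in ("sampling_rate", "modulation_frequency", "t0_offset"):
            if attr not in f.attrs:
                raise BlockIOError(f"container {path} is missing the '{attr}' attribute")
        dc = f["dc"][...]
        ph = f["ph"][...]
        if dc.shape != ph.shape:
            raise BlockIOError(f"dc/ph shape mismatch in {path}")
        channels = None
        if "channels" in f:
            cols = {}
            for col in f["channels"]:
                data = f["channels"][col][...]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            channels = pd.DataFrame(cols)[
                [c for c in _CHANNEL_COLS if c in cols]
            ]
        return BlockRecording(
            subject_id=str(f.attrs["subject_id"]),
            block_id=str(f.attrs["block_id"]),
            dc=dc,
            ph=ph,
            ac=f["ac"][...] if "ac" in f else None,
            instrument=InstrumentConfig(
                modulation_frequency=float(f.attrs["modulation_frequency"]),
                sampling_rate=float(f.attrs["sampling_rate"]),
            ),
            t0_offset=float(f.attrs["t0_offset"]),
            channels=channels,
        )


def _write_npz(path, rec: BlockRecording) -> None:
    payload = {
        "dc": rec.dc,
        "ph": rec.ph,
        "sampling_rate": rec.instrument.sampling_rate,
        "modulation_frequency": rec.instrument.modulation_frequency,
        "t0_offset": rec.t0_offset,
        "subject_id": np.array(rec.subject_id),
        "block_id": np.array(rec.block_id),
    }
    if rec.ac is not None:
        payload["ac"] = rec.ac
    np.savez(path, **payload)


def _read_npz(path) -> BlockRecording:
    with np.load(path, allow_pickle=False) as z:
        for name in ("dc", "ph", "sampling_rate"):
            if name not in z:
                raise BlockIOError(f"NPZ container {path} is missing '{name}'")
        return BlockRecording(
            subject_id=str(z["subject_id"]),
            block_id=str(z["block_id"]),
            dc=z["dc"],
            ph=z["ph"],
            ac=z["ac"] if "ac" in z else None,
            instrument=InstrumentConfig(
                modulation_frequency=float(z["modulation_frequency"]),
                sampling_rate=float(z["sampling_rate"]),
            ),
            t0_offset=float(z["t0_offset"]),
        )


def read_snirf_like(path) -> BlockRecording:
    """Parse a minimal SNIRF-layout container into a BlockRecording.

    Expects ``/nirs/data1/dataTimeSeries`` (time x measurements), ``time``
    (uniform grid), and per-measurement ``measurementList<N>`` groups with
    ``sourceIndex``, ``detectorIndex``, ``wavelengthIndex`` and a
    ``dataTypeLabel`` of 'DC', 'AC' or 'PH' (phase in degrees). Rows of the
    same (source, detector, wavelength) across labels are matched into one
    channel.
    """
    with h5py.File(path, "r") as f:
        try:
            data = f["nirs/data1"]
            series = data["dataTimeSeries"][...]
            time = data["time"][...]
        except KeyError as exc:
            raise BlockIOError(f"not a SNIRF-layout container: {path}") from exc
        if series.ndim != 2 or len(time) != series.shape[0]:
            raise BlockIOError("dataTimeSeries must be (time, measurements)")
        dt = np.diff(time)
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise BlockIOError("time grid must be uniform")
        fs = 1.0 / float(dt[0])
        wavelengths = None
        probe = f.get("nirs/probe")
        if probe is not None and "wavelengths" in probe:
            wavelengths = probe["wavelengths"][...]

        ml = {}
        for name in data:
            if not name.startswith("measurementList"):
                continue
            g = data[name]
            idx = int(name[len("measurementList"):]) - 1
            label = g["dataTypeLabel"][()]
            if isinstance(label, bytes):
                label = label.decode()
            key = (
                int(g["sourceIndex"][()]),
                int(g["detectorIndex"][()]),
                int(g["wavelengthIndex"][()]),
            )
            ml.setdefault(key, {})[label.upper()] = idx
        if not ml:
            raise BlockIOError(f"no measurementList entries in {path}")

        keys = sorted(ml)
        def stack(label):
            cols = []
            for k in keys:
                if label not in ml[k]:
                    raise BlockIOError(f"measurement {k} lacks a {label} data block")
                cols.append(series[:, ml[k][label]])
            return np.asarray(cols)  # channel-major

        dc = stack("DC")
        ph = stack("PH")
        rows = []
        for k in keys:
            wl = k[2]
            if wavelengths is not None and 1 <= wl <= len(wavelengths):
                wl = int(wavelengths[wl - 1])
            rows.append({"source": k[0], "detector": k[1], "wavelength": wl})
        return BlockRecording(
            subject_id=str(f.attrs.get("subject_id", "unknown")),
            block_id=str(f.attrs.get("block_id", "block-01")),
            dc=dc,
            ph=ph,
            instrument=InstrumentConfig(sampling_rate=fs),
            t0_offset=float(f.attrs.get("t0_offset", 1.0)),
            channels=pd.DataFrame(rows),
        )
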