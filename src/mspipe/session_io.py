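"""On-disk session format: flat int16 binary traces plus a JSON sidecar.

A session directory contains::

    wideband.bin     little-endian int16 samples
    lfp.bin          little-endian int16 samples
    session.json     sampling rates, duration, seed, per-trace scale (unit/bit)
    events.csv       time_s,label  (stimulation pulse onsets, ...)
    ground_truth/<unit_id>.csv   optional true spike times with subtype label

Traces are quantized at write time with a per-trace scale factor chosen to
span the int16 range; the round trip is lossless at int16 precision (raw
integer samples are preserved exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RecordingSession

__all__ = ["SessionFormatError", "write_session", "read_session"]

_INT16_MAX = 32767


class SessionFormatError(ValueError):
    """Malformed or inconsistent session directory."""


def _quantize(trace: np.ndarray) -> tuple[np.ndarray, float]:
    peak = float(np.max(np.abs(trace))) if trace.size else 0.0
    scale = peak / _INT16_MAX if peak > 0 else 1.0
    raw = np.clip(np.round(trace / scale), -_INT16_MAX, _INT16_MAX).astype("<i2")
    return raw, scale


def write_session(session: RecordingSession, path: str | Path) -> Path:
    """Serialize a session to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wb_raw, wb_scale = _quantize(np.asarray(session.wideband))
    lfp_raw, lfp_scale = _quantize(np.asarray(session.lfp))
    wb_raw.tofile(path / "wideband.bin")
    lfp_raw.tofile(path / "lfp.bin")
    sidecar = {
        "fs_wideband": session.fs_wideband,
        "fs_lfp": session.fs_lfp,
        "duration_s": session.duration,
        "seed": session.seed,
        "scale_wideband": wb_scale,
        "scale_lfp": lfp_scale,
        "n_wideband": int(wb_raw.size),
        "n_lfp": int(lfp_raw.size),
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    events = pd.DataFrame(
        {"time_s": np.asarray(session.pulse_times), "label": "pulse"}
    )
    events.to_csv(path / "events.csv", index=False, float_format="%.9g")
    if session.ground_truth:
        gt_dir = path / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        for uid, info in session.ground_truth.items():
            pd.DataFrame(
                {"time_s": np.asarray(info["spike_times"]), "label": info["subtype"]}
            ).to_csv(gt_dir / f"{uid}.csv", index=False, float_format="%.9g")
    return path


def read_session(path: str | Path) -> RecordingSession:
    """Load a session directory back into physical units."""
    path = Path(path)
    sidecar_path = path / "session.json"
    if not sidecar_path.exists():
        raise SessionFormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs_wideband", "fs_lfp", "duration_s", "scale_wideband", "scale_lfp"):
        if key not in meta:
            raise SessionFormatError(f"sidecar missing field {key!r}")
    wb_raw = np.fromfile(path / "wideband.bin", dtype="<i2")
    lfp_raw = np.fromfile(path / "lfp.bin", dtype="<i2")
    for raw, fs, name in (
        (wb_raw, meta["fs_wideband"], "wideband"),
        (lfp_raw, meta["fs_lfp"], "lfp"),
    ):
        expected = meta["duration_s"] * fs
        if abs(raw.size - expected) > 1:
            raise SessionFormatError(
                f"{name} length {raw.size} inconsistent with sidecar "
                f"({meta['duration_s']} s at {fs} Hz)"
            )
    events = pd.read_csv(path / "events.csv") if (path / "events.csv").exists() else None
    pulses = (
        events.loc[events["label"] == "pulse", "time_s"].to_numpy()
        if events is not None and len(events)
        else np.empty(0)
    )
    ground_truth = None
    gt_dir = path / "ground_truth"
    if gt_dir.is_dir():
        ground_truth = {}
        for f in sorted(gt_dir.glob("*.csv")):
            tbl = pd.read_csv(f)
            ground_truth[f.stem] = {
                "spike_times": tbl["time_s"].to_numpy(),
                "subtype": tbl["label"].iloc[0] if len(tbl) else "other",
            }
    return RecordingSession(
        wideband=wb_raw.astype(float) * meta["scale_wideband"],
        lfp=lfp_raw.astype(float) * meta["scale_lfp"],
        pulse_times=pulses,
        duration=meta["duration_s"],
        fs_wideband=meta["fs_wideband"],
        fs_lfp=meta["fs_lfp"],
        ground_truth=ground_truth,
        seed=meta.get("seed"),
    )
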