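"""Readers and writers for the on-disk session formats.

Everything is plain text: fluorescence and processed traces as delimited
CSV with a JSON sidecar of processing parameters, pupil traces as per-frame
CSV, behavioral events and ground truth as JSON.  Eye-video stacks use
multi-page TIFF.  All writers round-trip through the corresponding readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import SessionEvents, TrialRecord
from .traces import DffTrace, FluorescenceTrace, PupilTrace

__all__ = [
    "write_fluorescence",
    "read_fluorescence",
    "write_dff",
    "read_dff",
    "write_pupil",
    "read_pupil",
    "write_events",
    "read_events",
    "write_trials",
    "write_eye_stack",
    "read_eye_stack",
]


def write_fluorescence(path, trace: FluorescenceTrace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "f465": trace.values_465})
    if trace.values_405 is not None:
        df["f405"] = trace.values_405
    df.to_csv(path, index=False, float_format="%.10g")
    _write_sidecar(path, {"fs": trace.fs, "t0": trace.t0, "fiber_id": trace.fiber_id})


def read_fluorescence(path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    tcol = df.columns[0]
    t = df[tcol].to_numpy()
    fs = meta.get("fs") or float(1.0 / np.median(np.diff(t)))
    f465 = df["f465"].to_numpy() if "f465" in df else df[df.columns[1]].to_numpy()
    f405 = df["f405"].to_numpy() if "f405" in df else None
    return FluorescenceTrace(
        fs=fs, values_465=f465, values_405=f405,
        fiber_id=meta.get("fiber_id", ""), t0=meta.get("t0", float(t[0])),
    )


def write_dff(path, trace: DffTrace, params: dict | None = None) -> None:
    pd.DataFrame({"time_s": trace.times, "dff": trace.dff}).to_csv(
        path, index=False, float_format="%.10g"
    )
    meta = {
        "fs": trace.fs,
        "t0": trace.t0,
        "fiber_id": trace.fiber_id,
        "zscored": trace.zscored,
        "baseline_stats": list(trace.baseline_stats) if trace.baseline_stats else None,
    }
    if params:
        meta["processing"] = params
    _write_sidecar(path, meta)


def read_dff(path) -> DffTrace:
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    t = df["time_s"].to_numpy()
    fs = meta.get("fs") or float(1.0 / np.median(np.diff(t)))
    stats = meta.get("baseline_stats")
    return DffTrace(
        fs=fs, dff=df["dff"].to_numpy(), t0=meta.get("t0", float(t[0])),
        fiber_id=meta.get("fiber_id", ""), zscored=meta.get("zscored", False),
        baseline_stats=tuple(stats) if stats else None,
    )


def write_pupil(path, trace: PupilTrace) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(len(trace)), "diameter_px": trace.diameter,
         "valid": trace.valid.astype(int)}
    )
    if trace.ellipse_params is not None:
        for i, name in enumerate(("xc", "yc", "a", "b", "theta")):
            df[name] = trace.ellipse_params[:, i]
    df.to_csv(path, index=False, float_format="%.8g")
    _write_sidecar(path, {"fs": trace.fs, "t0": trace.t0})


def read_pupil(path) -> PupilTrace:
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    ellipse = None
    if "xc" in df:
        ellipse = df[["xc", "yc", "a", "b", "theta"]].to_numpy()
    return PupilTrace(
        fs=meta.get("fs", 30.0), diameter=df["diameter_px"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool), ellipse_params=ellipse,
        t0=meta.get("t0", 0.0),
    )


def write_events(path, events: SessionEvents) -> None:
    payload = {
        "session_id": events.session_id,
        "mouse_id": events.mouse_id,
        "stim_onsets": [
            {"onset_s": o, "tone": tone, "phase": phase}
            for o, tone, phase in events.stim_onsets
        ],
        "licks": events.licks.tolist(),
        "reinforcement": [{"time_s": t, "type": k} for t, k in events.reinforcement],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path) -> SessionEvents:
    payload = json.loads(Path(path).read_text())
    return SessionEvents(
        stim_onsets=[
            (d["onset_s"], d["tone"], d["phase"]) for d in payload["stim_onsets"]
        ],
        licks=np.asarray(payload["licks"], dtype=float),
        reinforcement=[(d["time_s"], d["type"]) for d in payload["reinforcement"]],
        session_id=payload.get("session_id", ""),
        mouse_id=payload.get("mouse_id", ""),
    )


def write_trials(path, trials: list[TrialRecord]) -> None:
    pd.DataFrame([vars(t) for t in trials]).to_csv(path, index=False)


def write_eye_stack(path, frames: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))


def read_eye_stack(path) -> np.ndarray:
    frames = tifffile.imread(path)
    return frames[None] if frames.ndim == 2 else frames


def _write_sidecar(path, meta: dict) -> None:
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def _read_sidecar(path) -> dict:
    side = Path(str(path) + ".json")
    return json.loads(side.read_text()) if side.exists() else {}
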