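"""File formats: signal CSV, calibration/model/report JSON, event JSONL.

All persisted formats are plain text with a leading version marker and
round-trip exactly (floats are written with 17 significant digits, enough
to reproduce any IEEE double bit-for-bit).

* EMG CSV — ``# format=handpilot-emg``, ``# version=1``, ``# fs=...``,
  ``# channels=m1,m2``, ``# units=au``, then ``time,ch1,ch2`` rows.
* IMU CSV — ``# format=handpilot-imu``, ``# version=1``,
  ``# nominal_fs=...``, then ``time,ax,ay,az,gx,gy,gz`` rows.
* EMG calibration / IMU model / performance report — JSON documents with
  ``format`` and ``version`` keys.
* Transition events — JSON lines, one object per event.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .actuators import ActuatorLog
from .emg import EmgCalibration, EmgRecording
from .errors import FormatError
from .fsm import HandState, TransitionEvent
from .imu import CHANNEL_ORDER, ActivationThresholds, ImuStream, PcaModel
from .protocol import PerformanceReport

FLOAT_FMT = "%.17g"
_VERSION = 1


def _read_header(path) -> tuple[dict[str, str], int]:
    """Parse leading ``# key=value`` lines; returns (header, n_header_lines)."""
    header: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
    return header, n


def _check_format(header: dict, expected: str, path) -> None:
    if header.get("format") != expected:
        raise FormatError(f"{path}: expected format={expected}, got {header.get('format')}")
    try:
        version = int(header.get("version", "0"))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed version {header.get('version')!r}") from exc
    if version != _VERSION:
        raise FormatError(f"{path}: unsupported version {version}")


def _read_table(path, n_header: int, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    if tuple(df.columns) != columns:
        raise FormatError(
            f"{path}: expected columns {','.join(columns)} on line {n_header + 1}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: missing/malformed value near line {n_header + 2 + bad}")
    return df


def write_emg_csv(recording: EmgRecording, path) -> None:
    buf = StringIO()
    buf.write(f"# format=handpilot-emg\n# version={_VERSION}\n")
    buf.write(f"# fs={recording.fs!r}\n# channels=m1,m2\n# units=au\n")
    df = pd.DataFrame(
        {"time": recording.times, "ch1": recording.data[:, 0], "ch2": recording.data[:, 1]}
    )
    df.to_csv(buf, index=False, float_format=FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_emg_csv(path) -> EmgRecording:
    header, n = _read_header(path)
    _check_format(header, "handpilot-emg", path)
    if "fs" not in header:
        raise FormatError(f"{path}: missing fs header")
    df = _read_table(path, n, ("time", "ch1", "ch2"))
    return EmgRecording(
        df[["ch1", "ch2"]].to_numpy(),
        fs=float(header["fs"]),
        start_time=float(df["time"].iloc[0]) if len(df) else 0.0,
    )


def write_imu_csv(stream: ImuStream, path, nominal_fs: float = 47.0) -> None:
    buf = StringIO()
    buf.write(f"# format=handpilot-imu\n# version={_VERSION}\n# nominal_fs={nominal_fs!r}\n")
    df = pd.DataFrame(stream.data, columns=list(CHANNEL_ORDER))
    df.insert(0, "time", stream.timestamps)
    df.to_csv(buf, index=False, float_format=FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_imu_csv(path) -> ImuStream:
    header, n = _read_header(path)
    _check_format(header, "handpilot-imu", path)
    df = _read_table(path, n, ("time",) + CHANNEL_ORDER)
    ts = df["time"].to_numpy()
    if ts.size >= 2 and np.any(np.diff(ts) <= 0):
        bad = int(np.flatnonzero(np.diff(ts) <= 0)[0])
        raise FormatError(f"{path}: non-monotone timestamps near line {n + 2 + bad}")
    return ImuStream(ts, df[["ax", "ay", "az"]].to_numpy(), df[["gx", "gy", "gz"]].to_numpy())


def write_calibration_json(calib: EmgCalibration, path) -> None:
    doc = {
        "format": "handpilot-emg-calibration",
        "version": _VERSION,
        "vc": [calib.vc1, calib.vc2],
        "ratios": {"rl1": calib.rl1, "rh1": calib.rh1, "rl2": calib.rl2, "rh2": calib.rh2},
        "rest_levels": [calib.rest_level1, calib.rest_level2],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_calibration_json(path) -> EmgCalibration:
    doc = _load_json(path, "handpilot-emg-calibration")
    try:
        return EmgCalibration(
            vc1=doc["vc"][0], vc2=doc["vc"][1],
            rest_level1=doc["rest_levels"][0], rest_level2=doc["rest_levels"][1],
            **doc["ratios"],
        )
    except (KeyError, IndexError, TypeError) as exc:
        raise FormatError(f"{path}: incomplete calibration document: {exc}") from exc


def write_model_json(model: PcaModel, alpha: ActivationThresholds, path) -> None:
    doc = {
        "format": "handpilot-imu-model",
        "version": _VERSION,
        "channel_order": list(CHANNEL_ORDER),
        "mean": model.mean.tolist(),
        "components": model.components.tolist(),
        "centroids": model.centroids.tolist(),
        "calibration_points": [
            {"label": int(lab), "point": list(pt)} for lab, pt in model.calibration_points
        ],
        "alpha": alpha.alpha.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model_json(path) -> tuple[PcaModel, ActivationThresholds]:
    doc = _load_json(path, "handpilot-imu-model")
    try:
        model = PcaModel(
            mean=np.array(doc["mean"]),
            components=np.array(doc["components"]),
            centroids=np.array(doc["centroids"]),
            calibration_points=[
                (p["label"], tuple(p["point"])) for p in doc.get("calibration_points", [])
            ],
        )
        alpha = ActivationThresholds(np.array(doc["alpha"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: incomplete model document: {exc}") from exc
    return model, alpha


def write_events_jsonl(events, path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_events_jsonl(path) -> list[TransitionEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                events.append(
                    TransitionEvent(
                        time=float(obj["time"]),
                        from_state=HandState(obj["from"]),
                        to_state=HandState(obj["to"]),
                        trigger=obj.get("trigger", {}),
                    )
                )
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise FormatError(f"{path}: bad event on line {lineno}: {exc}") from exc
    return events


def write_report_json(report: PerformanceReport, path) -> None:
    doc = {"format": "handpilot-report", "version": _VERSION, **report.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_report_json(path) -> PerformanceReport:
    doc = _load_json(path, "handpilot-report")
    try:
        return PerformanceReport(
            n_desired=doc["n_desired"], n_correct=doc["n_correct"],
            outcomes=doc.get("outcomes", []),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: incomplete report document: {exc}") from exc


def write_actuator_log_csv(log: ActuatorLog, path) -> None:
    rows = []
    for e in log.entries:
        rows.append(
            {
                "time": e.time,
                "state": e.state.value,
                "gesture": e.gesture or "",
                "channel": "" if e.channel is None else e.channel,
                **{k: v for k, v in e.params.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_scatter_csv(model: PcaModel, online_points, path) -> None:
    """Export calibration (squares) and online (stars) 2-D points for plotting."""
    rows = [
        {"set": "calibration", "label": int(lab), "pc1": pt[0], "pc2": pt[1]}
        for lab, pt in model.calibration_points
    ]
    rows += [
        {"set": "online", "label": int(lab), "pc1": float(p[0]), "pc2": float(p[1])}
        for lab, p in online_points
    ]
    rows += [
        {"set": "centroid", "label": i + 1, "pc1": c[0], "pc2": c[1]}
        for i, c in enumerate(model.centroids)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def _load_json(path, expected: str) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a JSON object")
    _check_format(doc, expected, path)
    return doc
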