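"""Reading and writing recordings and annotations.

Recordings are CSV with canonical header
``time_s,acc_ap,acc_ml,acc_v,gyr_ap,gyr_ml,gyr_v`` (units m/s^2 and deg/s).
Annotations are a JSON list of objects
``{subject_id, task, start_s, end_s, condition, tinetti_subscore}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FormatError,
    GroundTruthLabel,
    ImuRecording,
    IntervalSource,
    MotionInterval,
    Task,
    ValidationError,
)

__all__ = [
    "CANONICAL_COLUMNS",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
]

CANONICAL_COLUMNS = (
    "time_s",
    "acc_ap",
    "acc_ml",
    "acc_v",
    "gyr_ap",
    "gyr_ml",
    "gyr_v",
)


def read_recording(
    path: str | Path,
    axis_map: dict[str, str] | None = None,
    subject_id: str | None = None,
    task: Task | str = Task.SIT_TO_STAND,
    sampling_rate_hz: float | None = None,
    scale_accel: float = 1.0,
    scale_gyro: float = 1.0,
) -> ImuRecording:
    """Read a recording CSV into a validated :class:`ImuRecording`.

    ``axis_map`` maps file column names to canonical ones (e.g.
    ``{"ax": "acc_ap"}``); identity by default.  ``scale_accel`` /
    ``scale_gyro`` convert file units (e.g. g) to m/s^2 and deg/s.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path} is empty") from None
    if axis_map:
        frame = frame.rename(columns=axis_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise ValidationError(f"{path} contains no samples")
    time_s = frame["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time_s) <= 0):
        raise ValidationError(f"{path}: time_s is not strictly increasing")
    if sampling_rate_hz is None:
        if len(time_s) > 1:
            sampling_rate_hz = 1.0 / float(np.median(np.diff(time_s)))
        else:
            sampling_rate_hz = 40.0
    accel = frame[["acc_ap", "acc_ml", "acc_v"]].to_numpy(dtype=float).T
    gyro = frame[["gyr_ap", "gyr_ml", "gyr_v"]].to_numpy(dtype=float).T
    return ImuRecording(
        subject_id=subject_id or path.stem,
        task=Task(task),
        time_s=time_s,
        accel=accel * scale_accel,
        gyro=gyro * scale_gyro,
        sampling_rate_hz=float(sampling_rate_hz),
        axis_map=dict(axis_map or {}),
    )


def write_recording(rec: ImuRecording, path: str | Path) -> Path:
    """Write a recording as CSV in canonical column order."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "acc_ap": rec.accel[0],
            "acc_ml": rec.accel[1],
            "acc_v": rec.accel[2],
            "gyr_ap": rec.gyro[0],
            "gyr_ml": rec.gyro[1],
            "gyr_v": rec.gyro[2],
        }
    )
    frame.to_csv(path, index=False, float_format="%.9f")
    return path


def _label_to_dict(subject_id: str, label: GroundTruthLabel) -> dict:
    return {
        "subject_id": subject_id,
        "task": label.task.value,
        "start_s": label.interval.start_s,
        "end_s": label.interval.end_s,
        "source": label.interval.source.value,
        "degenerate_flag": label.interval.degenerate_flag,
        "condition": label.condition.value,
        "tinetti_subscore": label.tinetti_subscore,
    }


def read_annotations(path: str | Path) -> dict[str, GroundTruthLabel]:
    """Read an annotation JSON into ``subject_id -> GroundTruthLabel``.

    ``condition`` in the file is informative only: it is re-derived from
    the Tinetti sub-score (full mark = normal) and a mismatch raises.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    if not isinstance(raw, list):
        raise FormatError(f"{path}: expected a JSON list of annotations")
    out: dict[str, GroundTruthLabel] = {}
    for item in raw:
        try:
            task = Task(item["task"])
        except ValueError:
            raise ValidationError(f"unknown task {item.get('task')!r}") from None
        except (KeyError, TypeError):
            raise FormatError(f"{path}: malformed annotation entry {item!r}") from None
        interval = MotionInterval(
            start_s=item["start_s"],
            end_s=item["end_s"],
            source=item.get("source", IntervalSource.GROUND_TRUTH),
            degenerate_flag=bool(item.get("degenerate_flag", False)),
        )
        label = GroundTruthLabel(
            interval=interval, task=task, tinetti_subscore=item["tinetti_subscore"]
        )
        if "condition" in item and label.condition.value != item["condition"]:
            raise ValidationError(
                f"{item['subject_id']}: condition {item['condition']!r} "
                f"inconsistent with tinetti_subscore {label.tinetti_subscore}"
            )
        out[str(item["subject_id"])] = label
    return out


def write_annotations(
    labels: dict[str, GroundTruthLabel], path: str | Path
) -> Path:
    path = Path(path)
    payload = [_label_to_dict(sid, lab) for sid, lab in labels.items()]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
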