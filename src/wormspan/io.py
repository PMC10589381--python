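"""Readers and writers for the pipeline's on-disk formats.

Frames are 8-bit grayscale PNG named ``plate<P>_day<DD>.png``; lifespan
curves are CSV with columns ``day, alive_count, percent_alive, n_initial``
(1-based assay days, counting starting at day 4); detections are JSON with
the schema ``{"width", "height", "day", "detections": [{"box": [x1, y1, x2,
y2], "score": s}]}``.  All round trips are lossless for the corresponding
domain objects.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .blob_world import LifespanSample
from .detect_bridge import Detection, DetectionSet
from .lifespan_eval import LifespanCurve

__all__ = [
    "write_png", "read_png",
    "write_curve_csv", "read_curve_csv",
    "write_detections_json", "read_detections_json",
    "write_sample_dir", "read_sample_dir",
    "frame_name",
]

_FRAME_RE = re.compile(r"plate(?P<plate>\d+)_day(?P<day>\d+)\.png$")


def frame_name(plate: int, day: int) -> str:
    return f"plate{plate}_day{day:02d}.png"


def write_png(path: str | Path, frame: np.ndarray) -> None:
    frame = np.asarray(frame)
    if frame.dtype != np.uint8 or frame.ndim != 2:
        raise ValueError("frames must be 2-D uint8")
    Image.fromarray(frame, mode="L").save(Path(path))


def read_png(path: str | Path) -> np.ndarray:
    with Image.open(Path(path)) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def write_curve_csv(path: str | Path, curve: LifespanCurve) -> None:
    pd.DataFrame({
        "day": curve.days,
        "alive_count": curve.counts,
        "percent_alive": curve.percent,
        "n_initial": curve.n_initial,
    }).to_csv(Path(path), index=False)


def read_curve_csv(path: str | Path) -> LifespanCurve:
    df = pd.read_csv(Path(path))
    missing = {"day", "alive_count", "n_initial"} - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV {path} missing columns {sorted(missing)}")
    if (df["alive_count"] < 0).any():
        bad = df.index[df["alive_count"] < 0][0]
        raise ValueError(f"curve CSV {path}: negative count at row {bad}")
    n_initial = df["n_initial"].iloc[0]
    if (df["n_initial"] != n_initial).any():
        raise ValueError(f"curve CSV {path}: n_initial must be constant")
    return LifespanCurve(df["day"].to_numpy(), df["alive_count"].to_numpy(),
                         int(n_initial))


def write_detections_json(path: str | Path, dets: DetectionSet) -> None:
    payload = {
        "width": dets.source_size[0],
        "height": dets.source_size[1],
        "day": dets.day,
        "detections": [
            {"box": [float(v) for v in d.box], "score": float(d.score)}
            for d in dets.detections
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections_json(path: str | Path) -> DetectionSet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed detection JSON {path}: {exc}") from exc
    try:
        dets = tuple(Detection(box=tuple(d["box"]), score=d["score"])
                     for d in payload["detections"])
        return DetectionSet(dets, (payload["width"], payload["height"]),
                            payload.get("day", 1))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"detection JSON {path} missing field: {exc}") from exc


def write_sample_dir(directory: str | Path, sample: LifespanSample,
                     plate: int = 1, first_day: int = 4) -> None:
    """Materialize one simulated sample: per-day PNGs plus a labels CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(sample.images):
        write_png(directory / frame_name(plate, first_day + i), frame)
    pd.DataFrame({
        "day": np.arange(first_day, first_day + len(sample.labels)),
        "alive_count": sample.labels,
    }).to_csv(directory / "labels.csv", index=False)


def read_sample_dir(directory: str | Path, plate: int = 1,
                    first_day: int = 4) -> LifespanSample:
    directory = Path(directory)
    labels = pd.read_csv(directory / "labels.csv")["alive_count"].to_numpy()
    frames = []
    for i in range(len(labels)):
        path = directory / frame_name(plate, first_day + i)
        if not path.exists():
            raise FileNotFoundError(
                f"missing frame for assay day {first_day + i}: {path}")
        frames.append(read_png(path))
    return LifespanSample(np.stack(frames), labels.astype(int), {"plate": plate})
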