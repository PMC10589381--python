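"""Bridge from real plate images to the simplified blob domain.

A detector (externally trained; any model satisfying the
:class:`DetectionSet` schema) reports worm bounding boxes with confidence
scores on full-resolution plate photographs (1944x1944 by default).  The
domain change keeps detections above a score threshold (0.85 by default),
maps each surviving box center onto the 256x256 simplified grid by uniform
scaling, and renders a blob disc per center with the same renderer the
simulator uses — so real assays and synthetic training data meet in an
identical image space.

Also provided: the centroid-to-bounding-box labeling helper used when
annotating plates — around a clicked centroid, dark pixels (below an 8-bit
threshold, default 33) are segmented and the minimal axis-aligned rectangle
around the connected component at the centroid becomes the box label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .blob_world import BlobState, SimConfig, render_day

__all__ = [
    "Detection",
    "DetectionSet",
    "DetectorUnavailableError",
    "EmptySegmentationError",
    "boxes_to_blob_frame",
    "MockDetector",
    "detections_from_states",
    "bbox_from_centroid",
]

DEFAULT_SCORE_THRESHOLD = 0.85


class DetectorUnavailableError(RuntimeError):
    """Raised when a detector adapter cannot produce detections."""


class EmptySegmentationError(ValueError):
    """No foreground pixel found in the window; label needs manual correction."""


@dataclass(frozen=True)
class Detection:
    """One bounding box (x_min, y_min, x_max, y_max) with a confidence score."""

    box: tuple[float, float, float, float]
    score: float

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x1, y1, x2, y2 = self.box
        return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


@dataclass(frozen=True)
class DetectionSet:
    """All detections for one plate image on one assay day."""

    detections: tuple[Detection, ...]
    source_size: tuple[int, int] = (1944, 1944)
    day: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "detections", tuple(self.detections))
        w, h = self.source_size
        for d in self.detections:
            x1, y1, x2, y2 = d.box
            if not (0 <= x1 and x2 <= w and 0 <= y1 and y2 <= h):
                raise ValueError(f"box {d.box} outside source bounds {self.source_size}")

    def __len__(self) -> int:
        return len(self.detections)

    def filtered(self, threshold: float) -> "DetectionSet":
        kept = tuple(d for d in self.detections if d.score >= threshold)
        return DetectionSet(kept, self.source_size, self.day)


def boxes_to_blob_frame(dets: DetectionSet,
                        threshold: float = DEFAULT_SCORE_THRESHOLD,
                        config: SimConfig | None = None) -> np.ndarray:
    """Render one simplified-domain frame from a day's detections.

    Detections with ``score < threshold`` are discarded; surviving box
    centers are scaled from source resolution onto the ``config.image_size``
    grid (real-valued scaling, then rounding) and drawn as blob discs.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    config = config or SimConfig()
    kept = dets.filtered(threshold)
    scale_x = config.image_size / dets.source_size[0]
    scale_y = config.image_size / dets.source_size[1]
    states = []
    limit = config.image_size - 1
    for i, d in enumerate(kept.detections):
        cx, cy = d.center
        x = min(int(round(cx * scale_x)), limit)
        y = min(int(round(cy * scale_y)), limit)
        states.append(BlobState(i, True, (x, y)))
    return render_day(states, config)


class MockDetector:
    """Deterministic stand-in for an external detection network.

    Returns pre-configured per-day detection sets; raises
    :class:`DetectorUnavailableError` for days it has no answer for.  Used
    for tests and synthetic round trips.
    """

    def __init__(self, by_day: dict[int, DetectionSet]):
        self.by_day = dict(by_day)

    def __call__(self, image: np.ndarray, day: int = 1) -> DetectionSet:
        try:
            return self.by_day[day]
        except KeyError as exc:
            raise DetectorUnavailableError(f"no detections configured for day {day}") from exc


def detections_from_states(states: list[BlobState], config: SimConfig,
                           source_size: tuple[int, int] = (1944, 1944),
                           box_half: float = 30.0, score: float = 1.0,
                           day: int = 1) -> DetectionSet:
    """Ground-truth DetectionSet for simulated blobs, in source coordinates.

    Inverse of the domain change: each visible blob center on the simplified
    grid is scaled up to the source resolution and wrapped in a square box of
    half-width ``box_half``.  Supports synthetic round-trip checks.
    """
    sx = source_size[0] / config.image_size
    sy = source_size[1] / config.image_size
    dets = []
    for s in states:
        if s.occluded:
            continue
        cx, cy = s.last_position[0] * sx, s.last_position[1] * sy
        box = (max(cx - box_half, 0.0), max(cy - box_half, 0.0),
               min(cx + box_half, source_size[0]), min(cy + box_half, source_size[1]))
        dets.append(Detection(box=box, score=score))
    return DetectionSet(tuple(dets), source_size, day)


def bbox_from_centroid(image: np.ndarray, centroid: tuple[int, int],
                       window: int = 60, threshold: int = 33
                       ) -> tuple[int, int, int, int]:
    """Bounding-box label from a clicked centroid on a bright-field image.

    Within a ``window``-sized square around ``centroid`` (clamped to the
    image), pixels with intensity strictly below ``threshold`` are
    foreground.  The connected component whose bounding box contains the
    centroid (else the nearest component by center distance) yields the
    minimal enclosing rectangle, returned as (x_min, y_min, x_max, y_max) in
    full-image coordinates with exclusive maxima.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    cx, cy = int(centroid[0]), int(centroid[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"centroid {centroid} outside image {w}x{h}")
    half = window // 2
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    sub = image[y0:y1, x0:x1]
    fg = sub < threshold
    if not fg.any():
        raise EmptySegmentationError(
            f"no pixel below {threshold} in window around {centroid}")
    labels = measure.label(fg, connectivity=2)
    regions = measure.regionprops(labels)
    target = None
    local = (cy - y0, cx - x0)
    for r in regions:
        r0, c0, r1, c1 = r.bbox
        if r0 <= local[0] < r1 and c0 <= local[1] < c1:
            target = r
            break
    if target is None:
        target = min(regions, key=lambda r: (r.centroid[0] - local[0]) ** 2
                     + (r.centroid[1] - local[1]) ** 2)
    r0, c0, r1, c1 = target.bbox
    return (c0 + x0, r0 + y0, c1 + x0, r1 + y0)
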