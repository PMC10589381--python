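"""Simplified-domain plate image simulator.

Real plate photographs are reduced, by a detector, to a "simplified domain":
circular blobs on a constant background marking worm positions on a 256x256
grid.  This module simulates that domain directly so a counting network can
be trained on an unlimited labeled stream without any real images.

Per day, each worm is a :class:`BlobState` row — identifier, alive flag and
last known position.  Alive blobs move to a fresh uniformly random position
inside the plate disc each day; a blob that dies stays at its last position
forever (a dead worm does not move, which is exactly the visual cue the
counting network must learn).  The simulator also recreates nuisances seen in
real assays: per-day occlusions (a blob skipped for one day), blank frames on
days without capture (weekends/holidays, label carried from the previous
day), small whole-frame rotations/translations from plate placement, and
tail padding by replication of the last frame once the population is
extinct (padded labels are 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import draw

from .survival_sim import (
    GridSpec,
    SurvivalCurve,
    WeibullParams,
    perturb_curve,
    quantize_counts,
    theoretical_curve,
)

__all__ = [
    "BlobState",
    "SimConfig",
    "LifespanSample",
    "default_blank_days",
    "render_day",
    "step_day",
    "init_states",
    "simulate_sequence",
    "online_dataset",
]


@dataclass
class BlobState:
    """One row of the simulation state table: id, alive flag, last position.

    ``last_position`` is the (x, y) = (column, row) disc center, 0-based from
    the top-left frame corner.  ``occluded`` marks the blob invisible for the
    current day only.
    """

    id: int
    alive: bool
    last_position: tuple[int, int]
    occluded: bool = False


def default_blank_days(seq_length: int) -> frozenset[int]:
    """Weekend schedule: days 6, 7, 13, 14, ... of the assay (1-based)."""
    return frozenset(d for d in range(1, seq_length + 1) if d % 7 in (6, 0))


@dataclass(frozen=True)
class SimConfig:
    """Geometry, intensity and perturbation settings for the simulator.

    The backlit capture rig produces dark worms on a bright field, hence
    background 255 / blob 0 by default.  ``plate_margin`` keeps blob centers
    inside the inscribed plate disc; ``max_rotation`` (degrees) and
    ``max_translation`` (pixels) bound the whole-frame placement jitter.
    """

    image_size: int = 256
    seq_length: int = 57
    blob_radius: int = 3
    background_intensity: int = 255
    blob_intensity: int = 0
    plate_margin: int = 10
    occlusion_prob: float = 0.05
    blank_day_schedule: frozenset[int] | None = None
    max_rotation: float = 3.0
    max_translation: float = 4.0
    perturb_magnitude: float = 0.05

    def __post_init__(self) -> None:
        if self.blob_intensity == self.background_intensity:
            raise ValueError("blob and background intensities must differ")
        if not (0 <= self.occlusion_prob < 1):
            raise ValueError("occlusion_prob must be in [0, 1)")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")

    @property
    def blank_days(self) -> frozenset[int]:
        if self.blank_day_schedule is None:
            return default_blank_days(self.seq_length)
        return frozenset(self.blank_day_schedule)


@dataclass(frozen=True)
class LifespanSample:
    """A labeled training sample: per-day frames plus per-day live counts."""

    images: np.ndarray  # (seq_length, H, W) uint8
    labels: np.ndarray  # (seq_length,) int
    meta: dict

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")


def _allowed_radius(config: SimConfig) -> float:
    return config.image_size / 2.0 - config.plate_margin


def _sample_position(rng: np.random.Generator, config: SimConfig) -> tuple[int, int]:
    """Uniform point inside the plate disc (rejection sampling)."""
    r = _allowed_radius(config)
    c = config.image_size / 2.0
    while True:
        x, y = rng.uniform(-r, r, size=2)
        if x * x + y * y <= r * r:
            return (int(round(c + x)), int(round(c + y)))


def init_states(n: int, rng: np.random.Generator, config: SimConfig) -> list[BlobState]:
    """Create ``n`` alive blobs at random positions inside the plate disc."""
    return [BlobState(i, True, _sample_position(rng, config)) for i in range(n)]


def render_day(states: list[BlobState], config: SimConfig) -> np.ndarray:
    """Draw the day's frame: constant background plus one filled disc per
    non-occluded blob (alive or dead) at its last position."""
    size = config.image_size
    frame = np.full((size, size), config.background_intensity, dtype=np.uint8)
    for s in states:
        x, y = s.last_position
        if not (0 <= x < size and 0 <= y < size):
            raise ValueError(f"blob {s.id} position {s.last_position} outside frame")
        if s.occluded:
            continue
        rr, cc = draw.disk((y, x), config.blob_radius, shape=frame.shape)
        frame[rr, cc] = config.blob_intensity
    return frame


def step_day(states: list[BlobState], target_alive: int,
             rng: np.random.Generator, config: SimConfig) -> list[BlobState]:
    """Advance the state table one capture day.

    Kills uniformly chosen alive blobs until the alive count equals
    ``target_alive``; dead blobs keep their last position forever; surviving
    alive blobs get fresh uniform positions; every blob is independently
    occluded for this day with ``occlusion_prob``.
    """
    alive_ids = [s.id for s in states if s.alive]
    if target_alive > len(alive_ids):
        raise ValueError(
            f"target_alive={target_alive} exceeds current alive count {len(alive_ids)}")
    n_deaths = len(alive_ids) - target_alive
    dying = set(rng.choice(alive_ids, size=n_deaths, replace=False)) if n_deaths else set()
    out = []
    for s in states:
        alive = s.alive and s.id not in dying
        pos = _sample_position(rng, config) if alive else s.last_position
        occluded = bool(rng.random() < config.occlusion_prob)
        out.append(BlobState(s.id, alive, pos, occluded))
    return out


def _perturb_frame(frame: np.ndarray, rng: np.random.Generator,
                   config: SimConfig) -> np.ndarray:
    """Small random rotation about the frame center plus translation,
    nearest-neighbour resampled, background fill."""
    if config.max_rotation == 0 and config.max_translation == 0:
        return frame
    angle = rng.uniform(-config.max_rotation, config.max_rotation)
    dx, dy = rng.uniform(-config.max_translation, config.max_translation, size=2)
    cval = config.background_intensity
    out = ndimage.rotate(frame, angle, reshape=False, order=0, mode="constant", cval=cval)
    out = ndimage.shift(out, (dy, dx), order=0, mode="constant", cval=cval)
    return out.astype(np.uint8)


def simulate_sequence(triple: tuple[int, int, int], config: SimConfig,
                      rng: np.random.Generator) -> LifespanSample:
    """Generate one labeled image sequence for a grid triple.

    Steps: draw a theoretical Weibull curve for (mean_life, slope), jitter
    and quantize it to an integer count trajectory for ``n_objects`` worms,
    then run the blob world day by day.  Blank-schedule days emit a
    background-only frame and carry the previous day's label.  Once the
    trajectory reaches zero the last rendered frame is replicated to the end
    of the sequence with label 0.
    """
    n_objects, mean_life, slope = triple
    params = WeibullParams(a=float(slope), b=float(mean_life))
    curve = theoretical_curve(params, config.seq_length)
    curve = perturb_curve(curve, rng, config.perturb_magnitude)
    traj = quantize_counts(curve, n_objects)
    counts = traj.counts

    states = init_states(n_objects, rng, config)
    images = np.empty((config.seq_length, config.image_size, config.image_size),
                      dtype=np.uint8)
    labels = np.empty(config.seq_length, dtype=int)
    blank = np.full((config.image_size, config.image_size),
                    config.background_intensity, dtype=np.uint8)
    blanks = config.blank_days

    last_frame = blank
    prev_label = n_objects
    extinct_at = None  # first day index (1-based) with count 0, once rendered
    for d in range(1, config.seq_length + 1):
        if extinct_at is not None:
            # tail padding: replicate the last real frame, label 0
            images[d - 1] = last_frame
            labels[d - 1] = 0
            continue
        if d in blanks:
            images[d - 1] = blank
            labels[d - 1] = prev_label
            continue
        target = int(counts[d - 1])
        states = step_day(states, target, rng, config)
        frame = _perturb_frame(render_day(states, config), rng, config)
        images[d - 1] = frame
        labels[d - 1] = target
        last_frame = frame
        prev_label = target
        if target == 0:
            extinct_at = d
    return LifespanSample(images, labels, {"triple": triple})


def online_dataset(spec: GridSpec, config: SimConfig, seed: int):
    """Infinite reproducible stream of :class:`LifespanSample`.

    Cycles through the parameter grid; each sample draws a fresh random
    stream split from ``seed``, so the same triple yields different curves
    and blob positions on every pass while two streams with the same seed are
    identical.
    """
    from .survival_sim import parameter_grid

    grid = parameter_grid(spec)
    ss = np.random.SeedSequence(seed)
    i = 0
    while True:
        triple = grid[i % len(grid)]
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,))
        rng = np.random.default_rng(child)
        sample = simulate_sequence(triple, config, rng)
        sample.meta["seed_index"] = i
        yield sample
        i += 1
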