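"""Shared containers for centerline pose sequences and assay metadata.

Coordinate convention (documented in every pose-table header): x increases to
the right, y increases toward the flow source, origin at the bottom-left of
the arena.  Point ids 0-9 are the dorsal centerline head -> tail-base; point
id 10 is the tail-fin tip.  Angles are signed, counterclockwise-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: number of centerline keypoints (head -> tail-base)
N_CENTERLINE = 10
#: total keypoints including the tail-fin tip
N_KEYPOINTS = 11
#: number of interior angles of a 10-point centerline
N_ANGLES = 8

#: assay labels, sorted temporally ("control" precedes 1..8 weeks post-injury)
WEEKS: tuple[str, ...] = ("control", "1", "2", "3", "4", "5", "6", "7", "8")

#: default swim-tunnel protocol: three 5-min periods at 0, 10 and 20 cm/s
DEFAULT_FLOW_SCHEDULE: tuple[tuple[float, float], ...] = (
    (0.0, 300.0), (10.0, 300.0), (20.0, 300.0))

DEFAULT_FRAME_RATE = 70.0


def week_index(week: str) -> int:
    """Temporal order of an assay label (control=0, '1'..'8' -> 1..8)."""
    return WEEKS.index(str(week))


@dataclass
class PoseSequence:
    """A contiguous block of annotated frames for one assay.

    Attributes
    ----------
    xy : (n_frames, 11, 2) float array, pixel coordinates.
    likelihood : (n_frames, 11) float array in [0, 1].
    frame_rate : frames per second.
    flow_schedule : ((velocity_cm_s, duration_s), ...) applied in order.
    arena : (xmin, ymin, xmax, ymax) pixel bounds of the usable chamber.
    meta : free-form assay metadata (fish_id, week, ...).
    """

    xy: np.ndarray
    likelihood: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    flow_schedule: tuple[tuple[float, float], ...] = DEFAULT_FLOW_SCHEDULE
    arena: tuple[float, float, float, float] = (0.0, 0.0, 600.0, 1400.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(f"xy must be (n, {N_KEYPOINTS}, 2), got {self.xy.shape}")
        if self.likelihood.shape != self.xy.shape[:2]:
            raise ValueError("likelihood shape must match xy frames x keypoints")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def flow_velocity(self) -> np.ndarray:
        """Per-frame flow velocity (cm/s) from the flow schedule."""
        out = np.zeros(self.n_frames)
        t = np.arange(self.n_frames) / self.frame_rate
        start = 0.0
        for vel, dur in self.flow_schedule:
            out[(t >= start) & (t < start + dur)] = vel
            start += dur
        out[t >= start] = self.flow_schedule[-1][0]
        return out

    def period_slice(self, velocity: float) -> np.ndarray:
        """Boolean mask of frames recorded at the given flow velocity."""
        return np.isclose(self.flow_velocity(), velocity)


@dataclass
class BehaviorEpisode:
    """A maximal run of frames sharing one behavior label.

    Frame spans are 0-based, half-open [start, end).
    """

    label: str
    start: int
    end: int
    flow_cm_s: float
    n_extrema: int = 0

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def episodes_to_labels(episodes: Iterable[BehaviorEpisode], n_frames: int) -> np.ndarray:
    """Expand episodes back to a per-frame label array ('' where unlabeled)."""
    labels = np.full(n_frames, "", dtype=object)
    for ep in episodes:
        labels[ep.start:ep.end] = ep.label
    return labels
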