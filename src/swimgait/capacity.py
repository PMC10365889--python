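"""Swim-capacity measurements from the centroid track and behavior labels.

The centroid is the mean of the 10 centerline keypoints; frames rejected by
the quality filters are excluded, and displacements bridge the gap between
flanking valid frames (the summed-displacement reading of swim distance).
All measurements are reported in pixels / fractions exactly as defined:
distance over the whole assay, activity over the whole assay, burst
frequency only in still water (0 cm/s), time-against-flow and mean-y only
while water is flowing (10 and 20 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PoseSequence

#: default activity threshold, px/frame at the reference 70 fps
ACTIVITY_THRESHOLD_REF = 0.25
REF_FRAME_RATE = 70.0
UPSTREAM = np.array([0.0, 1.0])     # +y points toward the flow source


def default_activity_threshold(frame_rate: float) -> float:
    return ACTIVITY_THRESHOLD_REF * (frame_rate / REF_FRAME_RATE)


@dataclass
class CentroidTrack:
    """Per-frame centroid positions with a validity flag."""

    xy: np.ndarray          # (n, 2)
    valid: np.ndarray       # (n,) bool

    @classmethod
    def from_centerline(cls, centerline: np.ndarray,
                        valid: np.ndarray) -> "CentroidTrack":
        return cls(xy=np.asarray(centerline)[:, :10].mean(axis=1),
                   valid=np.asarray(valid, dtype=bool))

    def displacements(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-valid-frame displacement vector from the previous valid frame.

        Returns (vectors (m, 2), frame indices (m,)) for the 2nd..m-th valid
        frames; gaps over rejected frames are bridged.
        """
        idx = np.nonzero(self.valid)[0]
        if len(idx) < 2:
            return np.empty((0, 2)), np.empty(0, dtype=int)
        pts = self.xy[idx]
        return np.diff(pts, axis=0), idx[1:]


def swim_distance(track: CentroidTrack) -> float:
    """Sum of frame-to-frame centroid displacement (px) over the assay."""
    vecs, _ = track.displacements()
    if len(vecs) == 0:
        return float("nan")
    return float(np.linalg.norm(vecs, axis=1).sum())


def activity_fraction(track: CentroidTrack, threshold: float) -> float:
    """Fraction of valid frames whose displacement from the previous valid
    frame exceeds ``threshold`` (px)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_valid = int(track.valid.sum())
    if n_valid == 0:
        return float("nan")
    vecs, _ = track.displacements()
    active = np.linalg.norm(vecs, axis=1) > threshold
    return float(active.sum() / n_valid)


def _active_frames(track: CentroidTrack, threshold: float) -> np.ndarray:
    """Boolean per-frame centroid-active flag (False where invalid)."""
    out = np.zeros(len(track.valid), dtype=bool)
    vecs, idx = track.displacements()
    out[idx] = np.linalg.norm(vecs, axis=1) > threshold
    return out


def burst_frequency(track_or_labels, seq: PoseSequence, source: str = "centroid",
                    threshold: float | None = None) -> float:
    """Bursts per minute during the 0 cm/s flow period.

    A burst is a maximal run of active frames; activity is centroid
    displacement above threshold (``source='centroid'``) or a non-rest
    behavior label (``source='pose'``).
    """
    still = seq.period_slice(0.0)
    if not still.any():
        raise ValueError("no 0 cm/s period in the assay")
    if source == "centroid":
        thr = default_activity_threshold(seq.frame_rate) if threshold is None \
            else threshold
        active = _active_frames(track_or_labels, thr)
    elif source == "pose":
        labels = np.asarray(track_or_labels, dtype=object)
        active = (labels != "rest") & (labels != "")
    else:
        raise ValueError("source must be 'centroid' or 'pose'")
    a = active[still]
    starts = int(np.count_nonzero(a[1:] & ~a[:-1]) + int(a[0]))
    minutes = still.sum() / seq.frame_rate / 60.0
    return float(starts / minutes)


def time_against_flow(track: CentroidTrack, seq: PoseSequence,
                      threshold: float | None = None,
                      max_deviation_deg: float = 45.0) -> float:
    """Fraction of flowing-period frames moving upstream above threshold.

    A frame counts when its displacement from the previous valid frame
    exceeds the activity threshold and its direction lies within +/-45
    degrees (inclusive) of the upstream direction.
    """
    flowing = ~seq.period_slice(0.0)
    if not flowing.any():
        return float("nan")
    thr = default_activity_threshold(seq.frame_rate) if threshold is None \
        else threshold
    vecs, idx = track.displacements()
    mag = np.linalg.norm(vecs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(mag > 0, vecs @ UPSTREAM / np.maximum(mag, 1e-12), -1.0)
    ok = (mag > thr) & (cosang >= np.cos(np.deg2rad(max_deviation_deg)) - 1e-12)
    counted = ok & flowing[idx]
    return float(counted.sum() / flowing.sum())


def mean_y_position(track: CentroidTrack, seq: PoseSequence) -> float:
    """Mean valid centroid y over flowing-period frames (px); higher is
    closer to the flow source."""
    flowing = ~seq.period_slice(0.0)
    sel = flowing & track.valid
    if not sel.any():
        return float("nan")
    return float(track.xy[sel, 1].mean())


def compute_capacity_metrics(track: CentroidTrack, labels: np.ndarray,
                             seq: PoseSequence,
                             threshold: float | None = None) -> dict[str, float]:
    """All five capacity measurements for one assay."""
    thr = default_activity_threshold(seq.frame_rate) if threshold is None \
        else threshold
    return {
        "distance": swim_distance(track),
        "activity": activity_fraction(track, thr),
        "centroid_burst_frequency": burst_frequency(track, seq, "centroid", thr),
        "pose_burst_frequency": burst_frequency(labels, seq, "pose"),
        "time_against_flow": time_against_flow(track, seq, thr),
        "mean_y": mean_y_position(track, seq),
    }
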