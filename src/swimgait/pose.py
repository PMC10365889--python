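"""Centerline pose processing: spline smoothing, angle poses, quality filters.

The processing chain mirrors how annotated keypoints become analysis-ready
posture data: each frame's 10 centerline keypoints are smoothed by a cubic
spline and resampled to 10 evenly spaced points; interior keypoint triplets
are reduced to 8 signed angles (the *angle pose*); frames failing any of four
quality criteria (keypoint likelihood, pose length, pose curvature, inter-
frame jump) are rejected from all downstream analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import N_ANGLES, N_CENTERLINE, PoseSequence

#: filter thresholds (likelihood > 0.5 at all keypoints; length within
#: 8 MAD of the assay median; |curvature z| < 8 per angle position;
#: movement <= 45 px at all keypoints vs the nearest accepted neighbor)
LIKELIHOOD_MIN = 0.5
LENGTH_MAD_MAX = 8.0
CURVATURE_Z_MAX = 8.0
JUMP_MAX_PX = 45.0
JUMP_LOOKBACK = 3

FILTER_REASONS = ("likelihood", "length", "curvature", "jump")


def resample_centerline(points: np.ndarray, n_dense: int = 400) -> np.ndarray:
    """Fit a natural cubic spline through 10 centerline points and resample
    10 evenly spaced (by arc length) points from it.

    Parameters
    ----------
    points : (10, 2) array of pixel coordinates, head -> tail-base.

    Raises ``ValueError`` on non-finite coordinates (frame unusable).
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (N_CENTERLINE, 2):
        raise ValueError(f"expected ({N_CENTERLINE}, 2) points, got {points.shape}")
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite keypoint coordinates")
    chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(chord <= 0):
        raise ValueError("coincident adjacent keypoints")
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, points, bc_type="natural", axis=0)
    ud = np.linspace(0.0, u[-1], n_dense)
    dense = spline(ud)
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    targets = np.linspace(0.0, arc[-1], N_CENTERLINE)
    ut = np.interp(targets, arc, ud)
    return spline(ut)


def resample_sequence(seq: PoseSequence) -> tuple[np.ndarray, np.ndarray]:
    """Resample every frame of a sequence.

    Returns (centerline (n, 10, 2), valid (n,) bool); frames with non-finite
    or degenerate keypoints are marked invalid and passed through unchanged.
    """
    n = seq.n_frames
    out = np.empty((n, N_CENTERLINE, 2))
    valid = np.ones(n, dtype=bool)
    for i in range(n):
        try:
            out[i] = resample_centerline(seq.xy[i, :N_CENTERLINE])
        except ValueError:
            out[i] = seq.xy[i, :N_CENTERLINE]
            valid[i] = False
    return out, valid


def compute_angle_pose(points: np.ndarray) -> np.ndarray:
    """Signed angles at the 8 interior keypoints of a 10-point centerline.

    For each triplet (A, B, C) the angle at B is the signed rotation taking
    the direction of AB onto the direction of BC, in (-pi, pi], positive
    counterclockwise.  A collinear centerline yields all zeros.
    """
    points = np.asarray(points, dtype=float)
    single = points.ndim == 2
    pts = points[None] if single else points
    d = np.diff(pts, axis=-2)                      # (n, 9, 2) segment vectors
    norms = np.linalg.norm(d, axis=-1)
    if np.any(norms == 0):
        raise ValueError("coincident adjacent keypoints (zero-length segment)")
    a, b = d[:, :-1], d[:, 1:]
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = (a * b).sum(axis=-1)
    ang = np.arctan2(cross, dot)                   # (n, 8)
    return ang[0] if single else ang


def apply_quality_filters(seq: PoseSequence,
                          centerline: np.ndarray | None = None,
                          angles: np.ndarray | None = None,
                          resample_valid: np.ndarray | None = None
                          ) -> pd.DataFrame:
    """Per-frame quality mask with failure reasons.

    A frame passes iff (i) every keypoint likelihood exceeds 0.5; (ii) its
    total polyline length lies within 8 median absolute deviations of the
    assay median; (iii) every angle's z-score (per angle position, within the
    assay) is below 8 in magnitude; (iv) every keypoint moved at most 45 px
    relative to the nearest previously accepted frame within 3 frames (the
    criterion is skipped when no such frame exists).

    Returns a DataFrame with boolean columns ``pass``, one per reason, and a
    string ``reason`` column (first failed criterion, '' if passing).
    """
    n = seq.n_frames
    if n < 20:
        raise ValueError("need >= 20 frames to estimate assay statistics")
    if centerline is None or resample_valid is None:
        centerline, resample_valid = resample_sequence(seq)
    if angles is None:
        angles = np.zeros((n, N_ANGLES))
        angles[resample_valid] = compute_angle_pose(centerline[resample_valid])

    fail = {r: np.zeros(n, dtype=bool) for r in FILTER_REASONS}
    fail["likelihood"] = (seq.likelihood <= LIKELIHOOD_MIN).any(axis=1)

    lengths = np.linalg.norm(np.diff(seq.xy, axis=1), axis=2).sum(axis=1)
    med = np.median(lengths)
    mad = np.median(np.abs(lengths - med))
    if mad > 0:
        fail["length"] = np.abs(lengths - med) > LENGTH_MAD_MAX * mad

    mu = angles.mean(axis=0)
    sd = angles.std(axis=0)
    sd[sd == 0] = np.inf
    z = (angles - mu) / sd
    fail["curvature"] = (np.abs(z) >= CURVATURE_Z_MAX).any(axis=1)

    static_ok = ~(fail["likelihood"] | fail["length"] | fail["curvature"]) \
        & resample_valid
    accepted = np.zeros(n, dtype=bool)
    last_accepted = -10**9
    for i in range(n):
        ok = static_ok[i]
        if ok and i - last_accepted <= JUMP_LOOKBACK and last_accepted >= 0:
            move = np.linalg.norm(seq.xy[i] - seq.xy[last_accepted], axis=1).max()
            if move > JUMP_MAX_PX:
                fail["jump"][i] = True
                ok = False
        if ok:
            accepted[i] = True
            last_accepted = i

    mask = pd.DataFrame({"pass": accepted})
    for r in FILTER_REASONS:
        mask[f"fail_{r}"] = fail[r]
    mask["fail_resample"] = ~resample_valid
    reason = np.full(n, "", dtype=object)
    for r in reversed(FILTER_REASONS):
        reason[fail[r]] = r
    mask["reason"] = reason
    if not accepted.any():
        warnings.warn("all frames failed quality filters", stacklevel=2)
    return mask


def mask_wall_frames(centerline: np.ndarray,
                     arena: tuple[float, float, float, float],
                     margin: float | None = None) -> np.ndarray:
    """True where any centerline keypoint lies within ``margin`` of an edge.

    ``margin`` defaults to one body length (the median polyline length of
    the given frames).
    """
    centerline = np.atleast_3d(centerline)
    if margin is None:
        margin = float(np.median(np.linalg.norm(
            np.diff(centerline, axis=-2), axis=-1).sum(axis=-1)))
    xmin, ymin, xmax, ymax = arena
    if margin >= (xmax - xmin) / 2 or margin >= (ymax - ymin) / 2:
        raise ValueError("margin must be smaller than half the arena extent")
    if margin <= 0:
        return np.zeros(centerline.shape[0], dtype=bool)
    x, y = centerline[..., 0], centerline[..., 1]
    near = (x < xmin + margin) | (x > xmax - margin) \
        | (y < ymin + margin) | (y > ymax - margin)
    return near.any(axis=-1)


def process_assay(seq: PoseSequence) -> dict:
    """Run the full pose-processing chain on one assay.

    Returns a dict with ``centerline`` (n, 10, 2), ``tail_tip`` (n, 2),
    ``angles`` (n, 8), ``quality`` (DataFrame) and ``valid`` (bool mask of
    frames passing all filters).
    """
    centerline, rvalid = resample_sequence(seq)
    angles = np.zeros((seq.n_frames, N_ANGLES))
    if rvalid.any():
        angles[rvalid] = compute_angle_pose(centerline[rvalid])
    quality = apply_quality_filters(seq, centerline, angles, rvalid)
    return {"centerline": centerline, "tail_tip": seq.xy[:, -1],
            "angles": angles, "quality": quality,
            "valid": quality["pass"].to_numpy()}
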