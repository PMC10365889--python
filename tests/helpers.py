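"""Independent oracles used to cross-check pipeline computations."""

from __future__ import annotations

import numpy as np


def angle_oracle(points: np.ndarray) -> np.ndarray:
    """Signed interior angles via direction-angle differences (trigonometric
    oracle, independent of the cross/dot implementation)."""
    pts = np.asarray(points, dtype=float)
    d = np.diff(pts, axis=0)
    theta = np.arctan2(d[:, 1], d[:, 0])
    raw = np.diff(theta)
    return np.arctan2(np.sin(raw), np.cos(raw))   # wrap to (-pi, pi]


def dtw_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive warping-path enumeration with the symmetric step pattern
    (diagonal steps cost twice the local distance)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n, m = len(a), len(b)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    best = [np.inf]

    def rec(i: int, j: int, cost: float) -> None:
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, cost + 2.0 * d[i + 1, j + 1])
        if i + 1 < n:
            rec(i + 1, j, cost + d[i + 1, j])
        if j + 1 < m:
            rec(i, j + 1, cost + d[i, j + 1])

    rec(0, 0, 2.0 * d[0, 0])
    return float(best[0])


def random_smooth_centerline(rng: np.random.Generator,
                             n_points: int = 10) -> np.ndarray:
    """A random smooth 10-point centerline (low-frequency bend, no kinks)."""
    seg = rng.uniform(15.0, 25.0)
    amp = rng.uniform(0.0, 0.35)
    phase = rng.uniform(0.0, 2 * np.pi)
    freq = rng.uniform(0.3, 1.2)
    angles = amp * np.sin(freq * np.arange(n_points - 2) + phase)
    heading = rng.uniform(0.0, 2 * np.pi)
    dirs = heading + np.concatenate([[0.0], np.cumsum(angles)])
    steps = seg * np.stack([np.cos(dirs), np.sin(dirs)], axis=1)
    pts = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return pts + rng.uniform(-500, 500, size=2)
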