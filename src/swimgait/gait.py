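"""Gait-quality measurements.

The central object is the *cruise curvature profile*: per assay, the mean
center-to-peak angular amplitude at each of the 8 angle positions during
cruise episodes.  *Rostral compensation* — the maximum absolute difference
between an assay's profile and the uninjured control profile at the five
rostral positions — quantifies the head-heavy swimming of acutely injured
fish.  The module also measures cruise angular frequency, tail-beat
frequency, Strouhal number (still water only), the rest-bout-weighted
scoliosis score and a local-outlier-factor posture-novelty fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from sklearn.cluster import KMeans
from sklearn.neighbors import LocalOutlierFactor

from .core import N_ANGLES, BehaviorEpisode, PoseSequence

N_ROSTRAL = 5
_SG_WINDOW = 7      # light temporal smoothing before extremum detection
_SG_ORDER = 3


def _smooth(x: np.ndarray) -> np.ndarray:
    if len(x) >= _SG_WINDOW:
        return savgol_filter(x, _SG_WINDOW, _SG_ORDER)
    return x


def _extrema_indices(x: np.ndarray) -> np.ndarray:
    """Sorted indices of peaks and troughs of a (smoothed) trace."""
    prom = max(0.3 * x.std(), 1e-4)
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    return np.sort(np.concatenate([peaks, troughs]))


def halfcycle_amplitude(trace: np.ndarray) -> float:
    """Center-to-peak amplitude of an oscillating trace.

    Estimated per half-cycle as half the peak-to-trough excursion between
    consecutive extrema, averaged over the trace.  NaN when fewer than two
    extrema are found.
    """
    x = _smooth(np.asarray(trace, dtype=float))
    ext = _extrema_indices(x)
    if len(ext) < 2:
        return float("nan")
    vals = x[ext]
    return float(np.abs(np.diff(vals)).mean() / 2.0)


def oscillation_frequency(trace: np.ndarray, frame_rate: float) -> float:
    """Oscillations per second from successive same-sign extrema intervals.

    The median inter-extremum interval (rather than the mean) keeps the
    estimate robust to spurious noise peaks at low-amplitude angle
    positions.
    """
    x = np.asarray(trace, dtype=float) - np.mean(trace)
    if len(x) >= 11:
        x = savgol_filter(x, 11, 3)
    prom = max(0.7 * x.std(), 1e-4)
    freqs = []
    for sign in (1.0, -1.0):
        idx, _ = find_peaks(sign * x, prominence=prom)
        if len(idx) >= 2:
            freqs.append(frame_rate / np.median(np.diff(idx)))
    if not freqs:
        return float("nan")
    return float(np.mean(freqs))


@dataclass
class CruiseCurvatureProfile:
    """Per-assay mean center-to-peak amplitudes at the 8 angle positions."""

    amplitudes: np.ndarray          # (8,), radians
    n_cruises: int
    assay_key: tuple = ()

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (N_ANGLES,):
            raise ValueError("profile must have 8 amplitudes")


def cruise_curvature_profile(cruise_angles: list[np.ndarray],
                             assay_key: tuple = ()) -> CruiseCurvatureProfile | None:
    """Profile from the angle traces of an assay's cruise episodes.

    Per angle position, the per-episode amplitude is the mean half-cycle
    center-to-peak excursion; episode profiles are then averaged.  Returns
    None when no episode yields a measurable profile (the assay is excluded
    downstream, as for fish that never cruise).
    """
    per_episode = []
    for ang in cruise_angles:
        ang = np.asarray(ang, dtype=float)
        amps = np.array([halfcycle_amplitude(ang[:, i]) for i in range(N_ANGLES)])
        if np.isfinite(amps).any():
            per_episode.append(amps)
    if not per_episode:
        return None
    stacked = np.array(per_episode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(stacked, axis=0)   # per position, over episodes
    if not np.isfinite(profile).all():
        return None
    return CruiseCurvatureProfile(profile, n_cruises=len(per_episode),
                                  assay_key=assay_key)


def control_profile(profiles: list[CruiseCurvatureProfile]) -> np.ndarray:
    """Mean amplitude profile over uninjured assays."""
    if not profiles:
        raise ValueError("no control profiles available")
    return np.mean([p.amplitudes for p in profiles], axis=0)


def rostral_compensation(profile: CruiseCurvatureProfile | None,
                         control: np.ndarray) -> float:
    """Max absolute profile-vs-control difference at rostral positions 1-5."""
    if profile is None:
        return float("nan")
    diff = np.abs(profile.amplitudes[:N_ROSTRAL] - np.asarray(control)[:N_ROSTRAL])
    return float(diff.max())


def summed_rostral_amplitude(profile: CruiseCurvatureProfile | None) -> float:
    """Sum of the profile at rostral positions 1-5."""
    if profile is None:
        return float("nan")
    return float(profile.amplitudes[:N_ROSTRAL].sum())


def cruise_angular_frequency(cruise_angles: list[np.ndarray],
                             frame_rate: float) -> float:
    """Posture oscillations per second.

    Frequency is measured at each of the 8 angle positions, averaged over
    positions within a cruise, then averaged over cruises.
    """
    per_cruise = []
    for ang in cruise_angles:
        f = [oscillation_frequency(ang[:, i], frame_rate) for i in range(N_ANGLES)]
        f = [v for v in f if np.isfinite(v)]
        if f:
            per_cruise.append(np.mean(f))
    if not per_cruise:
        return float("nan")
    return float(np.mean(per_cruise))


# ---------------------------------------------------------------------------
# tail kinematics

def tail_lateral_trace(centerline: np.ndarray, tail_tip: np.ndarray,
                       smooth_frames: int = 35) -> np.ndarray:
    """Tail-tip displacement perpendicular to the smoothed heading.

    The heading axis is the (temporally smoothed) tail-base -> head vector;
    lateral displacement is the tail-tip position relative to the head,
    projected on the perpendicular of that axis.
    """
    head = centerline[:, 0]
    base = centerline[:, -1]
    axis = head - base
    if len(axis) >= smooth_frames:
        w = smooth_frames if smooth_frames % 2 == 1 else smooth_frames + 1
        axis = savgol_filter(axis, w, 2, axis=0)
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = axis / np.maximum(norm, 1e-9)
    perp = np.stack([-axis[:, 1], axis[:, 0]], axis=1)
    rel = tail_tip - head
    return (rel * perp).sum(axis=1)


def tail_beat_frequency(lateral: np.ndarray, frame_rate: float) -> float:
    """Oscillation frequency (Hz) of a tail-tip lateral trace.

    NaN when fewer than 3 extrema are measurable (e.g. a static tail).
    """
    x = _smooth(np.asarray(lateral, dtype=float) - np.mean(lateral))
    prom = max(0.3 * x.std(), 1e-3)
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    if len(peaks) + len(troughs) < 3:
        return float("nan")
    freqs = []
    for idx in (peaks, troughs):
        if len(idx) >= 2:
            freqs.append(frame_rate / np.diff(idx).mean())
    return float(np.mean(freqs)) if freqs else float("nan")


def assay_tail_beat_frequency(centerline: np.ndarray, tail_tip: np.ndarray,
                              episodes: list[BehaviorEpisode],
                              frame_rate: float,
                              flow_velocities: tuple[float, ...] | None = (0.0,)
                              ) -> float:
    """Duration-weighted mean tail-beat frequency over cruise episodes in the
    selected flow period(s) (all periods when ``flow_velocities`` is None)."""
    lateral = tail_lateral_trace(centerline, tail_tip)
    vals, weights = [], []
    for ep in episodes:
        if ep.label != "cruise":
            continue
        if flow_velocities is not None and ep.flow_cm_s not in flow_velocities:
            continue
        f = tail_beat_frequency(lateral[ep.start:ep.end], frame_rate)
        if np.isfinite(f):
            vals.append(f)
            weights.append(ep.n_frames)
    if not vals:
        return float("nan")
    return float(np.average(vals, weights=weights))


def strouhal_number(centerline: np.ndarray, tail_tip: np.ndarray,
                    episodes: list[BehaviorEpisode], frame_rate: float,
                    valid: np.ndarray | None = None) -> float:
    """Assay Strouhal number St = f * A / U over still-water cruises.

    Per cruise: f is the tail-beat frequency, A the mean peak-to-trough
    lateral tail-tip excursion, U the mean centroid speed.  Cruises with
    U = 0 are excluded; the assay St is the average weighted by each
    cruise's observed period count.
    """
    lateral = tail_lateral_trace(centerline, tail_tip)
    centroid = centerline[:, :10].mean(axis=1)
    sts, weights = [], []
    for ep in episodes:
        if ep.label != "cruise" or ep.flow_cm_s != 0.0:
            continue
        x = _smooth(lateral[ep.start:ep.end] - lateral[ep.start:ep.end].mean())
        prom = max(0.3 * x.std(), 1e-3)
        peaks, _ = find_peaks(x, prominence=prom)
        troughs, _ = find_peaks(-x, prominence=prom)
        if len(peaks) < 2 or len(troughs) < 1:
            continue
        f = tail_beat_frequency(lateral[ep.start:ep.end], frame_rate)
        ext = np.sort(np.concatenate([peaks, troughs]))
        amp = float(np.abs(np.diff(x[ext])).mean())        # peak-to-peak
        c = centroid[ep.start:ep.end]
        if valid is not None:
            c = c[valid[ep.start:ep.end]]
        if len(c) < 2:
            continue
        dist = np.linalg.norm(np.diff(c, axis=0), axis=1).sum()
        u = dist * frame_rate / (len(c) - 1)
        if u <= 0 or not np.isfinite(f):
            continue
        n_periods = min(len(peaks), len(troughs))
        sts.append(f * amp / u)
        weights.append(n_periods)
    if not sts:
        return float("nan")
    return float(np.average(sts, weights=weights))


# ---------------------------------------------------------------------------
# posture-derived scores

def scoliosis_score(rest_angles: list[np.ndarray],
                    weights: list[int] | None = None) -> float:
    """Rest-bout-weighted magnitude of the summed angle pose.

    Each rest bout contributes the absolute value of its mean summed angle
    pose; bouts are averaged weighted by their length.  Analyzing bouts
    separately keeps the score high for fish that flip dorso-ventrally
    between bouts (sign inversions would otherwise cancel).
    """
    if not rest_angles:
        return float("nan")
    mags, w = [], []
    for k, ang in enumerate(rest_angles):
        ang = np.asarray(ang, dtype=float)
        if ang.size == 0:
            continue
        bout_mean = ang.sum(axis=1).mean()
        mags.append(abs(bout_mean))
        w.append(weights[k] if weights is not None else len(ang))
    if not mags:
        return float("nan")
    return float(np.average(mags, weights=w))


@dataclass
class PostureNoveltyScorer:
    """Local-outlier-factor novelty detection against control posture.

    The training set samples 1,200 poses per control assay: 100 poses from
    each of 12 k-means clusters (with replacement when a cluster is small).
    ``score_assay`` returns the fraction of an assay's poses flagged novel.
    """

    n_clusters: int = 12
    samples_per_cluster: int = 100
    n_neighbors: int = 20
    random_state: int = 0

    def fit(self, control_angle_sets: list[np.ndarray]) -> "PostureNoveltyScorer":
        if not control_angle_sets:
            raise ValueError("need at least one control assay")
        samples = []
        for k, ang in enumerate(control_angle_sets):
            ang = np.asarray(ang, dtype=float)
            if len(np.unique(ang.round(9), axis=0)) < self.n_clusters:
                raise ValueError("fewer than 12 distinct control poses")
            km = KMeans(n_clusters=self.n_clusters, n_init=4,
                        random_state=self.random_state + k)
            lab = km.fit_predict(ang)
            rng = np.random.default_rng(self.random_state + k)
            for c in range(self.n_clusters):
                members = np.nonzero(lab == c)[0]
                if len(members) == 0:
                    continue
                take = rng.choice(members, size=self.samples_per_cluster,
                                  replace=len(members) < self.samples_per_cluster)
                samples.append(ang[take])
        X = np.vstack(samples)
        self.lof_ = LocalOutlierFactor(n_neighbors=self.n_neighbors,
                                       novelty=True, contamination="auto")
        self.lof_.fit(X)
        return self

    def score_assay(self, angles: np.ndarray) -> float:
        if not hasattr(self, "lof_"):
            raise ValueError("scorer is not fitted")
        angles = np.asarray(angles, dtype=float)
        if len(angles) == 0:
            return float("nan")
        return float((self.lof_.predict(angles) == -1).mean())


def posture_novelty(angles: np.ndarray, control_angle_sets: list[np.ndarray],
                    random_state: int = 0) -> float:
    """Functional wrapper: fit on controls, score one assay."""
    scorer = PostureNoveltyScorer(random_state=random_state)
    return scorer.fit(control_angle_sets).score_assay(angles)


# ---------------------------------------------------------------------------
# assay-level orchestration

def episode_angles(angles: np.ndarray, episodes: list[BehaviorEpisode],
                   label: str) -> list[np.ndarray]:
    return [angles[ep.start:ep.end] for ep in episodes if ep.label == label]


def compute_gait_metrics(angles: np.ndarray, centerline: np.ndarray,
                         tail_tip: np.ndarray, episodes: list[BehaviorEpisode],
                         seq: PoseSequence,
                         control: np.ndarray | None = None,
                         valid: np.ndarray | None = None,
                         assay_key: tuple = ()) -> dict:
    """Gait metrics for one assay; profile-dependent scores are NaN when the
    assay has no measurable cruise."""
    cruises = episode_angles(angles, episodes, "cruise")
    rests = episode_angles(angles, episodes, "rest")
    profile = cruise_curvature_profile(cruises, assay_key)
    out = {
        "profile": profile,
        "summed_rostral_amplitude": summed_rostral_amplitude(profile),
        "cruise_angular_frequency": cruise_angular_frequency(
            cruises, seq.frame_rate),
        "tail_beat_frequency": assay_tail_beat_frequency(
            centerline, tail_tip, episodes, seq.frame_rate),
        "strouhal": strouhal_number(centerline, tail_tip, episodes,
                                    seq.frame_rate, valid),
        "scoliosis": scoliosis_score(rests),
    }
    out["rostral_compensation"] = (
        rostral_compensation(profile, control) if control is not None
        else float("nan"))
    return out
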