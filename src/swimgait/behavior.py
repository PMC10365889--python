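"""Behavior annotation: pose windows, class balancing, classification and
episode segmentation.

Every quality-passing frame is labeled rest, cruise or turn (clockwise /
counterclockwise).  Classification operates on *pose windows*: the frame's
angle pose concatenated with the six angle poses before and after it (13 x 8
= 104 components), labeled with the middle frame's behavior.  Training
balances classes by synthetic minority oversampling, embeds windows with a
2-component UMAP (50 nearest neighbors) and fits a random forest on the
embedding; a posture-change threshold then re-labels near-static frames as
rest.  Cruises are defined as forward swims with at least five measured
lateral extrema (about three body oscillations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split

from .core import N_ANGLES, BehaviorEpisode

WINDOW_HALF = 6                       # frames each side of the center frame
WINDOW_LEN = 2 * WINDOW_HALF + 1      # 13 frames
WINDOW_DIM = WINDOW_LEN * N_ANGLES    # 104 components
MIN_CRUISE_EXTREMA = 5
LABELS = ("rest", "cruise", "turn_cw", "turn_ccw")

#: rest-threshold search grid (rad): 50 log-spaced values
REST_THRESHOLD_GRID = np.logspace(np.log10(1e-4), np.log10(0.5), 50)


def build_pose_windows(angles: np.ndarray, valid: np.ndarray,
                       labels: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Concatenate 13-frame neighborhoods of quality-passing frames.

    A window is emitted for every frame whose full 13-frame neighborhood
    passes quality; sequence edges produce no windows.  Returns
    (windows (m, 104), center frame indices (m,), center labels or None).
    """
    angles = np.asarray(angles, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = angles.shape[0]
    if n < WINDOW_LEN:
        empty = np.empty((0, WINDOW_DIM))
        return empty, np.empty(0, dtype=int), (np.empty(0, dtype=object)
                                               if labels is not None else None)
    # neighborhood fully valid <=> running sum of valid over 13 frames == 13
    ok = np.convolve(valid.astype(int), np.ones(WINDOW_LEN, dtype=int),
                     mode="valid") == WINDOW_LEN
    centers = np.nonzero(ok)[0] + WINDOW_HALF
    idx = centers[:, None] + np.arange(-WINDOW_HALF, WINDOW_HALF + 1)[None, :]
    windows = angles[idx].reshape(len(centers), WINDOW_DIM)
    y = None
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        y = labels[centers]
    return windows, centers, y


class SMOTESampler:
    """Synthetic minority oversampling to the majority-class count.

    Synthetic members are convex combinations of a class member and one of
    its k nearest same-class neighbors (k = 20 by default, clamped with a
    warning when a class is too small).
    """

    def __init__(self, k_neighbors: int = 20, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes to balance")
        target = counts.max()
        rng = np.random.default_rng(self.random_state)
        parts_X, parts_y = [X], [y]
        from sklearn.neighbors import NearestNeighbors
        for cls, cnt in zip(classes, counts):
            need = target - cnt
            if need == 0:
                continue
            Xc = X[y == cls]
            k = min(self.k_neighbors, cnt - 1)
            if k < 1:
                raise ValueError(f"class {cls!r} has a single member")
            if k < self.k_neighbors:
                warnings.warn(
                    f"class {cls!r} has {cnt} members; k clamped to {k}",
                    stacklevel=2)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, nbr = nn.kneighbors(Xc)
            base = rng.integers(0, cnt, size=need)
            pick = nbr[base, rng.integers(1, k + 1, size=need)]
            lam = rng.uniform(0.0, 1.0, size=need)[:, None]
            synth = Xc[base] + lam * (Xc[pick] - Xc[base])
            parts_X.append(synth)
            parts_y.append(np.full(need, cls, dtype=object))
        return np.vstack(parts_X), np.concatenate(parts_y)


def balance_classes(X: np.ndarray, y: np.ndarray, k_neighbors: int = 20,
                    random_state: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper over :class:`SMOTESampler`."""
    return SMOTESampler(k_neighbors, random_state).fit_resample(X, y)


def _window_frame_changes(windows: np.ndarray) -> np.ndarray:
    """Per window: min over (previous, next) of the max absolute angle change
    of the center frame — the quantity the rest threshold acts on."""
    w = windows.reshape(len(windows), WINDOW_LEN, N_ANGLES)
    center, prev, nxt = w[:, WINDOW_HALF], w[:, WINDOW_HALF - 1], w[:, WINDOW_HALF + 1]
    d_prev = np.abs(center - prev).max(axis=1)
    d_next = np.abs(center - nxt).max(axis=1)
    return np.minimum(d_prev, d_next)


@dataclass
class BehaviorClassifier:
    """UMAP + random-forest behavior classifier with a rest threshold.

    sklearn-style estimator: ``fit(X, y)`` on balanced pose windows, then
    ``predict(X)``.  ``rest_threshold_`` holds the optimized posture-change
    threshold; frames whose center angle pose differs from the previous or
    the next pose by at most this value are re-labeled rest.
    """

    n_neighbors: int = 50
    n_components: int = 2
    n_estimators: int = 200
    threshold_grid: np.ndarray = field(
        default_factory=lambda: REST_THRESHOLD_GRID.copy())
    random_state: int = 0

    def get_params(self, deep: bool = True) -> dict:
        return {"n_neighbors": self.n_neighbors, "n_components": self.n_components,
                "n_estimators": self.n_estimators,
                "threshold_grid": self.threshold_grid,
                "random_state": self.random_state}

    def set_params(self, **params) -> "BehaviorClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BehaviorClassifier":
        import umap

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        n_nb = min(self.n_neighbors, len(X) - 1)
        if n_nb < self.n_neighbors:
            warnings.warn(f"n_neighbors reduced to {n_nb}", stacklevel=2)
        self.umap_ = umap.UMAP(n_components=self.n_components,
                               n_neighbors=n_nb,
                               random_state=self.random_state)
        emb = self.umap_.fit_transform(X)
        if np.allclose(emb.std(axis=0), 0.0):
            raise ValueError("degenerate embedding: all points identical")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state,
            n_jobs=1)
        self.forest_.fit(emb, y.astype(str))
        # optimize the rest threshold on the training windows: maximize the
        # balanced accuracy of the final (classifier + threshold) labeling,
        # scored through the deployed path (out-of-sample embedding transform)
        raw = self.forest_.predict(self.umap_.transform(X))
        changes = _window_frame_changes(X)
        best_t, best_score = 0.0, -np.inf
        for t in self.threshold_grid:
            lab = raw.copy()
            lab[changes <= t] = "rest"
            score = balanced_accuracy_score(y.astype(str), lab)
            if score > best_score + 1e-12:
                best_t, best_score = float(t), score
        self.rest_threshold_ = best_t
        self.train_score_ = best_score
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "forest_"):
            raise ValueError("classifier is not fitted")

    def predict(self, X: np.ndarray, apply_threshold: bool = True) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            return np.empty(0, dtype=object)
        emb = self.umap_.transform(X)
        lab = self.forest_.predict(emb).astype(object)
        if apply_threshold:
            changes = _window_frame_changes(X)
            lab[changes <= self.rest_threshold_] = "rest"
        return lab


def per_class_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    out = {}
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    for cls in np.unique(y_true):
        m = y_true == cls
        out[str(cls)] = float((y_pred[m] == cls).mean())
    return out


def train_behavior_classifier(windows: np.ndarray, labels: np.ndarray,
                              rng_seed: int = 0,
                              validation_fraction: float = 0.25,
                              oversample_validation: bool = False,
                              **clf_params) -> BehaviorClassifier:
    """Split, balance and train; attach a training report.

    25% of the annotated windows are withheld for validation.  The training
    split is balanced by SMOTE; held-out accuracy is reported on the raw
    validation split by default (set ``oversample_validation`` to score an
    oversampled validation set as well).
    """
    X = np.asarray(windows, dtype=float)
    y = np.asarray(labels, dtype=object)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=validation_fraction, random_state=rng_seed, stratify=y)
    X_bal, y_bal = balance_classes(X_tr, y_tr, random_state=rng_seed)
    clf = BehaviorClassifier(random_state=rng_seed, **clf_params)
    clf.fit(X_bal, y_bal)
    report = {
        "train": per_class_accuracy(y_tr, clf.predict(X_tr)),
        "validation": per_class_accuracy(y_va, clf.predict(X_va)),
    }
    if oversample_validation:
        X_vb, y_vb = balance_classes(X_va, y_va, random_state=rng_seed)
        report["validation_oversampled"] = per_class_accuracy(
            y_vb, clf.predict(X_vb))
    clf.report_ = report
    return clf


def annotate_frames(angles: np.ndarray, valid: np.ndarray,
                    clf: BehaviorClassifier,
                    inherit_window: int = 6) -> np.ndarray:
    """Per-frame behavior labels for one assay.

    Windowed frames get the classifier's (threshold-adjusted) label; frames
    without windows inherit the nearest labeled frame's label within
    ``inherit_window`` frames (the earlier frame wins ties), else stay
    unlabeled ('').
    """
    n = len(angles)
    labels = np.full(n, "", dtype=object)
    windows, centers, _ = build_pose_windows(angles, valid)
    if len(centers):
        labels[centers] = clf.predict(windows)
    labeled = np.nonzero(labels != "")[0]
    if len(labeled):
        unlabeled = np.nonzero(labels == "")[0]
        pos = np.searchsorted(labeled, unlabeled)
        prev = labeled[np.clip(pos - 1, 0, len(labeled) - 1)]
        nxt = labeled[np.clip(pos, 0, len(labeled) - 1)]
        d_prev = np.abs(unlabeled - prev)
        d_next = np.abs(nxt - unlabeled)
        use_prev = d_prev <= d_next          # earlier frame wins ties
        src = np.where(use_prev, prev, nxt)
        dist = np.where(use_prev, d_prev, d_next)
        ok = dist <= inherit_window
        labels[unlabeled[ok]] = labels[src[ok]]
    return labels


def count_extrema(trace: np.ndarray, frame_rate: float,
                  smooth: bool = True) -> int:
    """Count lateral extrema (peaks + troughs) of a 1-D oscillation trace."""
    x = np.asarray(trace, dtype=float)
    if len(x) < 5:
        return 0
    x = x - x.mean()
    if smooth and len(x) >= 9:
        x = savgol_filter(x, 9, 3)
    prom = max(0.35 * x.std(), 1e-3)
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    return len(peaks) + len(troughs)


def segment_episodes(labels: np.ndarray, angles: np.ndarray,
                     frame_rate: float,
                     flow_velocity: np.ndarray | None = None
                     ) -> list[BehaviorEpisode]:
    """Merge per-frame labels into episodes.

    Maximal same-label runs become episodes; cruise runs with fewer than 5
    extrema (counted on the mean rostro-caudal angle trace) are demoted and
    not emitted.  Flow context is read from the per-frame flow velocity at
    the episode start.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    episodes: list[BehaviorEpisode] = []
    i = 0
    while i < n:
        lab = labels[i]
        j = i + 1
        while j < n and labels[j] == lab:
            j += 1
        if lab != "":
            flow = float(flow_velocity[i]) if flow_velocity is not None else 0.0
            n_ext = 0
            keep = True
            if lab == "cruise":
                mean_trace = angles[i:j].mean(axis=1)
                n_ext = count_extrema(mean_trace, frame_rate)
                keep = n_ext >= MIN_CRUISE_EXTREMA
            if keep:
                episodes.append(BehaviorEpisode(label=str(lab), start=i, end=j,
                                                flow_cm_s=flow, n_extrema=n_ext))
        i = j
    return episodes
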