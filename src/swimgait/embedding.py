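"""Cruise embedding: PCA traces, dynamic time warping, exemplar selection and
UMAP of the exemplar distance matrix.

Cruise episodes are projected onto 5 principal components of the angle poses
(fitted over the union of assays being embedded so traces share one
coordinate system), pairwise DTW distances are computed between traces,
affinity propagation picks exemplar cruises per assay (falling back to a
random sample of at most 16 on non-convergence), and the exemplar DTW matrix
is embedded with UMAP (precomputed metric, 20 nearest neighbors, 3 output
components).  Fish with scoliosis scores above 0.35 are excluded before
embedding so body shape does not dominate gait structure.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning

N_PCA_COMPONENTS = 5
SCOLIOSIS_CUTOFF = 0.35       # fish above this score are omitted
MAX_SAMPLED_CRUISES = 16
UMAP_NEIGHBORS = 20
UMAP_COMPONENTS = 3


def decompose_cruises(cruise_angle_sets: list[np.ndarray],
                      n_components: int = N_PCA_COMPONENTS
                      ) -> tuple[list[np.ndarray], PCA]:
    """Fit PCA on all cruise frames and project each cruise to a score trace.

    Returns (traces, fitted PCA); each trace is (n_frames, n_components).
    """
    if not cruise_angle_sets:
        raise ValueError("no cruises to decompose")
    stacked = np.vstack(cruise_angle_sets)
    if len(stacked) < 2:
        raise ValueError("need at least 2 cruise frames for a decomposition")
    pca = PCA(n_components=n_components)
    pca.fit(stacked)
    return [pca.transform(a) for a in cruise_angle_sets], pca


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic time warping distance between two multivariate traces.

    Euclidean local cost, symmetric step pattern with the diagonal step
    weighted twice (symmetric2), no window constraint, no path-length
    normalization.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.ndim == 2 and a.shape[0] == 1 and a.shape[1] > 1 and b.shape[1] != a.shape[1]:
        raise ValueError("trace dimensionalities differ")
    if a.size == 0 or b.size == 0:
        raise ValueError("empty trace")
    if a.shape[1] != b.shape[1]:
        raise ValueError("trace dimensionalities differ")
    n, m = a.shape[0], b.shape[0]
    if n < 2 or m < 2:
        raise ValueError("traces must have length >= 2")
    d = cdist(a, b)
    D = np.full((n, m), np.inf)
    D[0, 0] = 2.0 * d[0, 0]
    D[1:, 0] = D[0, 0] + np.cumsum(d[1:, 0])
    D[0, 1:] = D[0, 0] + np.cumsum(d[0, 1:])
    # fill by anti-diagonals so each step is a vectorized 3-way minimum
    for k in range(2, n + m - 1):
        i = np.arange(max(1, k - m + 1), min(n - 1, k - 1) + 1)
        if len(i) == 0:
            continue
        j = k - i
        dij = d[i, j]
        best = np.minimum(D[i - 1, j - 1] + 2.0 * dij,
                          np.minimum(D[i - 1, j], D[i, j - 1]) + dij)
        D[i, j] = best
    return float(D[-1, -1])


def dtw_distance_normalized(a: np.ndarray, b: np.ndarray) -> float:
    """Path-length-normalized variant (divides by n + m)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    return dtw_distance(a, b) / (a.shape[0] + b.shape[0])


def dtw_matrix(traces: list[np.ndarray]) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix with zero diagonal."""
    n = len(traces)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(traces[i], traces[j])
    return D


def select_exemplars(traces: list[np.ndarray], random_state: int = 0,
                     damping: float = 0.9, max_iter: int = 700,
                     convergence_iter: int = 200) -> list[int]:
    """Exemplar cruise indices for one assay.

    Affinity propagation on the negative DTW distance matrix (preference =
    median similarity); on non-convergence, a seeded random sample of at
    most 16 cruises.  Exemplars are always actual cruises.
    """
    n = len(traces)
    if n == 0:
        return []
    if n == 1:
        return [0]
    D = dtw_matrix(traces)
    ap = AffinityPropagation(affinity="precomputed", damping=damping,
                             max_iter=max_iter,
                             convergence_iter=convergence_iter,
                             random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap.fit(-D)
            centers = np.asarray(ap.cluster_centers_indices_)
            if centers is None or len(centers) == 0:
                raise ConvergenceWarning("no exemplars")
            return sorted(int(c) for c in centers)
        except ConvergenceWarning:
            rng = np.random.default_rng(random_state)
            k = min(MAX_SAMPLED_CRUISES, n)
            return sorted(rng.choice(n, size=k, replace=False).tolist())


def embed_cruises(distance_matrix: np.ndarray, random_state: int = 0,
                  n_neighbors: int = UMAP_NEIGHBORS,
                  n_components: int = UMAP_COMPONENTS) -> np.ndarray:
    """UMAP embedding of a precomputed exemplar DTW distance matrix."""
    import umap

    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.allclose(D, 0.0):
        raise ValueError("degenerate distance matrix (all zeros)")
    n = D.shape[0]
    if n <= n_neighbors:
        warnings.warn(f"n_neighbors reduced to {n - 1}", stacklevel=2)
        n_neighbors = n - 1
    reducer = umap.UMAP(n_components=n_components, n_neighbors=n_neighbors,
                        metric="precomputed", random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(D)


class CruiseEmbedder:
    """End-to-end cruise embedding as a transform-shaped estimator.

    ``fit_transform(cruise_angle_sets)`` fits the shared PCA, computes the
    pairwise DTW matrix over the resulting traces and embeds it with UMAP;
    fitted attributes: ``pca_``, ``traces_``, ``distances_``, ``embedding_``.
    """

    def __init__(self, n_pca_components: int = N_PCA_COMPONENTS,
                 n_neighbors: int = UMAP_NEIGHBORS,
                 n_components: int = UMAP_COMPONENTS, random_state: int = 0):
        self.n_pca_components = n_pca_components
        self.n_neighbors = n_neighbors
        self.n_components = n_components
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_pca_components": self.n_pca_components,
                "n_neighbors": self.n_neighbors,
                "n_components": self.n_components,
                "random_state": self.random_state}

    def set_params(self, **params) -> "CruiseEmbedder":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_transform(self, cruise_angle_sets: list[np.ndarray]) -> np.ndarray:
        self.traces_, self.pca_ = decompose_cruises(
            cruise_angle_sets, self.n_pca_components)
        self.distances_ = dtw_matrix(self.traces_)
        self.embedding_ = embed_cruises(
            self.distances_, random_state=self.random_state,
            n_neighbors=self.n_neighbors, n_components=self.n_components)
        return self.embedding_


def density_by_week(coords: np.ndarray, weeks: np.ndarray) -> dict:
    """Per-week, per-component Gaussian KDEs and weekly component means.

    Weeks with a single exemplar report a mean only (no KDE); empty weeks
    are omitted with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    weeks = np.asarray(weeks, dtype=object)
    out: dict = {}
    for wk in dict.fromkeys(weeks):          # preserves first-seen order
        sel = coords[weeks == wk]
        if len(sel) == 0:
            warnings.warn(f"week {wk!r} has no exemplars; omitted", stacklevel=2)
            continue
        entry = {"mean": sel.mean(axis=0), "n": len(sel), "kde": None}
        if len(sel) >= 2:
            kdes = []
            for c in range(coords.shape[1]):
                try:
                    kdes.append(gaussian_kde(sel[:, c]))
                except np.linalg.LinAlgError:
                    kdes.append(None)
            entry["kde"] = kdes
        out[str(wk)] = entry
    return out
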