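"""Tensor component analysis of longitudinal recovery data.

The cohort's standardized metrics form a 3-way tensor (fish x assay x
measurement).  Canonical polyadic (CP) decomposition by alternating least
squares factors it into rank-R per-mode loadings; model selection balances
low reconstruction error against high replicate similarity, and fish are
clustered on their factor rows by Ward agglomerative clustering with a
distance threshold chosen by scanning a grid and maximizing the number of
clusters subject to a minimum-cluster-size floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import week_index


@dataclass
class RecoveryTensor:
    """fish x assay x measurement array of z-scored metrics."""

    values: np.ndarray
    fish_ids: list[str]
    weeks: list[str]
    measurements: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # fish -> reason


def assemble_tensor(metrics: pd.DataFrame, measurements: list[str],
                    fish_reasons: dict[str, str] | None = None) -> RecoveryTensor:
    """Build the recovery tensor from a long-format per-assay metrics table.

    ``metrics`` needs columns fish_id, week and one column per measurement.
    Each measurement is z-scored over all (fish, assay) cells; fish with any
    missing cell are excluded and listed with a reason (taken from
    ``fish_reasons`` when provided, else 'missing data').  Zero-variance
    measurements are dropped with a warning.
    """
    weeks = sorted({str(w) for w in metrics["week"]}, key=week_index)
    fish = sorted(metrics["fish_id"].unique())
    if len(fish) < 2:
        raise ValueError("need at least 2 fish")
    wide = metrics.set_index(["fish_id", "week"])

    keep_meas = []
    for m in measurements:
        col = pd.to_numeric(metrics[m], errors="coerce")
        if np.nanstd(col.to_numpy(dtype=float)) == 0:
            warnings.warn(f"measurement {m!r} has zero variance; dropped",
                          stacklevel=2)
        else:
            keep_meas.append(m)

    cube = np.full((len(fish), len(weeks), len(keep_meas)), np.nan)
    for fi, f in enumerate(fish):
        for wi, w in enumerate(weeks):
            try:
                row = wide.loc[(f, w)]
            except KeyError:
                continue
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            cube[fi, wi] = [row[m] for m in keep_meas]

    complete = ~np.isnan(cube).any(axis=(1, 2))
    excluded = {}
    for fi, f in enumerate(fish):
        if not complete[fi]:
            excluded[f] = (fish_reasons or {}).get(f, "missing data")
    cube = cube[complete]
    kept_fish = [f for fi, f in enumerate(fish) if complete[fi]]
    if len(kept_fish) < 2:
        raise ValueError("fewer than 2 fish with complete data")
    # z-score each measurement over all (fish, assay) cells
    flat = cube.reshape(-1, len(keep_meas))
    mu, sd = flat.mean(axis=0), flat.std(axis=0)
    sd[sd == 0] = 1.0
    cube = (cube - mu) / sd
    return RecoveryTensor(values=cube, fish_ids=kept_fish, weeks=weeks,
                          measurements=keep_meas, excluded=excluded)


# ---------------------------------------------------------------------------
# CP decomposition by alternating least squares

def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    r = A.shape[1]
    return (A[:, None, :] * B[None, :, :]).reshape(-1, r)


def cp_reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    A, B, C = factors
    return np.einsum("ir,jr,kr->ijk", A, B, C)


@dataclass
class CPDecomposition:
    """Rank-R CP decomposition fitted by ALS with random initialization.

    Fitted attributes: ``factors_`` (list of three mode matrices with
    unit-norm-balanced columns times weights folded in), ``error_`` (the
    normalized reconstruction residual ||T - That||_F / ||T||_F) and
    ``n_iter_``.
    """

    rank: int
    max_iter: int = 500
    tol: float = 1e-12
    random_state: int = 0

    def get_params(self, deep: bool = True) -> dict:
        return {"rank": self.rank, "max_iter": self.max_iter,
                "tol": self.tol, "random_state": self.random_state}

    def set_params(self, **params) -> "CPDecomposition":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, T: np.ndarray) -> "CPDecomposition":
        T = np.asarray(T, dtype=float)
        if T.ndim != 3:
            raise ValueError("tensor must be 3-way")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        rng = np.random.default_rng(self.random_state)
        factors = [rng.standard_normal((s, self.rank)) for s in T.shape]
        norm_T = np.linalg.norm(T)
        unfolds = [_unfold(T, m) for m in range(3)]
        grams = [f.T @ f for f in factors]
        prev_err = np.inf
        err = np.inf
        for it in range(self.max_iter):
            for m in range(3):
                others = [k for k in range(3) if k != m][::-1]
                kr = _khatri_rao(factors[others[1]], factors[others[0]])
                V = grams[others[0]] * grams[others[1]]
                factors[m] = np.linalg.solve(
                    V + 1e-12 * np.eye(self.rank), (unfolds[m] @ kr).T).T
                grams[m] = factors[m].T @ factors[m]
            err = np.linalg.norm(T - cp_reconstruct(factors)) / norm_T
            if abs(prev_err - err) < self.tol:
                break
            prev_err = err
        # balance column norms across modes
        norms = [np.linalg.norm(f, axis=0) for f in factors]
        weights = norms[0] * norms[1] * norms[2]
        w3 = np.cbrt(np.maximum(weights, 1e-300))
        factors = [f / np.maximum(n, 1e-300) * w3
                   for f, n in zip(factors, norms)]
        order = np.argsort(-weights)
        self.factors_ = [f[:, order] for f in factors]
        self.error_ = float(err)
        self.n_iter_ = it + 1
        return self


@dataclass
class TCAModel:
    rank: int
    factors: list[np.ndarray]
    error: float
    replicate: int
    similarity: float = float("nan")    # mean similarity to sibling replicates

    @property
    def fish_factors(self) -> np.ndarray:
        return self.factors[0]


def factor_congruence(m1: TCAModel, m2: TCAModel) -> float:
    """Greedy component matching by congruence coefficient averaged over
    modes; returns the mean matched congruence in [0, 1]."""
    r = m1.rank
    sims = np.zeros((r, r))
    for f1, f2 in zip(m1.factors, m2.factors):
        n1 = f1 / np.maximum(np.linalg.norm(f1, axis=0), 1e-300)
        n2 = f2 / np.maximum(np.linalg.norm(f2, axis=0), 1e-300)
        sims += np.abs(n1.T @ n2)
    sims /= len(m1.factors)
    matched = []
    rows, cols = set(range(r)), set(range(r))
    flat = sorted(((sims[i, j], i, j) for i in range(r) for j in range(r)),
                  reverse=True)
    for s, i, j in flat:
        if i in rows and j in cols:
            matched.append(s)
            rows.discard(i)
            cols.discard(j)
    return float(np.mean(matched))


def fit_cp_models(tensor: RecoveryTensor | np.ndarray, ranks: list[int],
                  n_replicates: int = 4, seed: int = 0,
                  max_iter: int = 500) -> list[TCAModel]:
    """Fit CP-ALS at every rank with several random restarts and score
    replicate similarity within each rank."""
    T = tensor.values if isinstance(tensor, RecoveryTensor) else np.asarray(tensor)
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates to measure similarity")
    max_rank = min(T.shape[0] * T.shape[1], T.shape[0] * T.shape[2],
                   T.shape[1] * T.shape[2])
    models: list[TCAModel] = []
    for rank in ranks:
        if rank < 1 or rank > max_rank:
            raise ValueError(f"rank {rank} infeasible for tensor shape {T.shape}")
        reps = []
        for rep in range(n_replicates):
            cp = CPDecomposition(rank=rank, max_iter=max_iter,
                                 random_state=seed * 1000 + rank * 10 + rep)
            cp.fit(T)
            reps.append(TCAModel(rank=rank, factors=cp.factors_,
                                 error=cp.error_, replicate=rep))
        for mi, m in enumerate(reps):
            sims = [factor_congruence(m, o) for oi, o in enumerate(reps)
                    if oi != mi]
            m.similarity = float(np.mean(sims))
        models.extend(reps)
    return models


def selection_curves(models: list[TCAModel]) -> pd.DataFrame:
    rows = []
    for rank in sorted({m.rank for m in models}):
        reps = [m for m in models if m.rank == rank]
        rows.append({"rank": rank,
                     "mean_error": float(np.mean([m.error for m in reps])),
                     "min_error": float(np.min([m.error for m in reps])),
                     "mean_similarity": float(np.mean([m.similarity for m in reps]))})
    return pd.DataFrame(rows)


def select_model(models: list[TCAModel],
                 similarity_floor: float = 0.8) -> tuple[TCAModel, pd.DataFrame]:
    """Largest rank whose mean replicate similarity clears the floor; among
    its replicates, the lowest-error model.  Falls back to rank 1 with a
    warning when no rank passes."""
    curves = selection_curves(models)
    passing = curves[curves["mean_similarity"] >= similarity_floor]
    if len(passing):
        rank = int(passing["rank"].max())
    else:
        warnings.warn("no rank meets the similarity floor; returning rank 1"
                      if 1 in set(curves["rank"]) else
                      "no rank meets the similarity floor; returning min rank",
                      stacklevel=2)
        rank = int(curves["rank"].min())
    reps = [m for m in models if m.rank == rank]
    best = min(reps, key=lambda m: m.error)
    return best, curves


def cluster_fish_factors(model: TCAModel,
                         threshold_grid: np.ndarray | None = None,
                         min_cluster_size: int = 5
                         ) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Ward agglomerative clustering of fish-factor rows.

    Scans a grid of distance thresholds (default 1,000 values evenly spaced
    over [0.001, 5]), records (n_clusters, min cluster size) for each, and
    selects the threshold that maximizes the number of clusters subject to
    the minimum-size floor (largest such threshold on ties).  Returns
    (labels, chosen threshold, scan report).
    """
    X = model.fish_factors
    n = X.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int), 0.0, pd.DataFrame(
            [{"threshold": 0.0, "n_clusters": 1, "min_size": 1}])
    if threshold_grid is None:
        threshold_grid = np.linspace(0.001, 5.0, 1000)
    Z = linkage(X, method="ward")
    rows = []
    for t in threshold_grid:
        lab = fcluster(Z, t=t, criterion="distance")
        _, counts = np.unique(lab, return_counts=True)
        rows.append({"threshold": float(t), "n_clusters": len(counts),
                     "min_size": int(counts.min())})
    report = pd.DataFrame(rows)
    ok = report[report["min_size"] >= min(min_cluster_size, n)]
    if len(ok) == 0:
        ok = report
    best_n = ok["n_clusters"].max()
    chosen = float(ok[ok["n_clusters"] == best_n]["threshold"].max())
    labels = fcluster(Z, t=chosen, criterion="distance") - 1
    return labels, chosen, report


def summarize_clusters(labels: np.ndarray, fish_ids: list[str],
                       outcomes: pd.DataFrame,
                       metrics_8wpi: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cluster table: members and mean 8 wpi outcomes, sorted by mean glial
    bridging (low to high)."""
    df = pd.DataFrame({"fish_id": fish_ids, "cluster": labels})
    df = df.merge(outcomes, on="fish_id", how="left")
    if metrics_8wpi is not None:
        df = df.merge(metrics_8wpi, on="fish_id", how="left",
                      suffixes=("", "_8wpi"))
    num = df.select_dtypes(include=[np.number]).columns.difference(["cluster"])
    summary = df.groupby("cluster")[list(num)].mean()
    summary["n_fish"] = df.groupby("cluster").size()
    summary = summary.sort_values("glial_bridging").reset_index()
    return summary
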