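"""Outcome statistics: 8 wpi correlation structure and early-function
outcome prediction.

Cross-sectional analysis computes pairwise Spearman correlations between 8
wpi functional and cellular metrics (after sign-aligning metrics that rise
with acute injury), clusters the 1 - r_s distance matrix with average
linkage, and fits monotone curves to significantly correlated pairs.  The
predictor combines each fish's mean 1-2 wpi swim distance (ranked high to
low) and mean 1-2 wpi rostral compensation (ranked low to high) into a
wellness score; a per-sex median split defines highly / poorly regenerative
prediction groups whose 8 wpi cellular outcomes are compared by Welch's
t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr, ttest_ind
from sklearn.isotonic import IsotonicRegression

EXACT_PERMUTATION_N = 10    # below this, Spearman p is by exact enumeration


def sign_align_metrics(table: pd.DataFrame, control_means: pd.Series,
                       wpi1_means: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Negate metrics whose cohort mean strictly increased at 1 wpi.

    Aligned columns are renamed with a "(-) " prefix; returns the aligned
    table and the list of flipped metric names.
    """
    out = table.copy()
    flipped = []
    for col in table.columns:
        if col in control_means and col in wpi1_means:
            if wpi1_means[col] > control_means[col]:
                out[col] = -out[col]
                out = out.rename(columns={col: f"(-) {col}"})
                flipped.append(col)
    return out, flipped


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's r_s (small n)."""
    n = len(x)
    rx = rankdata(x)
    ry = rankdata(y)
    zx = (rx - rx.mean())
    zy = (ry - ry.mean())
    denom = np.sqrt((zx ** 2).sum() * (zy ** 2).sum())
    if denom == 0:
        return float("nan")
    perms = np.array(list(itertools.permutations(range(n))))
    stats = (zx[perms] @ zy) / denom
    return float((np.abs(stats) >= abs(r_obs) - 1e-12).mean())


def spearman_matrix(table: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations with p-values.

    Only rows complete in every column are used.  Constant columns are
    dropped with a warning.  p-values use the t-approximation with tie
    correction, or exact permutation when fewer than 10 rows remain.
    """
    data = table.dropna(axis=0, how="any")
    if len(data) < 5:
        raise ValueError("need >= 5 complete fish for correlation analysis")
    keep = []
    for col in data.columns:
        if np.std(data[col].to_numpy(dtype=float)) == 0:
            warnings.warn(f"metric {col!r} is constant; dropped", stacklevel=2)
        else:
            keep.append(col)
    data = data[keep]
    cols = list(data.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    exact = len(data) < EXACT_PERMUTATION_N
    for i in range(k):
        for j in range(i + 1, k):
            x = data[cols[i]].to_numpy(dtype=float)
            y = data[cols[j]].to_numpy(dtype=float)
            rs, pv = spearmanr(x, y)
            if exact:
                pv = _exact_spearman_p(x, y, rs)
            r[i, j] = r[j, i] = rs
            p[i, j] = p[j, i] = pv
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def cluster_metrics(corr: pd.DataFrame, n_clusters: int | None = None,
                    cut_height: float | None = None) -> dict:
    """Average-linkage hierarchical clustering on the 1 - r_s distance.

    Returns the linkage matrix, the dendrogram leaf order, and flat cluster
    labels at the requested cut (2 clusters by default).
    """
    if corr.shape[0] < 3:
        raise ValueError("need >= 3 metrics to cluster")
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        order = dendrogram(Z, no_plot=True)["leaves"]
    if cut_height is not None:
        flat = fcluster(Z, t=cut_height, criterion="distance") - 1
    else:
        flat = fcluster(Z, t=n_clusters or 2, criterion="maxclust") - 1
    return {"linkage": Z, "order": [corr.columns[i] for i in order],
            "labels": pd.Series(flat, index=corr.columns)}


@dataclass
class MonotonicFit:
    x: np.ndarray
    y_fit: np.ndarray
    increasing: bool
    residuals: np.ndarray

    def __call__(self, x_new: np.ndarray) -> np.ndarray:
        return np.interp(x_new, self.x, self.y_fit)


def fit_monotonic_spline(x: np.ndarray, y: np.ndarray, p_value: float,
                         alpha: float = 0.05,
                         smooth_window: int = 5) -> MonotonicFit:
    """Monotone curve (isotonic fit with light smoothing) for a
    significantly correlated metric pair; declines when p >= alpha.

    The direction is the sign of the Spearman correlation.
    """
    if not p_value < alpha:
        raise ValueError(
            f"correlation not significant (p={p_value:.3g} >= {alpha}); "
            "monotonic fit declined")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    rs = spearmanr(xs, ys).statistic if np.std(ys) > 0 else 0.0
    increasing = bool(rs >= 0)
    iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
    fit = iso.fit_transform(xs, ys)
    if smooth_window > 1 and len(fit) >= smooth_window:
        if smooth_window % 2 == 0:
            smooth_window += 1
        kernel = np.ones(smooth_window) / smooth_window
        padded = np.pad(fit, smooth_window // 2, mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")
        # re-project to monotone after smoothing
        fit = np.maximum.accumulate(sm) if increasing else np.minimum.accumulate(sm)
    return MonotonicFit(x=xs, y_fit=fit, increasing=increasing,
                        residuals=ys - fit)


# ---------------------------------------------------------------------------
# wellness score and outcome prediction

def wellness_scores(metrics: pd.DataFrame,
                    weeks: tuple[str, str] = ("1", "2")) -> pd.DataFrame:
    """Per-fish wellness scores from early swim function.

    ``metrics`` is long-format with columns fish_id, sex, week, distance,
    rostral_compensation.  Per fish, distance and compensation are averaged
    over the two early weeks; within each sex, distance is ranked descending
    (rank 1 = longest) and compensation ascending (rank 1 = least); the
    combined rank is their sum.  The highly regenerative prediction group is
    combined rank < the sex median; fish at or above the median go to the
    low group (ties conservatively assigned low).  Fish missing either week
    are excluded with a reason.
    """
    metrics = metrics.copy()
    metrics["week"] = metrics["week"].astype(str)
    sel = metrics[metrics["week"].isin([str(w) for w in weeks])]
    rows, excluded = [], {}
    for fid, grp in sel.groupby("fish_id"):
        if set(grp["week"]) != {str(w) for w in weeks} \
                or grp[["distance", "rostral_compensation"]].isna().any().any():
            excluded[fid] = "missing early-week measurement"
            continue
        rows.append({"fish_id": fid, "sex": grp["sex"].iloc[0],
                     "mean_distance": grp["distance"].mean(),
                     "mean_compensation": grp["rostral_compensation"].mean()})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no fish with complete early-week measurements")
    out = []
    for sex, grp in df.groupby("sex"):
        g = grp.copy()
        g["distance_rank"] = rankdata(-g["mean_distance"], method="average")
        g["compensation_rank"] = rankdata(g["mean_compensation"], method="average")
        g["combined_rank"] = g["distance_rank"] + g["compensation_rank"]
        med = g["combined_rank"].median()
        if (g["combined_rank"] == med).all():
            warnings.warn(f"all {sex} fish tied at the median; all assigned "
                          "to the low group", stacklevel=2)
        g["group"] = np.where(g["combined_rank"] < med, "high", "low")
        out.append(g)
    result = pd.concat(out, ignore_index=True)
    result.attrs["excluded"] = excluded
    return result


def evaluate_prediction(groups: pd.DataFrame, outcomes: pd.DataFrame,
                        outcome_cols: tuple[str, ...] = (
                            "glial_bridging", "axon_proximal", "axon_distal")
                        ) -> pd.DataFrame:
    """Compare 8 wpi cellular outcomes between prediction groups.

    Per outcome: group means and Welch's two-sample t-test (two-sided).
    Groups smaller than 2 report descriptives only (NaN statistics).
    """
    merged = groups[["fish_id", "group"]].merge(outcomes, on="fish_id")
    hi = merged[merged["group"] == "high"]
    lo = merged[merged["group"] == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both prediction groups must be non-empty")
    rows = []
    for col in outcome_cols:
        a = hi[col].dropna().to_numpy(dtype=float)
        b = lo[col].dropna().to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2:
            t, p = ttest_ind(a, b, equal_var=False)
        else:
            t, p = float("nan"), float("nan")
        rows.append({"outcome": col, "mean_high": a.mean() if len(a) else np.nan,
                     "mean_low": b.mean() if len(b) else np.nan,
                     "n_high": len(a), "n_low": len(b),
                     "t_statistic": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)
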