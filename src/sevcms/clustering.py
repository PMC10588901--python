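"""Severity clustering: optimal 1-D k-means thresholds with resampled CIs.

Severity levels are a total order, so clustering operates on the 1-D
composite score. In one dimension the optimal k-means partition is
contiguous on the sorted scores, which lets a dynamic program find the
global optimum exactly (no Lloyd restarts, no local minima). Cluster
boundaries are the midpoints between adjacent sorted centers — in 1-D these
reproduce nearest-center assignment exactly. Threshold stability is
quantified by refitting on resampled training scores (bootstrap by default)
and reporting the per-boundary mean and percentile confidence borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DatasetError


# ---------------------------------------------------------------------------
# Exact 1-D k-means
# ---------------------------------------------------------------------------

def kmeans_1d(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal 1-D k-means by dynamic programming.

    Returns (sorted cluster centers, cluster index per input value in input
    order, total within-cluster sum of squares). Requires at least ``k``
    distinct values.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if k < 1:
        raise DatasetError(f"k must be >= 1, got {k}")
    if len(np.unique(x)) < k:
        raise DatasetError(
            f"need at least {k} distinct values for k={k}, got {len(np.unique(x))}"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    # prefix sums for O(1) segment cost: SS(i..j) = sum x^2 - (sum x)^2 / m
    ps = np.concatenate([[0.0], np.cumsum(xs)])
    ps2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_cost(i: int, j: int) -> float:  # inclusive 0-based [i, j]
        m = j - i + 1
        s = ps[j + 1] - ps[i]
        return (ps2[j + 1] - ps2[i]) - s * s / m

    INF = np.inf
    D = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, best_i = INF, m - 1
            for i in range(m - 1, j):
                c = D[m - 1, i] + seg_cost(i, j - 1)
                if c < best:
                    best, best_i = c, i
            D[m, j] = best
            back[m, j] = best_i
    # recover segment boundaries
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m, j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = n
    centers = np.array([xs[bounds[m]:bounds[m + 1]].mean() for m in range(k)])
    labels_sorted = np.empty(n, dtype=int)
    for m in range(k):
        labels_sorted[bounds[m]:bounds[m + 1]] = m
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return centers, labels, float(D[k, n])


def suggest_k(explained_variance: np.ndarray) -> int:
    """Elbow suggestion from an explained-variance sequence (scree curve).

    Returns the 1-based index i maximizing x[i] - 2 x[i+1] + x[i+2], the
    point after which the curve flattens most sharply. A configured k always
    overrides this suggestion.
    """
    x = np.asarray(explained_variance, dtype=float)
    if len(x) < 3:
        raise DatasetError("elbow suggestion needs at least 3 explained-variance values")
    second = x[:-2] - 2 * x[1:-1] + x[2:]
    return int(np.argmax(second)) + 1


# ---------------------------------------------------------------------------
# Resampled thresholds
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Ordered severity clusters on the composite-score axis.

    Cluster ``k`` is the highest severity. ``thresholds`` are the mean
    resampled boundaries; ``threshold_ci`` the percentile confidence borders
    at ``ci_level``. Severity levels are relative to the models analyzed and
    carry no regulatory severity-category meaning.
    """

    k: int
    center_means: np.ndarray  # k ascending centers (mean over resamples)
    thresholds: np.ndarray  # k-1 strictly increasing boundaries
    threshold_ci: np.ndarray  # (k-1, 2) lower/upper at ci_level
    ci_level: float
    n_resamples: int
    seed: int
    resample_thresholds: np.ndarray = field(repr=False, default=None)  # (R, k-1)
    point_centers: np.ndarray = None  # DP fit on the unresampled scores
    point_thresholds: np.ndarray = None
    disclaimer: str = (
        "severity levels are relative to the models analyzed and are not "
        "transferable to Directive 2010/63/EU severity categories"
    )

    def ci_at(self, level: float) -> np.ndarray:
        """Percentile CI of each boundary at an arbitrary level."""
        if not (0 < level < 1):
            raise DatasetError("ci level must lie in (0, 1)")
        lo = 100 * (1 - level) / 2
        return np.column_stack([
            np.percentile(self.resample_thresholds, lo, axis=0),
            np.percentile(self.resample_thresholds, 100 - lo, axis=0),
        ])


def fit_cluster_thresholds(
    training_scores: np.ndarray,
    k: int,
    n_resamples: int = 100,
    ci_level: float = 0.95,
    seed: int = 0,
    resample_mode: str = "bootstrap",
    subsample_fraction: float = 0.8,
) -> ClusterModel:
    """Robust severity thresholds by resampled exact 1-D k-means.

    Each resample redraws the training scores (with replacement for
    ``bootstrap``, a fraction without replacement for ``subsample``), fits
    the DP k-means, sorts the centers and records the k-1 midpoints between
    adjacent centers. The model carries the mean boundaries plus percentile
    confidence borders. Resamples with fewer than k distinct values are
    redrawn.
    """
    x = np.asarray(training_scores, dtype=float)
    x = x[~np.isnan(x)]
    if len(np.unique(x)) < k:
        raise DatasetError(f"fewer than k={k} distinct training scores")
    if resample_mode not in ("bootstrap", "subsample"):
        raise DatasetError(f"unknown resample_mode {resample_mode!r}")
    rng = np.random.default_rng(seed)
    point_centers, _, _ = kmeans_1d(x, k)
    point_thresholds = 0.5 * (point_centers[:-1] + point_centers[1:])

    all_centers = np.empty((n_resamples, k))
    all_thresholds = np.empty((n_resamples, max(k - 1, 0)))
    for r in range(n_resamples):
        for _attempt in range(1000):
            if resample_mode == "bootstrap":
                sample = rng.choice(x, size=len(x), replace=True)
            else:
                size = max(k, int(round(subsample_fraction * len(x))))
                sample = rng.choice(x, size=size, replace=False)
            if len(np.unique(sample)) >= k:
                break
        else:  # pragma: no cover
            raise DatasetError("could not draw a resample with k distinct values")
        centers, _, _ = kmeans_1d(sample, k)
        all_centers[r] = centers
        if k > 1:
            all_thresholds[r] = 0.5 * (centers[:-1] + centers[1:])

    thresholds = all_thresholds.mean(axis=0) if k > 1 else np.empty(0)
    if k > 1 and np.any(np.diff(thresholds) <= 0):
        raise DatasetError("mean thresholds are not strictly increasing; "
                           "clusters are unstable at this k")
    lo = 100 * (1 - ci_level) / 2
    if k > 1:
        ci = np.column_stack([
            np.percentile(all_thresholds, lo, axis=0),
            np.percentile(all_thresholds, 100 - lo, axis=0),
        ])
    else:
        ci = np.empty((0, 2))
    return ClusterModel(
        k=k, center_means=all_centers.mean(axis=0), thresholds=thresholds,
        threshold_ci=ci, ci_level=ci_level, n_resamples=n_resamples, seed=seed,
        resample_thresholds=all_thresholds, point_centers=point_centers,
        point_thresholds=point_thresholds,
    )


# ---------------------------------------------------------------------------
# Assignment and allocation tables
# ---------------------------------------------------------------------------

@dataclass
class AllocationResult:
    """Per-animal cluster assignments and per-group percentage tables."""

    assignments: pd.Series  # animal_id -> cluster (1..k); NaN = unassigned
    unassigned: list[dict]
    group_table: pd.DataFrame  # rows (model, group), columns cluster 1..k, %
    top_cluster_sums: pd.DataFrame | None = None


def assign_severity(scores: pd.Series, model: ClusterModel) -> tuple[pd.Series, list[dict]]:
    """Assign each composite score to an ordered severity cluster.

    An animal with score s goes to cluster 1 + #(thresholds <= s); a score
    exactly on a boundary therefore goes to the higher cluster. Missing
    scores are reported as unassigned rather than silently dropped.
    """
    vals = scores.to_numpy(dtype=float)
    clusters = np.full(len(vals), np.nan)
    ok = ~np.isnan(vals)
    clusters[ok] = np.searchsorted(model.thresholds, vals[ok], side="right") + 1
    unassigned = [
        {"animal_id": a, "reason": "missing composite score"}
        for a, good in zip(scores.index, ok) if not good
    ]
    return pd.Series(clusters, index=scores.index, name="cluster"), unassigned


def allocation_table(
    assignments: pd.Series,
    meta: pd.DataFrame,
    k: int,
    top_clusters: int = 2,
) -> AllocationResult:
    """Percentage distribution of each (model, group) over the k clusters.

    Each row sums to 100. ``top_clusters`` controls the reported sum of the
    highest clusters (e.g. clusters k and k-1 combined), the headline
    comparison between burdened and control groups. Empty groups are
    omitted.
    """
    meta = meta.set_index("animal_id")
    rows = []
    top_rows = []
    cluster_cols = [f"cluster_{c}" for c in range(1, k + 1)]
    for (model_name, group), sub in meta.groupby(["model", "group"], sort=True):
        assigned = assignments.reindex(sub.index).dropna()
        if assigned.empty:
            continue
        pct = {f"cluster_{c}": 100.0 * float((assigned == c).sum()) / len(assigned)
               for c in range(1, k + 1)}
        rows.append({"model": model_name, "group": group, "n": len(assigned), **pct})
        top = sum(pct[f"cluster_{c}"] for c in range(max(1, k - top_clusters + 1), k + 1))
        top_rows.append({"model": model_name, "group": group,
                         "top_clusters_pct": top})
    group_table = pd.DataFrame(rows, columns=["model", "group", "n"] + cluster_cols)
    top_table = pd.DataFrame(top_rows)
    return AllocationResult(
        assignments=assignments,
        unassigned=[],
        group_table=group_table,
        top_cluster_sums=top_table,
    )


def allocation_table_pooled(
    scores: pd.Series,
    model: ClusterModel,
    meta: pd.DataFrame,
    top_clusters: int = 2,
) -> AllocationResult:
    """Allocation percentages pooled over animal x resample units.

    Each animal is assigned once per resampled threshold set; percentages
    therefore reflect threshold uncertainty, mirroring allocation tables
    whose granularity is finer than the animal count.
    """
    vals = scores.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    pooled = []
    for thr in model.resample_thresholds:
        c = np.full(len(vals), np.nan)
        c[ok] = np.searchsorted(thr, vals[ok], side="right") + 1
        pooled.append(pd.Series(c, index=scores.index))
    stacked = pd.concat(pooled, ignore_index=False)
    meta_rep = pd.concat([meta] * len(pooled), ignore_index=True)
    meta_rep["animal_id"] = [
        f"{aid}~r{r}" for r in range(len(pooled)) for aid in meta["animal_id"]
    ]
    stacked.index = meta_rep["animal_id"]
    return allocation_table(stacked, meta_rep, model.k, top_clusters)
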