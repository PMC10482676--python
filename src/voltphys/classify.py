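"""Hierarchical clustering of response types and the consensus classifier.

Feature vectors mix counts, rates and ratios, so columns are z-scored
(after per-parameter median imputation of undefined ratios) before Ward /
Euclidean agglomeration.  The classifier ranks a query against the cluster
centroids twice — by Euclidean distance and by Pearson correlation across
the 29 parameters — takes the top three of each ranking, and assigns the
best-rank-sum member of their intersection; disjoint top-3 sets leave the
query unassigned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass
class StandardizeParams:
    """Per-feature location/scale and imputation values."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    median: np.ndarray       # imputation value per column (pre-scaling)
    dropped: list[str] = field(default_factory=list)

    def apply(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy(float)
        else:
            X = np.asarray(X, float)
        X = X.copy()
        for j in range(X.shape[1]):
            bad = ~np.isfinite(X[:, j])
            X[bad, j] = self.median[j]
        return (X - self.mean) / self.sd


def standardize(X: pd.DataFrame | np.ndarray,
                impute: bool = True) -> tuple[np.ndarray, StandardizeParams]:
    """Z-score a feature matrix column-wise.

    NaNs are median-imputed per column first (the stored tables keep their
    NaNs; imputation happens only here).  Zero-variance columns are dropped
    with a warning.  Returns the scaled matrix and reusable parameters.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        A = X.to_numpy(float)
    else:
        A = np.asarray(X, float)
        columns = [f"f{j}" for j in range(A.shape[1])]
    if A.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    A = A.copy()
    med = np.zeros(A.shape[1])
    for j in range(A.shape[1]):
        col = A[:, j]
        finite = col[np.isfinite(col)]
        med[j] = np.median(finite) if finite.size else 0.0
        if impute:
            col[~np.isfinite(col)] = med[j]
    mean = A.mean(axis=0)
    sd = A.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn("dropping zero-variance columns: " + ", ".join(dropped))
    params = StandardizeParams(
        columns=[c for c, k in zip(columns, keep) if k],
        mean=mean[keep], sd=sd[keep], median=med[keep], dropped=dropped)
    return (A[:, keep] - mean[keep]) / sd[keep], params


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def auto_cutoff(linkage: np.ndarray) -> float:
    """Cutoff distance at the sharpest slope change of clusters vs cutoff.

    The cluster-count-versus-cutoff curve is a staircase that steps down
    at every merge height; its most pronounced slope change — the corner
    where rapid merging gives way to the longest stable plateau — sits at
    the largest gap between consecutive merge heights.  The cutoff is the
    midpoint of that gap.
    """
    heights = np.sort(linkage[:, 2])
    if len(heights) < 2 or heights[-1] <= heights[0]:
        return float(heights[-1])
    gaps = np.diff(heights)
    j = int(np.argmax(gaps))
    return float((heights[j] + heights[j + 1]) / 2)


def ward_cluster(Z: np.ndarray, cutoff: float | str = "auto"
                 ) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Ward / Euclidean agglomerative clustering with a distance cutoff.

    Returns ``(linkage matrix, labels, k, cutoff used)``; labels are
    1-based as produced by a tree cut at the cutoff distance.
    """
    Z = np.asarray(Z, float)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    link = hierarchy.linkage(Z, method="ward")
    if cutoff == "auto":
        cut = auto_cutoff(link)
    else:
        cut = float(cutoff)
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    return link, labels, int(labels.max()), cut


# ---------------------------------------------------------------------------
# Centroid model
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Per-cluster centroids in standardized feature space."""

    centroids: pd.DataFrame          # index: cluster id; columns: features
    params: StandardizeParams
    cutoff: float | None = None
    linkage_method: str = "ward"
    metric: str = "euclidean"

    @property
    def k(self) -> int:
        return len(self.centroids)

    def to_json(self, path) -> None:
        d = {
            "cutoff": self.cutoff,
            "linkage_method": self.linkage_method,
            "metric": self.metric,
            "clusters": self.centroids.index.tolist(),
            "features": list(self.centroids.columns),
            "centroids": self.centroids.to_numpy().tolist(),
            "standardize": {
                "columns": self.params.columns,
                "mean": self.params.mean.tolist(),
                "sd": self.params.sd.tolist(),
                "median": self.params.median.tolist(),
                "dropped": self.params.dropped,
            },
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        s = d["standardize"]
        params = StandardizeParams(
            columns=s["columns"], mean=np.asarray(s["mean"]),
            sd=np.asarray(s["sd"]), median=np.asarray(s["median"]),
            dropped=s.get("dropped", []))
        centroids = pd.DataFrame(d["centroids"], index=d["clusters"],
                                 columns=d["features"])
        return cls(centroids=centroids, params=params, cutoff=d.get("cutoff"),
                   linkage_method=d.get("linkage_method", "ward"),
                   metric=d.get("metric", "euclidean"))


def build_model(Z: np.ndarray, labels: np.ndarray,
                params: StandardizeParams,
                cutoff: float | None = None) -> ClusterModel:
    """Centroid model from a standardized matrix and cluster labels.

    Each centroid is the mean of its members' standardized vectors; labels
    may come from :func:`ward_cluster` or from an external table.
    """
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    if Z.shape[0] == 0:
        raise ValueError("cannot build a model from an empty cluster set")
    ids = np.unique(labels)
    rows = []
    for cid in ids:
        members = Z[labels == cid]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {cid}")
        rows.append(members.mean(axis=0))
    centroids = pd.DataFrame(rows, index=[int(i) for i in ids],
                             columns=params.columns)
    return ClusterModel(centroids=centroids, params=params, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Consensus classification
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Correlation of vector ``a`` with each row of ``B`` (NaN -> -inf)."""
    a = a - a.mean()
    B = B - B.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a) * np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (B @ a) / denom
    r[~np.isfinite(r)] = -np.inf
    return r


def classify_consensus(vector: np.ndarray, model: ClusterModel,
                       top: int = 3) -> tuple[int | None, dict]:
    """Dual-rank consensus assignment of one standardized vector.

    The query is ranked against all centroids by Euclidean distance
    (ascending) and by Pearson correlation (descending); the top three of
    each ranking are intersected and the member with the smallest rank sum
    wins (ties broken by the smaller distance rank).  An empty intersection
    returns ``(None, diagnostics)`` — unassigned.
    """
    v = np.asarray(vector, float)
    C = model.centroids.to_numpy(float)
    ids = np.asarray(model.centroids.index)
    top = min(top, len(ids))
    dist = np.linalg.norm(C - v, axis=1)
    corr = _pearson(v, C)
    order_d = np.argsort(dist, kind="stable")
    order_c = np.argsort(-corr, kind="stable")
    rank_d = np.empty(len(ids), int)
    rank_d[order_d] = np.arange(1, len(ids) + 1)
    rank_c = np.empty(len(ids), int)
    rank_c[order_c] = np.arange(1, len(ids) + 1)
    top_d = set(order_d[:top])
    top_c = set(order_c[:top])
    inter = top_d & top_c
    diag = {
        "distance": dict(zip(ids.tolist(), dist.tolist())),
        "correlation": dict(zip(ids.tolist(), corr.tolist())),
        "top_distance": [int(ids[i]) for i in order_d[:top]],
        "top_correlation": [int(ids[i]) for i in order_c[:top]],
    }
    if not inter:
        return None, diag
    best = min(inter, key=lambda i: (rank_d[i] + rank_c[i], rank_d[i], dist[i]))
    return int(ids[best]), diag


def classify_table(X: pd.DataFrame | np.ndarray, model: ClusterModel,
                   top: int = 3) -> list[int | None]:
    """Consensus-classify every row of a raw feature matrix."""
    Z = model.params.apply(X)
    return [classify_consensus(z, model, top=top)[0] for z in Z]


def cluster_load(X: pd.DataFrame | np.ndarray, model: ClusterModel,
                 top: int = 3) -> pd.Series:
    """Fraction of a population assigned to each cluster (plus unassigned).

    Fractions sum to 1 over the model's clusters and the "unassigned" bin.
    """
    X = X if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if len(X) == 0:
        raise ValueError("empty input population")
    assigned = classify_table(X, model, top=top)
    ids = model.centroids.index.tolist()
    counts = {cid: 0 for cid in ids}
    counts["unassigned"] = 0
    for a in assigned:
        counts[a if a is not None else "unassigned"] += 1
    load = pd.Series(counts, dtype=float) / len(assigned)
    return load


def self_consistency(Z: np.ndarray, labels: np.ndarray,
                     model: ClusterModel, top: int = 3) -> float:
    """Fraction of training vectors the classifier returns to their cluster."""
    hits = 0
    for z, lab in zip(np.asarray(Z, float), np.asarray(labels)):
        cid, _ = classify_consensus(z, model, top=top)
        hits += int(cid == lab)
    return hits / len(labels)
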