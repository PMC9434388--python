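"""Behavior clustering of daily activity features: standardize → PCA → elbow
k selection → k-means → activity ordering → period assignment → pre/post
movement matrix.

Daily 8-factor feature vectors are pooled across the pre and post periods so
cluster labels are comparable between periods; clusters are renumbered by
decreasing mean MVPA so cluster 1 is the most active group; and the movement
matrix cross-tabulates each participant's pre vs post cluster, with
below-diagonal moves (toward cluster 1) counted as desirable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .bouts import DailyFeatures

__all__ = [
    "Standardizer",
    "PCAProjection",
    "ClusterModel",
    "MovementMatrix",
    "standardize",
    "fit_pca",
    "choose_k_elbow",
    "fit_clusters",
    "order_clusters",
    "assign_periods",
    "movement_matrix",
    "fit_behavior_model",
]

FEATURE_COLUMNS = list(DailyFeatures.FEATURE_NAMES)


@dataclass(frozen=True)
class Standardizer:
    """Column means and sample SDs learned from training features."""

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X, self.columns)
        sd = np.where(self.sd == 0, 1.0, self.sd)
        Z = (X - self.mean) / sd
        Z[:, self.sd == 0] = 0.0
        return Z


@dataclass(frozen=True)
class PCAProjection:
    """Retained principal axes with the full explained-variance spectrum."""

    loadings: np.ndarray  # (p, m): columns are retained components
    explained_variance_ratio: np.ndarray  # full spectrum, non-increasing
    m: int

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z) @ self.loadings


@dataclass
class MovementMatrix:
    """k×k pre→post cluster cross-tabulation with the movement decomposition.

    Rows index the pre-period cluster, columns the post-period cluster
    (1-based, cluster 1 most active).  ``desirable`` counts moves below the
    diagonal (to a more active cluster), ``unfavorable`` above it.
    """

    counts: np.ndarray
    k: int
    n: int
    desirable: int
    same: int
    unfavorable: int

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(1, self.k + 1), name="pre_cluster")
        cols = pd.Index(range(1, self.k + 1), name="post_cluster")
        return pd.DataFrame(self.counts, index=idx, columns=cols)


@dataclass
class ClusterModel:
    """Fitted behavior-cluster model (activity-ordered labels, 1 = most active)."""

    k: int
    centroids: np.ndarray  # (k, m) in PC-score space, row i = cluster i+1
    labels_: np.ndarray  # training assignments, values 1..k
    seed: int
    inertia: float
    ordering: np.ndarray  # permutation applied to the raw k-means labels
    standardizer: Standardizer | None = None
    pca: PCAProjection | None = None
    ordered: bool = False

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Nearest-centroid cluster labels (1..k) for rows of PC scores."""
        d = cdist(np.asarray(scores, dtype=float), self.centroids)
        return d.argmin(axis=1) + 1

    def transform_features(self, features) -> np.ndarray:
        """Project raw 8-factor features through the stored standardizer + PCA."""
        if self.standardizer is None or self.pca is None:
            raise ValueError("model was fitted without a standardizer/PCA attached")
        return self.pca.transform(self.standardizer.transform(features))

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "labels": self.labels_.tolist(),
            "seed": self.seed,
            "inertia": self.inertia,
            "ordering": self.ordering.tolist(),
            "ordered": self.ordered,
            "standardizer": None
            if self.standardizer is None
            else {
                "mean": self.standardizer.mean.tolist(),
                "sd": self.standardizer.sd.tolist(),
                "columns": list(self.standardizer.columns),
            },
            "pca": None
            if self.pca is None
            else {
                "loadings": self.pca.loadings.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
                "m": self.pca.m,
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "ClusterModel":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        std = data["standardizer"]
        pca = data["pca"]
        return cls(
            k=data["k"],
            centroids=np.array(data["centroids"], dtype=float),
            labels_=np.array(data["labels"], dtype=int),
            seed=data["seed"],
            inertia=data["inertia"],
            ordering=np.array(data["ordering"], dtype=int),
            standardizer=None if std is None else Standardizer(
                np.array(std["mean"]), np.array(std["sd"]), tuple(std["columns"])
            ),
            pca=None if pca is None else PCAProjection(
                np.array(pca["loadings"]), np.array(pca["explained_variance_ratio"]),
                pca["m"],
            ),
            ordered=data["ordered"],
        )


def _as_matrix(X, columns=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        cols = list(columns) if columns is not None else [
            c for c in FEATURE_COLUMNS if c in X.columns
        ]
        X = X[cols]
    return np.asarray(X, dtype=float)


def standardize(X) -> tuple[np.ndarray, Standardizer]:
    """Z-score columns with the sample-SD (ddof=1) convention.

    Accepts a DataFrame (the 8 feature columns are selected by name) or a
    plain matrix.  Constant columns map to zeros with a warning; missing
    values are an error.
    """
    cols = tuple(c for c in FEATURE_COLUMNS if c in X.columns) if isinstance(X, pd.DataFrame) \
        else tuple(f"x{i}" for i in range(np.asarray(X).shape[1]))
    M = _as_matrix(X, cols if isinstance(X, pd.DataFrame) else None)
    if M.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    if np.isnan(M).any():
        raise ValueError("feature matrix contains missing values")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if (sd == 0).any():
        idx = [cols[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(f"constant feature columns standardized to zeros: {idx}")
    st = Standardizer(mean=mean, sd=sd, columns=cols)
    return st.transform(X), st


def fit_pca(Z: np.ndarray, variance_target: float = 0.90,
            fixed_m: int | None = None) -> tuple[PCAProjection, np.ndarray]:
    """Principal components of a z-matrix; retain ``fixed_m`` components or the
    smallest m whose cumulative explained variance reaches ``variance_target``.

    Returns the projection and the retained scores (Z · loadings).
    """
    if fixed_m is None and not (0 < variance_target <= 1):
        raise ValueError("variance_target must lie in (0, 1]")
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("z-matrix must be finite")
    full = PCA(n_components=min(Z.shape), svd_solver="full").fit(Z)
    evr = full.explained_variance_ratio_
    if fixed_m is not None:
        if not 1 <= fixed_m <= len(evr):
            raise ValueError(f"fixed_m must be in 1..{len(evr)}")
        m = int(fixed_m)
    else:
        m = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
        m = min(m, len(evr))
    loadings = full.components_[:m].T  # (p, m)
    proj = PCAProjection(loadings=loadings, explained_variance_ratio=evr, m=m)
    return proj, proj.transform(Z)


def _wss_curve(scores: np.ndarray, ks: Sequence[int], seed: int,
               replicates: int) -> np.ndarray:
    wss = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=replicates, random_state=seed).fit(scores)
        wss.append(km.inertia_)
    return np.asarray(wss, dtype=float)


def elbow_point(ks: Sequence[int], wss: Sequence[float]) -> int:
    """The k maximizing perpendicular distance from (k, WSS(k)) to the chord
    joining the WSS curve's endpoints; ties break toward the smaller k."""
    ks = list(ks)
    wss = np.asarray(wss, dtype=float)
    if len(ks) != len(wss) or len(ks) < 3:
        raise ValueError("need matching ks/wss with at least 3 points")
    if not np.isfinite(wss).all():
        raise ValueError("non-finite WSS encountered")
    x0, y0 = ks[0], wss[0]
    x1, y1 = ks[-1], wss[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    d = np.abs((y1 - y0) * (np.asarray(ks) - x0) - (x1 - x0) * (wss - y0)) / chord
    d[0] = d[-1] = -np.inf  # endpoints cannot be the elbow
    return ks[int(np.argmax(d))]  # argmax takes the first (smallest-k) maximum


def choose_k_elbow(scores: np.ndarray, k_range: Sequence[int] = range(2, 11),
                   seed: int = 0, replicates: int = 10,
                   return_curve: bool = False):
    """Elbow selection of k from the within-cluster sum-of-squares curve.

    WSS(k) is the best of ``replicates`` k-means fits for each k; the elbow is
    chosen by :func:`elbow_point` (maximum chord distance, ties toward the
    smaller k).
    """
    ks = list(k_range)
    scores = np.asarray(scores, dtype=float)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if max(ks) > len(scores):
        raise ValueError("k_range exceeds the number of rows")
    wss = _wss_curve(scores, ks, seed, replicates)
    k = elbow_point(ks, wss)
    return (k, dict(zip(ks, wss))) if return_curve else k


def fit_clusters(scores: np.ndarray, k: int, seed: int = 0,
                 n_init: int = 50) -> ClusterModel:
    """k-means (k-means++ init, best of ``n_init`` by WSS) on PC scores.

    Deterministic given ``seed``.  Labels are provisional (unordered 1..k)
    until :func:`order_clusters` renumbers them by activity.
    """
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(np.unique(scores, axis=0)):
        raise ValueError("k exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        labels_=km.labels_.astype(int) + 1,
        seed=seed,
        inertia=float(km.inertia_),
        ordering=np.arange(k),
    )


def order_clusters(model: ClusterModel, features) -> ClusterModel:
    """Renumber clusters 1..k by decreasing member-mean MVPA time (>=3 s bouts);
    ties break by increasing sedentary time (>=60 s bouts).  Idempotent.

    ``features`` are the training rows (aligned with ``model.labels_``) as a
    DataFrame with ``mvpa_time_3s`` and ``sb_time_60s`` columns or an
    (n, >=3) matrix in the canonical feature order.
    """
    if isinstance(features, pd.DataFrame):
        mvpa = features["mvpa_time_3s"].to_numpy(dtype=float)
        sb = features["sb_time_60s"].to_numpy(dtype=float)
    else:
        M = np.asarray(features, dtype=float)
        mvpa, sb = M[:, 0], M[:, 2]
    if len(mvpa) != len(model.labels_):
        raise ValueError("features must align with the model's training rows")
    key_mvpa = np.array([mvpa[model.labels_ == c].mean() for c in range(1, model.k + 1)])
    key_sb = np.array([sb[model.labels_ == c].mean() for c in range(1, model.k + 1)])
    order = np.lexsort((key_sb, -key_mvpa))  # primary: MVPA desc; tie: SB asc
    relabel = np.empty(model.k, dtype=int)
    relabel[order] = np.arange(1, model.k + 1)
    return replace(
        model,
        centroids=model.centroids[order],
        labels_=relabel[model.labels_ - 1],
        ordering=order,
        ordered=True,
    )


def assign_periods(model: ClusterModel, scores, groups: pd.DataFrame | None = None,
                   mode: str = "modal-day") -> pd.DataFrame:
    """Cluster label per participant-period from its days' PC scores.

    ``scores`` are per-day PC-score rows, with ``groups`` providing aligned
    ``participant``/``period`` columns (or pass a single DataFrame carrying
    both).  ``modal-day`` (default) assigns each day to its nearest centroid
    and takes the period's modal cluster, ties resolved toward the more
    active (smaller) label; ``mean-vector`` assigns the period's mean score
    vector directly.
    """
    if mode not in ("modal-day", "mean-vector"):
        raise ValueError("mode must be 'modal-day' or 'mean-vector'")
    if groups is None:
        if not isinstance(scores, pd.DataFrame):
            raise ValueError("pass groups, or a DataFrame with participant/period columns")
        groups = scores[["participant", "period"]]
        scores = scores.drop(columns=["participant", "period"])
    S = np.asarray(scores, dtype=float)
    if len(S) != len(groups):
        raise ValueError("scores and groups must align")
    df = groups.reset_index(drop=True).copy()
    rows = []
    for (pid, period), idx in df.groupby(["participant", "period"], sort=True).groups.items():
        block = S[np.asarray(idx)]
        if len(block) == 0:
            raise ValueError(f"participant {pid!r} period {period!r} has no valid days")
        if mode == "mean-vector":
            label = int(model.predict(block.mean(axis=0, keepdims=True))[0])
        else:
            day_labels = model.predict(block)
            counts = np.bincount(day_labels, minlength=model.k + 1)
            label = int(np.flatnonzero(counts == counts.max())[0])  # tie -> more active
        rows.append({"participant": pid, "period": period, "cluster": label})
    return pd.DataFrame(rows)


def movement_matrix(pre: Mapping[str, int] | pd.Series,
                    post: Mapping[str, int] | pd.Series,
                    k: int | None = None) -> MovementMatrix:
    """Cross-tabulate pre vs post cluster labels per participant.

    Cell (i, j) counts participants in pre cluster i and post cluster j.
    With cluster 1 the most active, j < i is a desirable move, the diagonal is
    no change, and j > i is unfavorable.
    """
    pre = dict(pre)
    post = dict(post)
    if set(pre) != set(post):
        raise ValueError("pre and post label sets cover different participants")
    labels = list(pre.values()) + list(post.values())
    if k is None:
        k = int(max(labels))
    if min(labels) < 1 or max(labels) > k:
        raise ValueError(f"cluster labels must lie in 1..{k}")
    counts = np.zeros((k, k), dtype=int)
    for pid in pre:
        counts[pre[pid] - 1, post[pid] - 1] += 1
    n = int(counts.sum())
    same = int(np.trace(counts))
    desirable = int(np.tril(counts, -1).sum())
    unfavorable = int(np.triu(counts, 1).sum())
    return MovementMatrix(counts=counts, k=k, n=n, desirable=desirable,
                          same=same, unfavorable=unfavorable)


def fit_behavior_model(features: pd.DataFrame, k: "int | str" = "auto",
                       pcs: "int | str" = "auto", variance_target: float = 0.90,
                       seed: int = 0, n_init: int = 50,
                       k_range: Sequence[int] = range(2, 11),
                       replicates: int = 10) -> tuple[ClusterModel, np.ndarray]:
    """End-to-end fit on pooled daily features: standardize → PCA → (elbow) →
    k-means → activity ordering.  Returns the ordered model and the PC scores.
    """
    Z, st = standardize(features)
    proj, scores = fit_pca(Z, variance_target=variance_target,
                           fixed_m=None if pcs == "auto" else int(pcs))
    if k == "auto":
        k_sel = choose_k_elbow(scores, k_range=k_range, seed=seed, replicates=replicates)
    else:
        k_sel = int(k)
    model = fit_clusters(scores, k_sel, seed=seed, n_init=n_init)
    model.standardizer = st
    model.pca = proj
    model = order_clusters(model, features)
    return model, scores
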