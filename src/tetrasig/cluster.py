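"""Distance matrices, PCA, pseudo-F model selection and hierarchical clustering.

The subgrouping procedure: cosine distances between tetranucleotide profiles
summarise pairwise compositional similarity; the number of subgroups is chosen
by maximising the pseudo-F (Calinski-Harabasz) statistic over repeated
k-means partitions; PCA gives the low-dimensional view; the similarity matrix
itself is hierarchically clustered (Pearson-correlation distance, average
linkage) for the heatmap ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "PCAScores",
    "PerfectSeparationError",
    "cosine_distance",
    "distance_matrix",
    "pseudo_f",
    "select_k",
    "pca_profiles",
    "cluster_similarity_matrix",
    "station_report",
]


class PerfectSeparationError(ValueError):
    """Raised when within-cluster scatter is exactly zero (pseudo-F infinite)."""


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # n x n, symmetric, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class ClusterResult:
    ids: tuple[str, ...]
    labels: np.ndarray
    k: int
    pseudo_f: float
    restarts: int
    seed: int
    trace: dict[int, float] = field(default_factory=dict)  # k -> best pseudo-F

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "pseudo_f": self.pseudo_f,
                "restarts": self.restarts,
                "seed": self.seed,
                "labels": {i: int(l) for i, l in zip(self.ids, self.labels)},
                "trace": {str(k): v for k, v in sorted(self.trace.items())},
            },
            indent=2,
        )


@dataclass(frozen=True)
class PCAScores:
    ids: tuple[str, ...]
    scores: np.ndarray  # n x n_components
    explained_variance: np.ndarray  # fractions, non-increasing


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(angle(u, v)); lies in [0, 1] for nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


def distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Symmetric pairwise cosine-distance matrix over profile rows."""
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("distance matrix requires at least 2 profiles")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = profiles.index[int(np.argmax(norms == 0))]
        raise ValueError(f"profile {bad!r} is a zero vector")
    D = squareform(pdist(X, metric="cosine"))
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids=tuple(map(str, profiles.index)), values=D)


def pseudo_f(X: np.ndarray | pd.DataFrame, labels) -> float:
    """Calinski-Harabasz ratio [BGSS/(k-1)] / [WGSS/(n-k)].

    BGSS / WGSS are between- and within-cluster sums of squared Euclidean
    deviations from the cluster centroids / grand centroid.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if not 2 <= k <= n - 1:
        raise ValueError(f"pseudo-F requires 2 <= k <= n-1, got k={k}, n={n}")
    grand = X.mean(axis=0)
    bgss = 0.0
    wgss = 0.0
    for lab in uniq:
        member = X[labels == lab]
        if member.shape[0] == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"empty cluster {lab!r}")
        centroid = member.mean(axis=0)
        bgss += member.shape[0] * float(((centroid - grand) ** 2).sum())
        wgss += float(((member - centroid) ** 2).sum())
    if wgss == 0.0:
        raise PerfectSeparationError(
            f"zero within-cluster scatter at k={k}: clusters are perfectly separated"
        )
    return (bgss / (k - 1)) / (wgss / (n - k))


def select_k(
    profiles: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    restarts: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """Choose the cluster count maximising pseudo-F over repeated k-means runs.

    For each candidate k, k-means (squared Euclidean, k-means++ seeding) is
    restarted ``restarts`` times with seeds derived from ``seed``; the
    labelling with the highest pseudo-F is kept.  The returned k maximises
    the per-k best pseudo-F, ties broken toward smaller k.  A perfectly
    separated labelling (zero within-cluster scatter) beats any finite score.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = tuple(map(str, profiles.index))
        X = np.asarray(profiles, dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        ids = tuple(str(i) for i in range(X.shape[0]))
    n = X.shape[0]
    kmin, kmax = k_range
    if not (2 <= kmin <= kmax <= n - 1):
        raise ValueError(f"k_range {k_range} invalid for n={n}: need 2 <= kmin <= kmax <= n-1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(kmax - kmin + 1)]
    best_k = None
    best_f = -np.inf
    best_labels = None
    trace: dict[int, float] = {}
    for k, kseed in zip(range(kmin, kmax + 1), child_seeds):
        rng = np.random.RandomState(kseed)
        k_best_f = -np.inf
        k_best_labels = None
        for _ in range(restarts):
            km = KMeans(
                n_clusters=k, init="k-means++", n_init=1,
                random_state=int(rng.randint(2**31)),
            ).fit(X)
            labels = km.labels_
            if len(np.unique(labels)) < k:
                continue
            try:
                f = pseudo_f(X, labels)
            except PerfectSeparationError:
                f = np.inf
            if f > k_best_f:
                k_best_f = f
                k_best_labels = labels
        trace[k] = float(k_best_f)
        if k_best_labels is not None and k_best_f > best_f:
            best_f = k_best_f
            best_k = k
            best_labels = k_best_labels
    if best_k is None:
        raise ValueError("no valid clustering found in the requested k range")
    return ClusterResult(
        ids=ids, labels=best_labels, k=best_k, pseudo_f=float(best_f),
        restarts=restarts, seed=seed, trace=trace,
    )


def pca_profiles(profiles: pd.DataFrame | np.ndarray, n_components: int = 3) -> PCAScores:
    """Project mean-centred profiles onto the top principal components.

    Columns are centred but not variance-scaled; explained-variance fractions
    are non-increasing.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = tuple(map(str, profiles.index))
        X = np.asarray(profiles, dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        ids = tuple(str(i) for i in range(X.shape[0]))
    if X.shape[0] < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} rows for {n_components} components")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("zero total variance: all profiles identical")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAScores(ids=ids, scores=scores, explained_variance=pca.explained_variance_ratio_)


def cluster_similarity_matrix(dm: DistanceMatrix, linkage: str = "average"):
    """Hierarchically cluster rows of the similarity matrix S = 1 - D.

    Rows of S are compared by Pearson-correlation distance (1 - r) and merged
    by the requested linkage (default average), mirroring the heatmap-viewer
    convention of clustering the loaded matrix itself.  Returns the SciPy
    merge list ``Z`` and the deterministic leaf order.
    """
    S = 1.0 - dm.values
    sd = S.std(axis=1)
    if (sd == 0).any():
        bad = dm.ids[int(np.argmax(sd == 0))]
        raise ValueError(f"row {bad!r} is constant; Pearson correlation undefined")
    d = pdist(S, metric="correlation")
    Z = hierarchy.linkage(d, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return Z, [dm.ids[i] for i in leaves]


def station_report(
    gc_table: pd.DataFrame, station_map: pd.Series | dict
) -> pd.DataFrame:
    """Per-station high-GC composition table.

    ``gc_table`` needs columns ``id`` and ``gc_class``; ``station_map`` maps
    every id to a station label.  Output columns: station, n, n_high,
    pct_high (one decimal).  A final ``overall`` row pools counts across
    stations (a pooled ratio, not a mean of station percentages).
    """
    if isinstance(station_map, dict):
        station_map = pd.Series(station_map)
    missing = set(gc_table["id"]) - set(station_map.index)
    if missing:
        raise ValueError(f"ids missing from station map: {sorted(missing)[:5]}")
    df = gc_table.copy()
    df["station"] = df["id"].map(station_map)
    rows = []
    for station, sub in df.groupby("station", sort=True):
        n = len(sub)
        n_high = int((sub["gc_class"] == "high").sum())
        rows.append(
            {"station": station, "n": n, "n_high": n_high,
             "pct_high": round(100.0 * n_high / n, 1)}
        )
    n_all = len(df)
    n_high_all = int((df["gc_class"] == "high").sum())
    rows.append(
        {"station": "overall", "n": n_all, "n_high": n_high_all,
         "pct_high": round(100.0 * n_high_all / n_all, 1)}
    )
    return pd.DataFrame(rows)
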