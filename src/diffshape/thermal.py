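"""Thermal-unfolding clustering of per-nucleotide reactivity trajectories.

Probing the same RNA at a ladder of temperatures (37, 53, 65, 74, 85 degC
in the reference protocol) yields one reactivity vector per nucleotide.
Nucleotides sharing an unfolding behaviour cluster together; with k = 4
the clusters map onto four archetypes:

``always_reactive``
    single-stranded positions, highly reactive already at 37 degC;
``tertiary_37_53``
    positions gaining reactivity between 37 and 53 degC, where the
    Mg2+-dependent tertiary structure (pseudoknots, kissing loops,
    non-canonical pairs) melts cooperatively;
``secondary_65``
    regular helices opening from ~65 degC;
``stable_85``
    exceptionally stable helices only opening above ~74 degC.

Vectors are log2-transformed (after flooring at 0.01, since normalized
SHAPE values can be <= 0) and standardized nucleotide-wise then
temperature-wise, so clustering sees the *shape* of the thermal response
rather than its magnitude. k is chosen from the within-cluster
sum-of-squared-errors ("distortion") curve over k = 1..10 by the
maximum-distance-to-chord elbow rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans

from .io import ReactivityProfile

__all__ = [
    "ARCHETYPES",
    "TemperatureMatrix",
    "ClusterAssignment",
    "ReactivityStandardizer",
    "ThermalArchetypeKMeans",
    "build_matrix",
    "transform",
    "kmeans_cluster",
    "elbow",
    "label_archetypes",
]

ARCHETYPES = ("always_reactive", "tertiary_37_53", "secondary_65", "stable_85", "unassigned")


@dataclass
class TemperatureMatrix:
    """Nucleotide x temperature reactivity matrix with complete rows only."""

    temperatures: np.ndarray  # degC, strictly increasing
    positions: np.ndarray  # kept 1-based nucleotide indices
    bases: np.ndarray
    matrix: np.ndarray  # shape (n_positions, n_temperatures)
    transformed: bool = False
    dropped_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.positions), len(self.temperatures)):
            raise ValueError("matrix shape inconsistent with positions/temperatures")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.isnan(self.matrix).any():
            raise ValueError("temperature matrix must not contain undetermined entries")


@dataclass
class ClusterAssignment:
    """k-means result on a temperature matrix, plus archetype labels."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray  # in the transformed space used for clustering
    distortion: float  # within-cluster sum of squared errors
    seed: int
    archetypes: list[str] = field(default_factory=list)  # per cluster, len k


def build_matrix(profiles: list[ReactivityProfile]) -> TemperatureMatrix:
    """Assemble aggregated per-temperature profiles into one matrix.

    Positions undetermined at (or absent from) any temperature are dropped
    and recorded in ``dropped_positions``; the matrix is raw (untransformed).
    """
    if len(profiles) < 2:
        raise ValueError("need profiles for at least two temperatures")
    profiles = sorted(profiles, key=lambda p: p.condition.temperature_C)
    temps = np.array([p.condition.temperature_C for p in profiles], dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("profiles must come from distinct temperatures")

    universe = sorted(set().union(*(map(int, p.positions) for p in profiles)))
    maps = []
    for p in profiles:
        maps.append({int(pos): i for i, pos in enumerate(p.positions)})
    kept, dropped, rows, bases = [], [], [], []
    base_map = {int(pos): str(b) for p in profiles for pos, b in zip(p.positions, p.bases)}
    for pos in universe:
        row = []
        for p, m in zip(profiles, maps):
            i = m.get(pos)
            if i is None or p.undetermined[i]:
                row = None
                break
            row.append(p.mean[i])
        if row is None:
            dropped.append(pos)
        else:
            kept.append(pos)
            rows.append(row)
            bases.append(base_map[pos])
    return TemperatureMatrix(
        temperatures=temps,
        positions=np.array(kept, dtype=int),
        bases=np.array(bases, dtype="U1"),
        matrix=np.array(rows, dtype=float).reshape(len(kept), len(temps)),
        transformed=False,
        dropped_positions=np.array(dropped, dtype=int),
    )


class ReactivityStandardizer(TransformerMixin, BaseEstimator):
    """Floor -> log2 -> row-standardize -> column-standardize transformer.

    Values below ``floor`` (default 0.01) are clamped before the log so that
    non-positive normalized reactivities stay finite. Rows (nucleotides) are
    standardized to mean 0 / sd 1, then columns (temperatures) likewise;
    zero-variance rows or columns are centered only (the divide is skipped).
    Standard deviations use the population convention (ddof = 0).

    The transform is stateless — ``fit`` only validates — so the estimator
    composes with sklearn pipelines without leaking information across
    folds.
    """

    def __init__(self, floor: float = 0.01):
        self.floor = floor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D nucleotide x temperature array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.log2(np.maximum(np.asarray(X, dtype=float), self.floor))
        X = _standardize(X, axis=1)
        X = _standardize(X, axis=0)
        return X

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)


def _standardize(X: np.ndarray, axis: int) -> np.ndarray:
    mean = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, keepdims=True)
    X = X - mean
    with np.errstate(invalid="ignore"):
        return np.where(sd > 0, X / np.where(sd > 0, sd, 1.0), X)


def transform(matrix: TemperatureMatrix, floor: float = 0.01) -> TemperatureMatrix:
    """Return the log2 + twice-standardized version of a raw matrix."""
    if matrix.transformed:
        raise ValueError("matrix is already transformed")
    X = ReactivityStandardizer(floor=floor).fit_transform(matrix.matrix)
    return TemperatureMatrix(
        temperatures=matrix.temperatures,
        positions=matrix.positions,
        bases=matrix.bases,
        matrix=X,
        transformed=True,
        dropped_positions=matrix.dropped_positions,
    )


def kmeans_cluster(
    matrix: TemperatureMatrix, k: int, seed: int = 42, n_restarts: int = 50
) -> ClusterAssignment:
    """Best-of-``n_restarts`` k-means on the transformed matrix.

    Squared-Euclidean objective with k-means++ seeding; deterministic given
    ``seed``. The reported distortion is the within-cluster sum of squared
    errors of the best restart.
    """
    n = matrix.matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=seed, tol=1e-6, init="k-means++"
    ).fit(matrix.matrix)
    return ClusterAssignment(
        k=k,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        distortion=float(km.inertia_),
        seed=seed,
    )


def elbow(
    matrix: TemperatureMatrix, k_max: int = 10, seed: int = 42, n_restarts: int = 50
) -> tuple[np.ndarray, int]:
    """Distortion curve for k = 1..k_max and the elbow-chosen k.

    The elbow is automated as the k maximizing the perpendicular distance
    from (k, distortion_k) to the chord joining the curve's endpoints; the
    full curve is always returned so the choice can be overridden.
    """
    k_max = min(k_max, matrix.matrix.shape[0])
    distortions = np.array(
        [kmeans_cluster(matrix, k, seed=seed, n_restarts=n_restarts).distortion for k in range(1, k_max + 1)]
    )
    if np.any(np.diff(distortions) > 1e-9 * max(distortions[0], 1.0)):
        warnings.warn("distortion curve is not monotonically decreasing; consider more restarts")
    if k_max == 1:
        return distortions, 1
    ks = np.arange(1, k_max + 1, dtype=float)
    # Perpendicular distance to the chord (1, d1) -- (k_max, d_kmax).
    x1, y1, x2, y2 = ks[0], distortions[0], ks[-1], distortions[-1]
    norm = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * ks - (x2 - x1) * distortions + x2 * y1 - y2 * x1) / norm
    return distortions, int(ks[int(np.argmax(dist))])


def label_archetypes(
    assignment: ClusterAssignment,
    matrix_raw: TemperatureMatrix,
    high_37_thresh: float = 0.7,
) -> ClusterAssignment:
    """Attach thermal-archetype names to a k = 4 cluster assignment.

    A cluster whose mean raw reactivity at the lowest temperature exceeds
    ``high_37_thresh`` is ``always_reactive``; otherwise the label follows
    the temperature interval where the cluster's raw centroid rises most:
    the first interval (37->53) marks tertiary positions, the last (74->85)
    exceptionally stable helices, anything in between regular secondary
    structure. With k != 4 every cluster is labelled ``unassigned``.
    """
    if matrix_raw.transformed:
        raise ValueError("archetype labelling needs the raw (untransformed) matrix")
    k = assignment.k
    if k != 4:
        warnings.warn(f"archetype labels defined for k=4, got k={k}; labelling unassigned")
        assignment.archetypes = ["unassigned"] * k
        return assignment
    n_int = len(matrix_raw.temperatures) - 1
    labels = []
    for c in range(k):
        rows = matrix_raw.matrix[assignment.labels == c]
        if rows.size == 0:
            labels.append("unassigned")
            continue
        centroid = rows.mean(axis=0)
        if centroid[0] > high_37_thresh:
            labels.append("always_reactive")
            continue
        rises = np.diff(centroid)
        best = int(np.argmax(rises))
        if np.sum(rises == rises[best]) > 1:
            labels.append("unassigned")
        elif best == 0:
            labels.append("tertiary_37_53")
        elif best == n_int - 1:
            labels.append("stable_85")
        else:
            labels.append("secondary_65")
    assignment.archetypes = labels
    return assignment


class ThermalArchetypeKMeans(ClusterMixin, BaseEstimator):
    """End-to-end thermal clustering estimator.

    Parameters
    ----------
    n_clusters:
        Cluster count, or ``"auto"`` to select k by the elbow rule.
    k_max:
        Upper end of the distortion curve scanned when ``n_clusters="auto"``.
    n_restarts:
        k-means restarts per k (best distortion wins).
    floor:
        Reactivity floor applied before the log2 transform.
    high_37_thresh:
        Raw 37 degC mean above which a cluster is called always_reactive.
    random_state:
        Seed; results are bit-reproducible given (seed, n_restarts).

    Attributes (after :meth:`fit`)
    ------------------------------
    ``labels_``, ``cluster_centers_`` (transformed space), ``inertia_``,
    ``k_``, ``distortions_`` (curve over 1..k_max when k was automatic),
    ``archetypes_`` (per-cluster names) and ``archetype_labels_``
    (per-sample names).
    """

    def __init__(
        self,
        n_clusters: int | str = "auto",
        k_max: int = 10,
        n_restarts: int = 50,
        floor: float = 0.01,
        high_37_thresh: float = 0.7,
        random_state: int = 42,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.floor = floor
        self.high_37_thresh = high_37_thresh
        self.random_state = random_state

    def fit(self, X, y=None, temperatures=None):
        """Cluster a raw nucleotide x temperature reactivity matrix.

        ``X`` may be a :class:`TemperatureMatrix` (raw) or a plain 2-D
        array, in which case ``temperatures`` supplies the column grid
        (defaults to the 37/53/65/74/85 ladder when five columns are given).
        """
        tm = _as_matrix(X, temperatures)
        tmx = transform(tm, floor=self.floor)
        if self.n_clusters == "auto":
            self.distortions_, self.k_ = elbow(
                tmx, k_max=self.k_max, seed=self.random_state, n_restarts=self.n_restarts
            )
        else:
            self.k_ = int(self.n_clusters)
            self.distortions_ = None
        assignment = kmeans_cluster(tmx, self.k_, seed=self.random_state, n_restarts=self.n_restarts)
        assignment = label_archetypes(assignment, tm, high_37_thresh=self.high_37_thresh)
        self.labels_ = assignment.labels
        self.cluster_centers_ = assignment.centroids
        self.inertia_ = assignment.distortion
        self.archetypes_ = assignment.archetypes
        self.archetype_labels_ = np.array([assignment.archetypes[c] for c in assignment.labels])
        self.assignment_ = assignment
        self.positions_ = tm.positions
        return self


def _as_matrix(X, temperatures) -> TemperatureMatrix:
    if isinstance(X, TemperatureMatrix):
        if X.transformed:
            raise ValueError("pass the raw matrix; the estimator transforms internally")
        return X
    X = np.asarray(X, dtype=float)
    if temperatures is None:
        if X.shape[1] == 5:
            temperatures = np.array([37.0, 53.0, 65.0, 74.0, 85.0])
        else:
            raise ValueError("temperatures must be given for a plain array")
    n = X.shape[0]
    return TemperatureMatrix(
        temperatures=np.asarray(temperatures, dtype=float),
        positions=np.arange(1, n + 1),
        bases=np.array(["A"] * n, dtype="U1"),
        matrix=X,
    )
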