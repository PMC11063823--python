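"""k-means clustering of preferred directions on the unit circle.

Preferred directions are fixed to unit length and converted to
Cartesian coordinates, so Euclidean (chord) distance — monotone in
angular separation up to 180° — drives both the k-means objective and
the silhouette fitness

.. math::

    \\mathrm{SV}(i) = \\frac{b(i) - a(i)}{\\max(a(i), b(i))},

with :math:`a(i)` the mean distance to the point's own cluster and
:math:`b(i)` the mean distance to the nearest other cluster.  The model
either selects k over a range by maximal mean SV or fixes k; clusters
are then labeled ventral/dorsal/nasal/temporal anchored to the angles
of genetically identified reference cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "fit_direction_clusters",
    "silhouette_values",
    "label_clusters",
    "circular_mean_deg",
]

_LABELS = ("ventral", "dorsal", "nasal", "temporal")


class LabelingConflictError(ValueError):
    """Two anatomical labels resolved to the same cluster."""


@dataclass
class ClusterModel:
    """Fitted direction-clustering model (result object)."""

    k: int
    points_xy: np.ndarray          # (n, 2) unit vectors
    angles_deg: np.ndarray         # (n,)
    assignments: np.ndarray        # (n,) int
    centroids_xy: np.ndarray       # (k, 2)
    sv_per_point: np.ndarray       # (n,)
    mean_sv: float
    seed: int
    sv_by_k: dict[int, float] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)
    single_cluster: bool = False

    @property
    def centroid_angles_deg(self) -> np.ndarray:
        return np.rad2deg(np.arctan2(self.centroids_xy[:, 1],
                                     self.centroids_xy[:, 0])) % 360.0

    def label_of(self, cluster: int) -> str:
        return self.labels.get(int(cluster), "unlabeled")


def _to_unit_xy(angles_deg: np.ndarray) -> np.ndarray:
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.column_stack([np.cos(theta), np.sin(theta)])


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles, in [0, 360)."""
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.sin(theta).mean(),
                                       np.cos(theta).mean())) % 360.0)


def _circdiff_deg(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def silhouette_values(points_xy: np.ndarray,
                      assignments: np.ndarray) -> np.ndarray:
    """Per-point silhouette values (max-denominator definition).

    a(i) is the mean distance from i to the other members of its
    cluster (0 for singleton clusters, hence SV = 1 when b > 0);
    b(i) the mean distance to the members of the nearest other cluster.
    Points with a = b = 0 (coincident clusters) get SV = 0.
    """
    points = np.asarray(points_xy, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    dist = cdist(points, points)
    n = points.shape[0]
    a = np.zeros(n)
    b = np.full(n, np.inf)
    for lab in uniq:
        members = labels == lab
        size = members.sum()
        if size == 0:
            raise ValueError("empty cluster")
        within = dist[np.ix_(members, members)]
        a[members] = within.sum(axis=1) / max(size - 1, 1)
        for other in uniq:
            if other == lab:
                continue
            mean_to = dist[np.ix_(members, labels == other)].mean(axis=1)
            b[members] = np.minimum(b[members], mean_to)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        sv = (b - a) / denom
    return np.where(denom > 0, sv, 0.0)


def fit_direction_clusters(preferred_angles_deg, k_range=range(2, 9),
                           n_restarts: int = 10, seed: int = 0,
                           force_k: int | None = None) -> ClusterModel:
    """Cluster preferred directions by k-means on unit vectors.

    For each k in ``k_range`` (or only ``force_k``), k-means with
    k-means++ seeding and ``n_restarts`` restarts keeps the best
    within-cluster objective; the returned model carries the k that
    maximizes mean silhouette value (ties to the smaller k).
    """
    angles = np.asarray(preferred_angles_deg, dtype=float) % 360.0
    points = _to_unit_xy(angles)
    n = points.shape[0]
    if n == 0:
        raise ValueError("no points to cluster")
    if np.unique(np.round(points, 12), axis=0).shape[0] == 1:
        return ClusterModel(k=1, points_xy=points, angles_deg=angles,
                            assignments=np.zeros(n, dtype=int),
                            centroids_xy=points[:1].copy(),
                            sv_per_point=np.full(n, np.nan),
                            mean_sv=float("nan"), seed=seed,
                            single_cluster=True)

    ks = [force_k] if force_k is not None else list(k_range)
    best = None
    sv_by_k: dict[int, float] = {}
    for k in ks:
        if k > n:
            warnings.warn(f"skipping k={k}: fewer points than clusters",
                          stacklevel=2)
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        with warnings.catch_warnings():
            # duplicate points can leave k-means with fewer distinct
            # clusters than requested; handled below
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = km.fit_predict(points)
        if np.unique(labels).size < 2:
            continue
        sv = silhouette_values(points, labels)
        mean_sv = float(sv.mean())
        sv_by_k[k] = mean_sv
        if best is None or mean_sv > best[0] + 1e-12:
            best = (mean_sv, k, labels, km.cluster_centers_, sv)
    if best is None:
        raise ValueError("no k in k_range could be fitted")
    mean_sv, k, labels, centers, sv = best
    return ClusterModel(k=k, points_xy=points, angles_deg=angles,
                        assignments=labels, centroids_xy=centers,
                        sv_per_point=sv, mean_sv=mean_sv, seed=seed,
                        sv_by_k=sv_by_k)


def label_clusters(model: ClusterModel, reference_angles_deg,
                   nasal_reference_angles_deg=None) -> ClusterModel:
    """Assign ventral/dorsal/nasal/temporal labels to clusters.

    The ventral cluster is the one whose centroid angle is circularly
    nearest the circular mean of the reference angles (genetically
    identified ventral-preferring cells); dorsal is the cluster nearest
    ventral + 180°.  Nasal comes from its own references when given,
    otherwise the unlabeled cluster nearest ±90° off the ventral axis;
    temporal is nearest nasal + 180°.  Each cluster takes at most one
    label.
    """
    refs = np.atleast_1d(np.asarray(reference_angles_deg, dtype=float))
    if refs.size == 0:
        raise ValueError("reference angle list is empty")
    cent = model.centroid_angles_deg
    taken: dict[int, str] = {}

    def claim(target_deg: float, label: str) -> int:
        order = np.argsort(_circdiff_deg(cent, target_deg))
        best = int(order[0])
        if best in taken:
            free = [int(i) for i in order if int(i) not in taken]
            if not free:
                raise LabelingConflictError(
                    f"label {label!r} collides on cluster {best}")
            warnings.warn(f"label {label!r}: nearest cluster already "
                          "labeled; using next nearest", stacklevel=3)
            best = free[0]
        taken[best] = label
        return best

    ventral_deg = circular_mean_deg(refs)
    claim(ventral_deg, "ventral")
    if model.k >= 2:
        claim((ventral_deg + 180.0) % 360.0, "dorsal")
    if model.k >= 3:
        if nasal_reference_angles_deg is not None:
            nasal_deg = circular_mean_deg(nasal_reference_angles_deg)
        else:
            free = [i for i in range(model.k) if i not in taken]
            nasal_deg = cent[min(
                free,
                key=lambda i: min(_circdiff_deg(cent[i],
                                                (ventral_deg + 90) % 360),
                                  _circdiff_deg(cent[i],
                                                (ventral_deg - 90) % 360)))]
        claim(nasal_deg, "nasal")
    if model.k >= 4:
        claim((nasal_deg + 180.0) % 360.0, "temporal")
    if model.k < 4:
        warnings.warn("fewer than 4 clusters: partial labeling",
                      stacklevel=2)
    model.labels = taken
    return model
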