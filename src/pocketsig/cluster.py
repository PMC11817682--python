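"""Two-stage definition of receptor conformations.

Stage 1 groups trajectory frames into ``h`` hierarchical clusters by
complete-linkage agglomerative clustering of the combined configuration
distance.  Each cluster is represented by its medoid (the member frame
minimizing the summed distance to all other members).  Stage 2 measures
pairwise structural RMSD between the medoids, converts it to a Gaussian
similarity ``S_ij = exp(-D_ij^2 / (2 delta^2))``, and groups the medoids
(and thereby all frames) into ``c`` conformations by spectral clustering
with the deterministic pivoted-QR label assignment.

The per-ligand occupancy of those conformations — the fraction table —
is the independent variable of the downstream efficacy regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import SpectralClustering

from .distance import (
    DistanceWeights,
    combine_components,
    component_matrices,
    cross_component_matrices,
    superpose_rmsd,
)
from .featurize import FeatureLayout, FeatureTable

__all__ = [
    "HierarchicalClustering",
    "ConformationModel",
    "hierarchical_cluster",
    "compute_medoids",
    "similarity_from_rmsd",
    "spectral_conformations",
    "ConformationClusterer",
    "fit_conformation_model",
    "conformation_fractions",
    "assign_external_frames",
]


@dataclass
class HierarchicalClustering:
    """Stage-1 result: per-frame cluster labels (1..h) and cluster medoids."""

    h: int
    labels: np.ndarray
    medoid_frames: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoid_frames = np.asarray(self.medoid_frames, dtype=int)
        counts = np.bincount(self.labels, minlength=self.h + 1)[1:]
        if np.any(counts == 0):
            raise ValueError("hierarchical clustering produced an empty cluster")
        for g, m in enumerate(self.medoid_frames, start=1):
            if self.labels[m] != g:
                raise ValueError(f"medoid of cluster {g} carries label {self.labels[m]}")


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels onto 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def hierarchical_cluster(D: np.ndarray, h: int) -> HierarchicalClustering:
    """Complete-linkage agglomerative clustering cut to exactly ``h`` clusters."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (2 <= h <= n):
        raise ValueError(f"h must satisfy 2 <= h <= n_frames ({n}); got {h}")
    if h == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=h, criterion="maxclust")
        labels = _relabel_by_first_occurrence(np.asarray(labels, dtype=int))
        realized = labels.max()
        if realized != h:
            raise ValueError(
                f"complete-linkage cut produced {realized} clusters instead of {h} "
                "(tied merge heights); choose a different h"
            )
    medoids = compute_medoids(D, labels)
    return HierarchicalClustering(h=h, labels=labels, medoid_frames=medoids)


def compute_medoids(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cluster medoid frame indices; ties go to the lowest frame index."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels, dtype=int)
    medoids = []
    for g in range(1, labels.max() + 1):
        members = np.flatnonzero(labels == g)
        if members.size == 0:
            raise ValueError(f"cluster {g} is empty")
        sums = D[np.ix_(members, members)].sum(axis=1)
        medoids.append(int(members[int(np.argmin(sums))]))  # argmin takes first tie
    return np.asarray(medoids, dtype=int)


def similarity_from_rmsd(D_rmsd: np.ndarray, delta: float) -> np.ndarray:
    """Gaussian similarity ``exp(-D^2 / (2 delta^2))`` from an RMSD matrix."""
    if delta <= 0:
        raise ValueError(f"bandwidth delta must be positive, got {delta}")
    D_rmsd = np.asarray(D_rmsd, dtype=float)
    if D_rmsd.ndim != 2 or D_rmsd.shape[0] != D_rmsd.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(D_rmsd, D_rmsd.T, atol=1e-10):
        raise ValueError("RMSD matrix must be symmetric")
    return np.exp(-(D_rmsd**2) / (2.0 * delta**2))


def spectral_conformations(S: np.ndarray, c: int) -> np.ndarray:
    """Group ``h`` medoids into ``c`` conformations by spectral clustering.

    Normalized-Laplacian spectral embedding with the pivoted-QR
    (``cluster_qr``) assignment — deterministic, no k-means restarts.
    Returns a mapping array of length h with values in 1..c.
    """
    S = np.asarray(S, dtype=float)
    h = S.shape[0]
    if not (2 <= c <= h - 1):
        raise ValueError(f"c must satisfy 2 <= c <= h - 1 (h={h}); got {c}")
    sc = SpectralClustering(
        n_clusters=c,
        affinity="precomputed",
        assign_labels="cluster_qr",
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fully-connected graph warning is expected
        raw = sc.fit_predict(S)
    return _relabel_by_first_occurrence(np.asarray(raw, dtype=int) + 1)


def conformation_fractions(
    frame_labels: np.ndarray,
    ligand_ids: Sequence[str],
    c: int,
    ligand_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-ligand occupancy fractions f_{l,c} (rows sum to 1).

    Replicate runs of one ligand are pooled (all its frames counted
    together) before normalization.
    """
    frame_labels = np.asarray(frame_labels, dtype=int)
    ligand_ids = np.asarray(ligand_ids, dtype=object)
    if ligand_order is None:
        seen: dict[str, None] = {}
        for lid in ligand_ids:
            seen.setdefault(str(lid))
        ligand_order = list(seen)
    rows = []
    for lig in ligand_order:
        mask = ligand_ids == lig
        if not mask.any():
            raise ValueError(f"ligand {lig!r} has zero frames")
        counts = np.bincount(frame_labels[mask], minlength=c + 1)[1 : c + 1]
        rows.append(counts / counts.sum())
    return pd.DataFrame(rows, index=list(ligand_order), columns=range(1, c + 1))


class ConformationClusterer:
    """Two-stage conformation model as a scikit-learn style estimator.

    Parameters
    ----------
    h : int
        Number of stage-1 hierarchical (complete-linkage) clusters.
    delta : float
        Bandwidth of the Gaussian RMSD similarity kernel (A).
    c : int
        Number of conformations returned by the spectral stage.
    weights : tuple of three floats
        Convex weights (w_theta, w_ca, w_hb) of the combined distance.
    medoid_metric : {"ca_features", "superposed"}
        How the stage-2 medoid-medoid RMSD matrix is measured.
        ``ca_features`` uses the RMS difference of the C-alpha
        pairwise-distance features (A, rotation-invariant, available for
        feature-only inputs); ``superposed`` uses the C-alpha RMSD after
        optimal rigid superposition and requires coordinates at fit time.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (n_frames,) conformation id (1..c) per frame.
    hierarchical_ : stage-1 :class:`HierarchicalClustering`.
    cluster_to_conf_ : (h,) conformation id per hierarchical cluster.
    medoid_rmsd_, similarity_ : stage-2 matrices over medoids.
    conformation_medoids_ : one representative frame index per conformation.
    medoid_features_ : feature matrix of the h cluster medoids (for
        nearest-medoid assignment of external frames).
    """

    def __init__(
        self,
        h: int = 40,
        delta: float = 2.0,
        c: int = 14,
        weights: tuple[float, float, float] = (0.25, 0.25, 0.5),
        medoid_metric: str = "ca_features",
    ) -> None:
        self.h = h
        self.delta = delta
        self.c = c
        self.weights = weights
        self.medoid_metric = medoid_metric

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "h": self.h,
            "delta": self.delta,
            "c": self.c,
            "weights": self.weights,
            "medoid_metric": self.medoid_metric,
        }

    def set_params(self, **params) -> "ConformationClusterer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def distance_weights(self) -> DistanceWeights:
        return DistanceWeights(*self.weights)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        X: FeatureTable,
        y=None,
        distance_matrix: np.ndarray | None = None,
        coords: np.ndarray | None = None,
    ) -> "ConformationClusterer":
        """Fit the two-stage model on a feature table.

        ``distance_matrix`` may supply a precomputed combined-distance
        matrix over the same frames (the hyperparameter search reuses
        per-component matrices this way).  ``coords`` is an optional
        (n_frames, n_atoms, 3) C-alpha coordinate stack enabling the
        superposed RMSD metric between medoids.
        """
        if not isinstance(X, FeatureTable):
            raise TypeError("X must be a FeatureTable")
        w = self.distance_weights
        if distance_matrix is None:
            d_th, d_ca, d_hb = component_matrices(X.theta, X.ca, X.hb)
            distance_matrix = combine_components(d_th, d_ca, d_hb, w)
        D = np.asarray(distance_matrix, dtype=float)
        if D.shape != (X.n_frames, X.n_frames):
            raise ValueError("distance matrix does not match the feature table")

        hier = hierarchical_cluster(D, self.h)
        med = hier.medoid_frames
        if self.medoid_metric == "superposed":
            if coords is None:
                raise ValueError("medoid_metric='superposed' requires coords at fit time")
            m = med.size
            D_rmsd = np.zeros((m, m))
            for i in range(m):
                for j in range(i + 1, m):
                    D_rmsd[i, j] = D_rmsd[j, i] = superpose_rmsd(
                        coords[med[i]], coords[med[j]]
                    )
        elif self.medoid_metric == "ca_features":
            ca = X.ca[med]
            diff = ca[:, None, :] - ca[None, :, :]
            D_rmsd = np.sqrt(np.mean(diff**2, axis=-1))
            np.fill_diagonal(D_rmsd, 0.0)
        else:
            raise ValueError(f"unknown medoid_metric {self.medoid_metric!r}")

        S = similarity_from_rmsd(D_rmsd, self.delta)
        cluster_to_conf = spectral_conformations(S, self.c)
        frame_labels = cluster_to_conf[hier.labels - 1]

        conf_medoids = []
        for conf in range(1, self.c + 1):
            members = np.flatnonzero(frame_labels == conf)
            sums = D[np.ix_(members, members)].sum(axis=1)
            conf_medoids.append(int(members[int(np.argmin(sums))]))

        self.layout_: FeatureLayout = X.layout
        self.hierarchical_ = hier
        self.medoid_rmsd_ = D_rmsd
        self.similarity_ = S
        self.cluster_to_conf_ = cluster_to_conf
        self.labels_ = frame_labels
        self.conformation_medoids_ = np.asarray(conf_medoids, dtype=int)
        self.medoid_features_ = X.values[med].copy()
        self.medoid_theta_ = X.theta[med].copy()
        self.medoid_ca_ = X.ca[med].copy()
        self.medoid_hb_ = X.hb[med].copy()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "labels_"):
            raise AttributeError("ConformationClusterer is not fitted yet")

    def fit_predict(self, X: FeatureTable, y=None, **kw) -> np.ndarray:
        return self.fit(X, y, **kw).labels_

    def predict(self, X: FeatureTable, distances_to_medoids: np.ndarray | None = None) -> np.ndarray:
        """Assign new frames to conformations via their nearest cluster medoid.

        Ties between equidistant medoids resolve to the lowest conformation
        id, then the lowest cluster index.
        """
        self._check_fitted()
        if distances_to_medoids is None:
            if X.layout != self.layout_:
                raise ValueError("feature layout of X does not match the fitted model")
            d_th, d_ca, d_hb = cross_component_matrices(
                X.theta, X.ca, X.hb, self.medoid_theta_, self.medoid_ca_, self.medoid_hb_
            )
            distances_to_medoids = combine_components(d_th, d_ca, d_hb, self.distance_weights)
        D = np.asarray(distances_to_medoids, dtype=float)
        labels = np.empty(D.shape[0], dtype=int)
        confs = self.cluster_to_conf_
        for i in range(D.shape[0]):
            row = D[i]
            best = row.min()
            candidates = np.flatnonzero(np.isclose(row, best, rtol=0.0, atol=1e-12))
            labels[i] = int(confs[candidates].min())
        return labels

    def fractions(self, ligand_ids: Sequence[str], ligand_order=None) -> pd.DataFrame:
        self._check_fitted()
        return conformation_fractions(self.labels_, ligand_ids, self.c, ligand_order)


@dataclass
class ConformationModel:
    """Plain-record view of a fitted two-stage clustering."""

    c: int
    cluster_to_conf: np.ndarray
    frame_labels: np.ndarray
    conformation_medoids: np.ndarray
    clusterer: ConformationClusterer = field(repr=False)

    def to_dict(self) -> dict:
        cl = self.clusterer
        return {
            "hyperparameters": cl.get_params(),
            "c": self.c,
            "cluster_to_conf": self.cluster_to_conf.tolist(),
            "conformation_medoids": self.conformation_medoids.tolist(),
            "medoid_features": cl.medoid_features_.tolist(),
            "layout": {
                "n_theta": cl.layout_.n_theta,
                "n_ca": cl.layout_.n_ca,
                "n_hb": cl.layout_.n_hb,
            },
        }


def fit_conformation_model(
    features: FeatureTable,
    h: int,
    delta: float,
    c: int,
    weights: DistanceWeights | tuple[float, float, float],
    coords: np.ndarray | None = None,
    medoid_metric: str | None = None,
) -> ConformationModel:
    """Pipeline composition: complete-linkage -> medoids -> medoid RMSD ->
    Gaussian similarity -> spectral grouping -> frame relabeling."""
    if isinstance(weights, DistanceWeights):
        weights = (weights.w_theta, weights.w_ca, weights.w_hb)
    if medoid_metric is None:
        medoid_metric = "superposed" if coords is not None else "ca_features"
    cl = ConformationClusterer(
        h=h, delta=delta, c=c, weights=weights, medoid_metric=medoid_metric
    )
    cl.fit(features, coords=coords)
    return ConformationModel(
        c=c,
        cluster_to_conf=cl.cluster_to_conf_,
        frame_labels=cl.labels_,
        conformation_medoids=cl.conformation_medoids_,
        clusterer=cl,
    )


def assign_external_frames(
    model: ConformationModel | ConformationClusterer,
    features: FeatureTable,
    weights: DistanceWeights | None = None,
) -> np.ndarray:
    """Label held-out frames with the conformation of their nearest medoid."""
    cl = model.clusterer if isinstance(model, ConformationModel) else model
    if weights is not None:
        w = (weights.w_theta, weights.w_ca, weights.w_hb)
        if tuple(cl.weights) != w:
            raise ValueError("weights differ from the weights the model was fitted with")
    return cl.predict(features)
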