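"""Weighted configuration-configuration distance for receptor ensembles.

A configuration (one trajectory frame) is described by three feature
vectors: backbone/side-chain torsion angles, pairwise C-alpha distances,
and hydrogen-bond donor-acceptor distances.  The distance between two
configurations combines one root-mean-square component per feature kind,
with the torsion component measured on the circle.  The three components
are commensurate (each is an RMS over its own features), so a convex
combination with weights ``w_theta + w_ca + w_hb = 1`` yields a single
scalar distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DistanceWeights",
    "DistanceMatrix",
    "torsion_component",
    "vector_component",
    "combined_distance",
    "component_matrices",
    "pairwise_matrix",
    "superpose_rmsd",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class DistanceWeights:
    """Convex weights for the torsion, C-alpha and H-bond components."""

    w_theta: float
    w_ca: float
    w_hb: float

    def __post_init__(self) -> None:
        w = np.array([self.w_theta, self.w_ca, self.w_hb], dtype=float)
        if np.any(w < 0):
            raise ValueError(f"distance weights must be nonnegative, got {tuple(w)}")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"distance weights must sum to 1, got sum {w.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_theta, self.w_ca, self.w_hb], dtype=float)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with frame bookkeeping.

    ``frame_ids`` maps each row to ``(ligand_id, frame_index)`` so that
    clustering results can be traced back to their source ensemble.
    """

    values: np.ndarray
    frame_ids: Sequence[tuple[str, int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v
        if self.frame_ids is None:
            self.frame_ids = [("", i) for i in range(v.shape[0])]
        elif len(self.frame_ids) != v.shape[0]:
            raise ValueError("frame_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def wrap_angles(theta: np.ndarray) -> np.ndarray:
    """Wrap angles (radians) into [-pi, pi)."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi, TWO_PI) - np.pi


def angular_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest absolute difference between angles, accounting for periodicity."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % TWO_PI
    return np.minimum(d, TWO_PI - d)


def torsion_component(theta_i: np.ndarray, theta_j: np.ndarray) -> float:
    """RMS of periodic per-angle differences between two torsion vectors."""
    theta_i = np.asarray(theta_i, dtype=float)
    theta_j = np.asarray(theta_j, dtype=float)
    if theta_i.shape != theta_j.shape:
        raise ValueError(
            f"torsion vectors differ in length: {theta_i.shape} vs {theta_j.shape}"
        )
    if theta_i.size == 0:
        raise ValueError("torsion vectors must have length >= 1")
    delta = angular_difference(theta_i, theta_j)
    return float(np.sqrt(np.mean(delta**2)))


def vector_component(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """RMS of per-feature differences between two distance vectors.

    Used identically for the C-alpha pairwise-distance vector and the
    hydrogen-bond donor-acceptor distance vector.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"feature vectors differ in length: {x_i.shape} vs {x_j.shape}")
    if x_i.size == 0:
        raise ValueError("feature vectors must have length >= 1")
    return float(np.sqrt(np.mean((x_i - x_j) ** 2)))


def combined_distance(fi, fj, weights: DistanceWeights) -> float:
    """Weighted sum of the three per-kind RMS components.

    ``fi``/``fj`` are :class:`~pocketsig.featurize.ConfigurationFeatures`
    (anything exposing ``theta``, ``ca`` and ``hb`` arrays).
    """
    d_theta = torsion_component(fi.theta, fj.theta)
    d_ca = vector_component(fi.ca, fj.ca)
    d_hb = vector_component(fi.hb, fj.hb)
    return weights.w_theta * d_theta + weights.w_ca * d_ca + weights.w_hb * d_hb


def _cross_rms(a: np.ndarray, b: np.ndarray, periodic: bool, chunk: int = 256) -> np.ndarray:
    """(nA, nB) matrix of per-kind RMS differences, computed in row chunks."""
    out = np.empty((a.shape[0], b.shape[0]), dtype=float)
    for start in range(0, a.shape[0], chunk):
        stop = min(start + chunk, a.shape[0])
        diff = a[start:stop, None, :] - b[None, :, :]
        if periodic:
            diff = np.abs(diff) % TWO_PI
            diff = np.minimum(diff, TWO_PI - diff)
        out[start:stop] = np.sqrt(np.mean(diff**2, axis=-1))
    return out


def _pairwise_rms(block: np.ndarray, periodic: bool, chunk: int = 256) -> np.ndarray:
    """n x n matrix of per-kind RMS differences."""
    out = _cross_rms(block, block, periodic, chunk)
    # enforce exact symmetry/zero diagonal against round-off
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


def cross_component_matrices(
    theta_a: np.ndarray,
    ca_a: np.ndarray,
    hb_a: np.ndarray,
    theta_b: np.ndarray,
    ca_b: np.ndarray,
    hb_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-component RMS matrices between two stacks of configurations."""
    return (
        _cross_rms(np.atleast_2d(theta_a), np.atleast_2d(theta_b), periodic=True),
        _cross_rms(np.atleast_2d(ca_a), np.atleast_2d(ca_b), periodic=False),
        _cross_rms(np.atleast_2d(hb_a), np.atleast_2d(hb_b), periodic=False),
    )


def component_matrices(
    theta: np.ndarray, ca: np.ndarray, hb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise per-component RMS matrices for a stack of configurations.

    Inputs are (n_frames, N_kind) arrays.  Precomputing the three
    matrices once lets the hyperparameter grid search re-weight them
    without recomputing any per-feature differences.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    ca = np.atleast_2d(np.asarray(ca, dtype=float))
    hb = np.atleast_2d(np.asarray(hb, dtype=float))
    n = theta.shape[0]
    if ca.shape[0] != n or hb.shape[0] != n:
        raise ValueError("feature blocks disagree on frame count")
    return (
        _pairwise_rms(theta, periodic=True),
        _pairwise_rms(ca, periodic=False),
        _pairwise_rms(hb, periodic=False),
    )


def combine_components(
    d_theta: np.ndarray, d_ca: np.ndarray, d_hb: np.ndarray, weights: DistanceWeights
) -> np.ndarray:
    return weights.w_theta * d_theta + weights.w_ca * d_ca + weights.w_hb * d_hb


def pairwise_matrix(features: Sequence, weights: DistanceWeights) -> DistanceMatrix:
    """Symmetric matrix of combined distances over a frame sequence."""
    if len(features) < 2:
        raise ValueError("pairwise matrix requires at least 2 frames")
    theta = np.stack([np.asarray(f.theta, float) for f in features])
    ca = np.stack([np.asarray(f.ca, float) for f in features])
    hb = np.stack([np.asarray(f.hb, float) for f in features])
    d_theta, d_ca, d_hb = component_matrices(theta, ca, hb)
    return DistanceMatrix(values=combine_components(d_theta, d_ca, d_hb, weights))


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """C-alpha RMSD (Angstrom) after optimal rigid superposition.

    Least-squares rotation + translation (Kabsch, proper rotation only —
    no reflection), computed with
    :meth:`scipy.spatial.transform.Rotation.align_vectors`.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a0, b0)
    resid = a0 - rot.apply(b0)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
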