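"""Generalized Procrustes analysis for 2-D landmark configurations.

A full Procrustes fit removes position (centering), size (scaling to unit
centroid size) and orientation (least-squares rotation, reflections
forbidden) from each configuration, leaving pure shape. The consensus (mean
shape) is estimated iteratively: align every configuration to the current
mean, re-average, rescale the mean to unit size, repeat until the mean stops
moving. Distances reported are partial Procrustes distances — the root summed
squared difference between unit-size, optimally rotated configurations — the
convention of mainstream geometric-morphometrics software.

Shape variation is linearized by orthogonal projection onto the tangent space
at the mean shape; with k landmarks in 2-D the tangent coordinates span at
most 2k - 4 dimensions (2 lost to centering, 1 to scale, 1 to rotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConvergenceError, DegenerateGeometryError
from .landmarking import LandmarkConfiguration

GPA_TOL = 1e-10
# high-dispersion samples converge only linearly, so allow a generous cap
GPA_MAX_ITER = 1000


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition."""

    aligned: np.ndarray        # (n, k, 2), unit centroid size, centered
    mean_shape: np.ndarray     # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,), mm
    labels: list[str]
    iterations: int
    converged: bool
    ss_history: list[float] | None = None  # sum of squared residuals per iteration

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def shape_dim(self) -> int:
        """Dimension of shape space: 2k - 4 for 2-D configurations."""
        return 2 * self.k - 4


def _as_array(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    a = np.asarray(config, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("configuration must be a (k, 2) array")
    return a


def centroid_size(config) -> float:
    """Square root of summed squared landmark deviations from the centroid."""
    a = _as_array(config)
    d = a - a.mean(axis=0)
    cs = float(np.sqrt((d ** 2).sum()))
    if cs <= 0.0:
        raise DegenerateGeometryError("all landmarks coincide: zero centroid size")
    return cs


def _center_scale(config) -> np.ndarray:
    a = _as_array(config)
    c = a - a.mean(axis=0)
    return c / centroid_size(a)


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||A @ R - B||_F for centered A, B."""
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def align_pair(A, B) -> tuple[float, np.ndarray, float]:
    """Rotate centered unit-size A onto B; returns (angle_rad, A_rotated, residual).

    The residual is the Frobenius norm of A_rotated - B (the partial
    Procrustes distance when both inputs are pre-standardized). Reflections
    are not permitted.
    """
    A = _as_array(A)
    B = _as_array(B)
    if not np.allclose(A.mean(axis=0), 0, atol=1e-8) or not np.allclose(B.mean(axis=0), 0, atol=1e-8):
        raise ValueError("align_pair expects centered configurations")
    R = optimal_rotation(A, B)
    A_rot = A @ R
    angle = float(np.arctan2(R[0, 1], R[0, 0]))
    return angle, A_rot, float(np.linalg.norm(A_rot - B))


def procrustes_distance(A, B) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, then optimally
    rotated; the distance is the residual root-sum-of-squares. Zero iff the
    two configurations have the same shape; symmetric.
    """
    a = _center_scale(A)
    b = _center_scale(B)
    _, a_rot, resid = align_pair(a, b)
    return resid


def gpa(configs: Sequence, tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER) -> ProcrustesFit:
    """Generalized Procrustes analysis of >= 2 configurations.

    Iterates align-to-mean / re-average / rescale-mean-to-unit-size until the
    mean shape changes by less than ``tol`` (Frobenius norm). The first
    configuration initializes the consensus.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    arrays = [_as_array(c) for c in configs]
    k = arrays[0].shape[0]
    if any(a.shape != (k, 2) for a in arrays):
        raise ValueError("all configurations must share the same landmark count")
    labels = [c.population if isinstance(c, LandmarkConfiguration) else ""
              for c in configs]
    sizes = np.array([centroid_size(a) for a in arrays])
    X = np.stack([_center_scale(a) for a in arrays])  # (n, k, 2)
    mean = X[0].copy()
    converged = False
    it = 0
    change = np.inf
    ss_history: list[float] = []
    for it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ optimal_rotation(X[i], mean)
        ss_history.append(float(((X - mean) ** 2).sum()))
        new_mean = X.mean(axis=0)
        ncs = np.sqrt((new_mean ** 2).sum())
        if ncs <= 1e-15:
            raise DegenerateGeometryError("degenerate consensus: mean shape collapsed")
        new_mean /= ncs
        change = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})",
            last_change=change)
    # canonical orientation: principal axes of the consensus, so the result
    # does not depend on how the input batch happened to be oriented
    evals, V = np.linalg.eigh(mean.T @ mean)
    V = V[:, np.argsort(evals)[::-1]]
    if np.linalg.det(V) < 0:
        V[:, 1] *= -1.0
    mean = mean @ V
    flat = mean.ravel()
    if flat[np.argmax(np.abs(flat))] < 0:   # half-turn, still a rotation
        V = -V
        mean = -mean
    X = X @ V
    for i in range(len(X)):
        X[i] = X[i] @ optimal_rotation(X[i], mean)
    return ProcrustesFit(aligned=X, mean_shape=mean, centroid_sizes=sizes,
                         labels=labels, iterations=it, converged=True,
                         ss_history=ss_history)


def tangent_coordinates(fit: ProcrustesFit) -> np.ndarray:
    """Orthogonal projection of the aligned shapes onto the tangent space at
    the mean; returns an (n, 2k) coordinate table of rank <= 2k - 4.

    The mean shape itself projects to the zero vector.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    m = fit.mean_shape.ravel()          # unit norm by construction
    X = fit.aligned.reshape(fit.n, -1)
    return X - np.outer(X @ m, m)
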