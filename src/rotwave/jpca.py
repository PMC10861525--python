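"""jPCA: exact least-squares fit of skew-symmetric linear dynamics.

The method models preprocessed population activity as ``xdot = M x`` with
``M`` constrained to be skew-symmetric, so that ``x(t) = expm(M t) x(0)``
rotates without inflating or contracting.  Data are first reduced to ``k``
PCA dimensions (default 6); the constrained least-squares problem

    minimize || Xdot - X M^T ||_F   over  M = -M^T

is convex and solved exactly: the stationarity condition is the Lyapunov
equation ``A W + W A = B - B^T`` with ``A = X^T X``, ``B = X^T Xdot`` and
``W = M^T``, solved by a Sylvester solver rather than gradient descent.
Conditions are then projected onto the plane of the strongest rotation (the
eigenvalue pair of ``M`` with the largest |imaginary part|), producing the
familiar "sheaf" of co-rotating trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve_sylvester

from .dataset import PopulationDataset, StackedMatrix, stack_conditions

__all__ = ["JpcaResult", "fit_skew", "fit_unconstrained_r2", "evolve", "project",
           "mean_angular_velocity"]


@dataclass(frozen=True)
class JpcaResult:
    """Outcome of the skew-symmetric dynamics fit.

    ``M_skew`` is the generator in the reduced space (column convention:
    ``xdot = M_skew x``, exactly skew by construction).  ``pca_basis`` maps
    neurons to the reduced space, ``plane_basis`` maps the reduced space to
    the leading rotation plane, and ``projections`` holds each condition's
    2-D trajectory in that plane.
    """

    M_skew: np.ndarray               # (k, k), exactly skew-symmetric
    pca_basis: np.ndarray            # (n, k), orthonormal columns
    pca_mean: np.ndarray             # (n,), column means removed before PCA
    plane_basis: np.ndarray          # (k, 2), orthonormal columns
    projections: tuple[np.ndarray, ...]  # per-condition (t_l, 2) trajectories
    fit_r2: float                    # variance of Xdot explained by the fit
    frequencies: np.ndarray          # positive rotation frequencies, descending

    def ambient_generator(self) -> np.ndarray:
        """The fitted generator mapped back to neuron space (n x n)."""
        return self.pca_basis @ self.M_skew @ self.pca_basis.T

    def plane(self, index: int) -> np.ndarray:
        """Orthonormal basis (k, 2) of the ``index``-th rotation plane
        (0 = strongest)."""
        return _rotation_plane(self.M_skew, index)


def _rotation_plane(M: np.ndarray, index: int = 0) -> np.ndarray:
    """Real 2-D invariant subspace of the ``index``-th strongest eigenpair."""
    vals, vecs = np.linalg.eig(M)
    pos = np.flatnonzero(vals.imag > 0)
    if len(pos) <= index:
        raise ValueError(f"generator has only {len(pos)} rotation plane(s)")
    pos = pos[np.argsort(-vals.imag[pos], kind="stable")]
    v = vecs[:, pos[index]]
    basis, _ = np.linalg.qr(np.column_stack([v.real, v.imag]))
    return basis


def _block_gradient(sm_like: np.ndarray, boundaries, dt: float) -> np.ndarray:
    out = np.empty_like(sm_like)
    for s, e in boundaries:
        if e - s < 3:
            raise ValueError(f"condition block [{s}, {e}) has fewer than 3 time samples")
        out[s:e] = np.gradient(sm_like[s:e], dt, axis=0)
    return out


def fit_skew(sm: StackedMatrix, k: int = 6, center: bool = True) -> JpcaResult:
    """Fit skew-symmetric dynamics to stacked (already preprocessed) data.

    ``k`` is the even number of PCA dimensions retained before the fit;
    ``center=False`` skips mean removal (useful when the data are known to
    orbit the origin).  The returned plane is oriented so that the average
    signed angular velocity across conditions is counter-clockwise.
    """
    n = sm.X.shape[1]
    if k % 2 != 0 or not 2 <= k <= n:
        raise ValueError(f"k must be even and within [2, {n}]; got {k}")
    mean = sm.X.mean(axis=0) if center else np.zeros(n)
    Xc = sm.X - mean
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    if svals[k - 1] <= svals[0] * np.finfo(float).eps * max(Xc.shape):
        raise np.linalg.LinAlgError(
            f"data have numerical rank < k={k}; lower k or reduce smoothing"
        )
    basis = Vt[:k].T
    scores = Xc @ basis
    d_scores = _block_gradient(scores, sm.boundaries, sm.dt)

    A = scores.T @ scores
    B = scores.T @ d_scores
    W = solve_sylvester(A, A, B - B.T)
    W = 0.5 * (W - W.T)                       # exact skew-symmetry
    M = W.T                                   # column convention xdot = M x

    resid = d_scores - scores @ W
    r2 = 1.0 - np.linalg.norm(resid) ** 2 / np.linalg.norm(d_scores) ** 2

    plane = _rotation_plane(M, 0)
    projections = [scores[s:e] @ plane for s, e in sm.boundaries]
    winding = sum(
        float(np.sum(p[:-1, 0] * p[1:, 1] - p[1:, 0] * p[:-1, 1])) for p in projections
    )
    if winding < 0:                           # orient counter-clockwise on average
        plane = plane @ np.diag([1.0, -1.0])
        projections = [p @ np.diag([1.0, -1.0]) for p in projections]

    freqs = np.sort(np.abs(np.linalg.eigvals(M).imag))[::-1][0:k:2]
    return JpcaResult(
        M_skew=M,
        pca_basis=basis,
        pca_mean=mean,
        plane_basis=plane,
        projections=tuple(projections),
        fit_r2=float(r2),
        frequencies=freqs,
    )


def fit_unconstrained_r2(sm: StackedMatrix, k: int = 6, center: bool = True) -> float:
    """R^2 of the unconstrained least-squares dynamics fit (baseline).

    The skew-constrained optimum can never beat this value.
    """
    n = sm.X.shape[1]
    mean = sm.X.mean(axis=0) if center else np.zeros(n)
    Xc = sm.X - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ Vt[:k].T
    d_scores = _block_gradient(scores, sm.boundaries, sm.dt)
    W, *_ = np.linalg.lstsq(scores, d_scores, rcond=None)
    resid = d_scores - scores @ W
    return float(1.0 - np.linalg.norm(resid) ** 2 / np.linalg.norm(d_scores) ** 2)


def evolve(M_skew: np.ndarray, x0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Integrate ``xdot = M x`` exactly: rows are ``expm(M t) x0``.

    ``M_skew`` must be skew-symmetric, so the flow is orthogonal and the
    norm of the state is conserved.
    """
    M = np.asarray(M_skew, dtype=float)
    if not np.allclose(M, -M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
        raise ValueError("generator is not skew-symmetric")
    x0 = np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    return np.stack([expm(M * t) @ x0 for t in t_grid])


def project(ds: PopulationDataset, res: JpcaResult) -> tuple[np.ndarray, ...]:
    """Map each condition of ``ds`` through the fitted PCA basis and rotation
    plane; returns per-condition (t, 2) trajectories."""
    sm = stack_conditions(ds)
    if sm.X.shape[1] != res.pca_basis.shape[0]:
        raise ValueError(
            f"dataset has {sm.X.shape[1]} neurons but the fit used {res.pca_basis.shape[0]}"
        )
    scores = (sm.X - res.pca_mean) @ res.pca_basis
    return tuple(scores[s:e] @ res.plane_basis for s, e in sm.boundaries)


def mean_angular_velocity(traj: np.ndarray) -> float:
    """Average signed angular velocity (rad/sample) of a 2-D trajectory
    about the origin; positive = counter-clockwise."""
    traj = np.asarray(traj, dtype=float)
    a, b = traj[:-1], traj[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    angles = np.arctan2(cross, dot)
    return float(angles.mean())
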