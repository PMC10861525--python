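"""Curvature of high-dimensional trajectories.

For a curve ``x(t)`` in any ambient dimension the curvature is computed from
the velocity and acceleration alone,

    kappa = sqrt(|x'|^2 |x''|^2 - (x' . x'')^2) / |x'|^3,

which equals the classical cross-product formula in 3-D but needs no cross
product, so it works for hundreds of neurons.  ``kappa`` is the unsigned
curvature: 1/kappa is the radius of the osculating circle.  Derivatives are
numerical gradients along the trajectory (second-order central differences
in the interior, one-sided at the two boundary samples).

The module also measures how much PCA compression distorts a trajectory's
curvature profile: the mean absolute error between the profiles before and
after projection, with values clipped at a ceiling (default 1000) so a few
near-cusps do not dominate the average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "CurvatureProfile",
    "curvature_profile",
    "curvature_cross3d",
    "curvature_mae",
    "compress_pca",
]

#: Default ceiling applied before averaging curvature differences.
DEFAULT_CLIP = 1000.0


@dataclass(frozen=True)
class CurvatureProfile:
    """Per-time-sample curvature of one condition's trajectory.

    ``kappa`` has one value per time sample.  The first and last two samples
    are touched by one-sided gradient stencils (the acceleration is a
    gradient of a gradient) and are excluded from comparisons by default.
    Samples where the velocity vanishes are NaN (undefined, not zero).
    """

    kappa: np.ndarray
    dt_ms: float = 1.0

    @property
    def interior(self) -> np.ndarray:
        """Curvature where both derivatives use central differences only."""
        return self.kappa[2:-2]


def _gradients(traj: np.ndarray):
    vel = np.gradient(traj, axis=0)
    acc = np.gradient(vel, axis=0)
    return vel, acc


def curvature_profile(traj: np.ndarray, dt_ms: float = 1.0) -> CurvatureProfile:
    """Unsigned curvature along a ``(t, d)`` trajectory.

    Requires ``t >= 3`` samples and ``d >= 2`` ambient dimensions.  The
    result does not depend on the sampling step (curvature is invariant to
    time reparameterization); ``dt_ms`` is carried as metadata only.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2:
        raise ValueError("trajectory must be a (time, dimension) matrix")
    t, d = traj.shape
    if t < 3:
        raise ValueError(f"need at least 3 time samples; got {t}")
    if d < 2:
        raise ValueError(f"need ambient dimension >= 2; got {d}")
    vel, acc = _gradients(traj)
    v2 = np.einsum("ij,ij->i", vel, vel)
    a2 = np.einsum("ij,ij->i", acc, acc)
    va = np.einsum("ij,ij->i", vel, acc)
    gram = np.clip(v2 * a2 - va**2, 0.0, None)  # clamp tiny negative round-off
    still = v2 == 0
    if still.any():
        warnings.warn(
            f"{int(still.sum())} sample(s) have zero velocity; curvature undefined there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.sqrt(gram) / v2**1.5
    kappa[still] = np.nan
    return CurvatureProfile(kappa=kappa, dt_ms=dt_ms)


def curvature_cross3d(traj: np.ndarray, dt_ms: float = 1.0) -> CurvatureProfile:
    """Reference 3-D implementation via the explicit cross product.

    ``kappa = |x' x x''| / |x'|^3``; defined only for 3-D trajectories and
    used as an independent cross-check of :func:`curvature_profile`.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("cross-product curvature requires a (time, 3) trajectory")
    vel, acc = _gradients(traj)
    num = np.linalg.norm(np.cross(vel, acc), axis=1)
    v = np.linalg.norm(vel, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = num / v**3
    kappa[v == 0] = np.nan
    return CurvatureProfile(kappa=kappa, dt_ms=dt_ms)


def curvature_mae(
    original: CurvatureProfile,
    compressed: CurvatureProfile,
    clip: float = DEFAULT_CLIP,
    exclude_boundary: bool = True,
) -> float:
    """Mean absolute difference between two curvature profiles.

    Both profiles are clipped at ``clip`` before averaging; the two boundary
    samples at each end (one-sided gradient stencils) are excluded by
    default.  Samples undefined in either profile are ignored.
    """
    if not clip > 0:
        raise ValueError(f"clip must be positive; got {clip}")
    a, b = original.kappa, compressed.kappa
    if a.shape != b.shape:
        raise ValueError(f"profile lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if exclude_boundary:
        a, b = a[2:-2], b[2:-2]
    a = np.minimum(a, clip)
    b = np.minimum(b, clip)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no sample has a defined curvature in both profiles")
    return float(np.abs(a[ok] - b[ok]).mean())


def compress_pca(traj: np.ndarray, k: int) -> np.ndarray:
    """Project a ``(t, d)`` trajectory onto its top-``k`` principal axes.

    The trajectory is mean-centred first; with ``k = d`` the projection is an
    orthogonal change of basis and curvature is unchanged.
    """
    traj = np.asarray(traj, dtype=float)
    d = traj.shape[1]
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}]; got {k}")
    return PCA(n_components=k, svd_solver="full").fit_transform(traj)
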