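"""The gyration number: a model-free measure of structural rotation.

Stacking all conditions into one tall matrix ``X`` (rows = time, columns =
neurons) and differentiating in time block-wise gives the differential
covariance matrix ``X^T Xdot``.  If the population traces a consistent
rotation, this matrix is dominated by its skew-symmetric part and its
leading eigenvalues form a complex-conjugate pair.  Normalizing the real and
imaginary parts of that pair by the total spectral power gives two
coordinates in the unit square,

    x = (|Re l1| + |Re l2|) / sum_i |l_i|     (decay / stretch)
    y = (|Im l1| + |Im l2|) / sum_i |l_i|     (rotation)

the *gyration plane*.  Datasets above the main diagonal (y >= x) exhibit
structural rotations; the division is empirical.  An optional dominance
threshold additionally requires the leading pair to carry a minimum share
of the total power before calling a dataset rotational.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import PopulationDataset, StackedMatrix, stack_conditions
from .preprocess import PreprocessConfig, apply as _preprocess

__all__ = [
    "GyrationResult",
    "differential_covariance",
    "eigenspectrum",
    "gyration_number",
    "gyration_pipeline",
    "gyration_plane",
]

#: Relative tolerance used to decide that the two leading eigenvalues form a
#: complex-conjugate pair.
CONJUGATE_TOL = 1e-6


@dataclass(frozen=True)
class GyrationResult:
    """Eigenspectrum of the differential covariance matrix and the derived
    gyration-plane coordinates."""

    eigenvalues: np.ndarray          # complex, sorted by modulus descending
    x: float                         # decay coordinate, in [0, 1]
    y: float                         # rotation coordinate, in [0, 1]
    dominant_pair: tuple[complex, complex]
    pair_share: float                # (|l1| + |l2|) / sum |l_i|
    is_structural_rotation: bool
    dominance_threshold: float


def _block_gradient(sm: StackedMatrix) -> np.ndarray:
    """Time derivative of the stacked matrix, per condition block.

    Differencing never crosses a block boundary: conditions are distinct
    trials and a seam derivative would be spurious.
    """
    out = np.empty_like(sm.X)
    for s, e in sm.boundaries:
        if e - s < 3:
            raise ValueError(
                f"condition block [{s}, {e}) has fewer than 3 time samples"
            )
        out[s:e] = np.gradient(sm.X[s:e], sm.dt, axis=0)
    return out


def differential_covariance(sm: StackedMatrix, side: str = "neuron") -> np.ndarray:
    """``X^T Xdot`` (side="neuron", n x n) or ``Xdot X^T`` (side="time",
    ct x ct).

    The nonzero eigenvalues of the two products coincide, so analyses use
    whichever problem is smaller.  Skew-symmetry of this matrix is the
    algebraic signature of rotation.
    """
    dX = _block_gradient(sm)
    if side == "neuron":
        return sm.X.T @ dX
    if side == "time":
        return dX @ sm.X.T
    raise ValueError(f"side must be 'neuron' or 'time'; got {side!r}")


def eigenspectrum(M: np.ndarray) -> np.ndarray:
    """Full eigenvalue multiset of a square matrix, sorted by modulus
    descending (ties broken by descending real then imaginary part)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("eigenspectrum requires a square matrix")
    vals = np.linalg.eigvals(M)
    order = np.lexsort((-vals.imag, -vals.real, -np.abs(vals)))
    return vals[order]


def _dominant_pair(eigs: np.ndarray) -> tuple[complex, complex]:
    """First complex-conjugate pair by modulus, else the two largest."""
    l1 = eigs[0]
    if abs(l1.imag) > 0:
        for cand in eigs[1:]:
            if abs(cand - np.conj(l1)) <= CONJUGATE_TOL * abs(l1):
                return complex(l1), complex(cand)
    return complex(l1), complex(eigs[1])


def gyration_number(
    data: PopulationDataset | StackedMatrix,
    dominance_threshold: float = 0.0,
) -> GyrationResult:
    """Gyration-plane coordinates of a dataset.

    ``data`` is analysed as given; run :func:`rotwave.preprocess.apply` (or
    :func:`gyration_pipeline`) first to reproduce the standard chain.
    ``dominance_threshold`` is the minimum leading-pair power share required
    for the rotational classification (0 reduces the rule to the empirical
    main-diagonal test ``y >= x``).
    """
    sm = stack_conditions(data) if isinstance(data, PopulationDataset) else data
    n = sm.X.shape[1]
    side = "neuron" if n <= sm.X.shape[0] else "time"
    eigs = eigenspectrum(differential_covariance(sm, side=side))
    total = np.abs(eigs).sum()
    if total == 0:
        raise ValueError("differential covariance is identically zero (degenerate data)")
    l1, l2 = _dominant_pair(eigs)
    x = (abs(l1.real) + abs(l2.real)) / total
    y = (abs(l1.imag) + abs(l2.imag)) / total
    share = (abs(l1) + abs(l2)) / total
    return GyrationResult(
        eigenvalues=eigs,
        x=float(x),
        y=float(y),
        dominant_pair=(l1, l2),
        pair_share=float(share),
        is_structural_rotation=bool(y >= x and share >= dominance_threshold),
        dominance_threshold=float(dominance_threshold),
    )


def gyration_pipeline(
    ds: PopulationDataset,
    config: PreprocessConfig | None = PreprocessConfig(),
    dominance_threshold: float = 0.0,
) -> GyrationResult:
    """Standard preprocessing chain followed by :func:`gyration_number`.

    ``config=None`` analyses the raw rates.
    """
    if config is not None:
        ds = _preprocess(ds, config)
    return gyration_number(ds, dominance_threshold=dominance_threshold)


def gyration_plane(
    results: list[tuple[str, GyrationResult]],
    path: str | Path | None = None,
    insets: dict[str, np.ndarray] | None = None,
):
    """Scatter datasets on the unit square spanned by (decay, rotation).

    The main diagonal separating rotational from non-rotational datasets is
    drawn; ``insets`` may map labels to 2-D trajectories drawn as thumbnails
    next to the corresponding points.  Returns the figure.
    """
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("need at least one result to plot")
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot([0, 1], [0, 1], color="0.6", ls="--", lw=1, zorder=1)
    for label, res in results:
        color = "tab:green" if res.is_structural_rotation else "tab:red"
        ax.scatter([res.x], [res.y], color=color, zorder=3)
        ax.annotate(label, (res.x, res.y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
        if insets and label in insets:
            traj = np.asarray(insets[label])
            sub = ax.inset_axes([res.x + 0.02, res.y - 0.12, 0.14, 0.14],
                                transform=ax.transData)
            sub.plot(traj[:, 0], traj[:, 1], lw=0.8)
            sub.set_xticks([])
            sub.set_yticks([])
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("decay  x = (|Re $\\lambda_1$| + |Re $\\lambda_2$|) / $\\sum_i |\\lambda_i|$")
    ax.set_ylabel("rotation  y = (|Im $\\lambda_1$| + |Im $\\lambda_2$|) / $\\sum_i |\\lambda_i|$")
    ax.set_title("gyration plane")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
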