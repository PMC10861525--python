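"""Peri-event time histogram population images and peak sorting.

Stacking every neuron's across-condition average response and sorting rows
by peak time turns a sequence-like population pattern into a diagonal band -
the travelling wave.  The pipeline: per-neuron Min-Max normalization (pooled
over conditions and time), per-neuron peak time taken from the
across-condition average, stable sort of neurons by that peak time.  The
mean-subtracted per-condition images reuse the average ordering, so single
conditions can be inspected against the population sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import PopulationDataset

__all__ = ["PethImage", "build_peth", "render_peth"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PethImage:
    """Sorted population PETH.

    matrix
        ``(n, t)`` across-condition average of the Min-Max-normalized rates,
        rows in sorted order.
    order
        Permutation of original neuron indices: sorted row ``i`` is neuron
        ``order[i]``.
    peak_times
        Per-row time index of the average-response maximum (non-decreasing).
    per_condition
        ``(c, n, t)`` per-condition images after subtracting the
        across-condition mean, rows in the same sorted order.
    """

    matrix: np.ndarray
    order: np.ndarray
    peak_times: np.ndarray
    per_condition: np.ndarray
    dt_ms: float
    event_index: int | None = None


def build_peth(ds: PopulationDataset) -> PethImage:
    """Build the sorted population PETH of ``ds``.

    Constant neurons (zero pooled range) cannot be Min-Max normalized; they
    are mapped to all-zero rows and a warning is logged.
    """
    rates = ds.rates
    lo = rates.min(axis=(0, 1))
    rng = rates.max(axis=(0, 1)) - lo
    flat = rng == 0
    if flat.any():
        log.warning(
            "%d constant neuron(s) mapped to zero rows in the PETH", int(flat.sum())
        )
    safe = np.where(flat, 1.0, rng)
    norm = (rates - lo) / safe
    norm[:, :, flat] = 0.0

    average = norm.mean(axis=0)                       # (t, n)
    peaks = np.argmax(average, axis=0)                # first occurrence on plateaus
    order = np.argsort(peaks, kind="stable")          # ties keep original index order
    centered = norm - average[None]                   # across-condition mean removed
    return PethImage(
        matrix=average.T[order],
        order=order,
        peak_times=peaks[order],
        per_condition=np.transpose(centered, (0, 2, 1))[:, order],
        dt_ms=ds.dt_ms,
        event_index=ds.event_index,
    )


def render_peth(img: PethImage, condition: int | None = None, path: str | Path | None = None):
    """Heatmap of the sorted PETH (average, or one condition's centered image).

    Returns the matplotlib figure; saves it to ``path`` when given.
    """
    import matplotlib.pyplot as plt

    if condition is None:
        data, title = img.matrix, "average PETH (sorted by peak time)"
        cmap = "viridis"
    else:
        c = img.per_condition.shape[0]
        if not (0 <= condition < c):
            raise IndexError(f"condition {condition} out of range [0, {c})")
        data = img.per_condition[condition]
        title = f"condition {condition} (average sort order kept)"
        cmap = "RdBu_r"
    n, t = data.shape
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = (0.0, t * img.dt_ms, n - 0.5, -0.5)
    im = ax.imshow(data, aspect="auto", interpolation="nearest", cmap=cmap, extent=extent)
    if img.event_index is not None:
        ax.axvline(img.event_index * img.dt_ms, color="k", ls="--", lw=1, label="event")
        ax.legend(loc="upper right", frameon=False)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron (peak-sorted)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized rate")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
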