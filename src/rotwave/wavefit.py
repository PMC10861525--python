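"""Per-trajectory fits of the Gaussian travelling-wave response model.

Each neuron's response in each condition is fitted independently with
``A * exp(-((t - k) / sigma)**2)`` by nonlinear least squares, and the fit
quality is summarized by R^2.  High R^2 across a population whose fitted
peak times ``k`` increase linearly with peak-ordered neuron index is the
signature of a travelling wave.  The model has no baseline-offset term by
design, so data with a firing-rate floor will fit poorly - that is part of
the diagnosis, not a bug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dataset import PopulationDataset

__all__ = ["WaveFit", "fit_wave", "fit_dataset", "summarize_fits"]

_MAX_NFEV = 10_000


@dataclass(frozen=True)
class WaveFit:
    """One neuron-condition fit: parameters, R^2 and convergence flags."""

    amplitude: float
    peak_time: float
    width: float
    r2: float
    converged: bool
    degenerate: bool = False      # constant series: R^2 undefined


def _gauss(t, A, k, sigma):
    return A * np.exp(-(((t - k) / sigma) ** 2))


def _initial_guess(series: np.ndarray, t_grid: np.ndarray):
    i_max = int(np.argmax(series))
    A0 = float(series[i_max])
    k0 = float(t_grid[i_max])
    span = float(t_grid[-1] - t_grid[0])
    # half width at half maximum -> sigma; fallback to span/10
    above = series >= A0 / 2.0
    if A0 > 0 and above.sum() >= 2:
        width = float(t_grid[above][-1] - t_grid[above][0])
        s0 = max(width / (2.0 * math.sqrt(math.log(2.0))), span / 100.0)
    else:
        s0 = span / 10.0
    return A0 if A0 != 0 else 1.0, k0, s0


def fit_wave(series: np.ndarray, t_grid: np.ndarray) -> WaveFit:
    """Nonlinear least-squares fit of one response trace.

    Non-convergence is reported through the ``converged`` flag, never
    raised; a constant series is flagged degenerate with undefined R^2.
    """
    series = np.asarray(series, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if series.shape != t_grid.shape or series.ndim != 1:
        raise ValueError("series and t_grid must be matching 1-D arrays")
    if series.size < 4:
        raise ValueError("need at least 4 samples (more samples than parameters)")
    ss_tot = float(np.sum((series - series.mean()) ** 2))
    if ss_tot == 0:
        return WaveFit(math.nan, math.nan, math.nan, math.nan,
                       converged=False, degenerate=True)
    span = float(t_grid[-1] - t_grid[0])
    lower = [-np.inf, t_grid[0] - span / 2.0, np.finfo(float).tiny]
    upper = [np.inf, t_grid[-1] + span / 2.0, span]
    try:
        popt, _ = curve_fit(
            _gauss, t_grid, series,
            p0=_initial_guess(series, t_grid),
            bounds=(lower, upper),
            max_nfev=_MAX_NFEV,
        )
    except RuntimeError:
        return WaveFit(math.nan, math.nan, math.nan, math.nan,
                       converged=False, degenerate=False)
    ss_res = float(np.sum((series - _gauss(t_grid, *popt)) ** 2))
    return WaveFit(
        amplitude=float(popt[0]),
        peak_time=float(popt[1]),
        width=float(popt[2]),
        r2=1.0 - ss_res / ss_tot,
        converged=True,
    )


def fit_dataset(ds: PopulationDataset) -> pd.DataFrame:
    """Fit every (condition, neuron) trajectory of ``ds``.

    Returns a long table with one row per fit; degenerate or non-converged
    fits are recorded, not fatal.  The time grid is the dataset's own axis
    in ms.
    """
    t_grid = ds.time_ms
    rows = []
    for l in range(ds.n_conditions):
        for j in range(ds.n_neurons):
            fit = fit_wave(ds.rates[l, :, j], t_grid)
            rows.append({
                "condition": ds.condition_labels[l],
                "neuron": ds.neuron_ids[j],
                "neuron_index": j,
                "amplitude": fit.amplitude,
                "peak_time": fit.peak_time,
                "width": fit.width,
                "r2": fit.r2,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
            })
    return pd.DataFrame(rows)


def summarize_fits(table: pd.DataFrame) -> dict:
    """Quantiles of R^2 and convergence counts for a fit table."""
    r2 = table["r2"].dropna()
    return {
        "n_fits": int(len(table)),
        "n_converged": int(table["converged"].sum()),
        "n_degenerate": int(table["degenerate"].sum()),
        "frac_converged": float(table["converged"].mean()),
        "r2_median": float(r2.median()) if len(r2) else math.nan,
        "r2_q25": float(r2.quantile(0.25)) if len(r2) else math.nan,
        "r2_q75": float(r2.quantile(0.75)) if len(r2) else math.nan,
    }
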