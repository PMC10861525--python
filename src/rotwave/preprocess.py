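"""Standard preprocessing chain applied before any rotation analysis.

Order of the full chain (:func:`apply`): Gaussian smoothing along time ->
optional crop -> soft-normalization -> cross-condition mean subtraction.
Each step is also available on its own and returns a new dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataset import PopulationDataset

__all__ = [
    "PreprocessConfig",
    "smooth",
    "crop",
    "soft_normalize",
    "subtract_cc_mean",
    "apply",
]

#: Kernel support is truncated at +-4 standard deviations; boundaries are
#: handled by reflection so short windows are not attenuated at the edges.
_TRUNCATE = 4.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the standard chain.

    kernel_ms
        Std of the Gaussian smoothing kernel in ms (typical range 10-30;
        0 disables smoothing).
    soft_norm_const
        Additive constant of soft-normalization: each neuron is divided by
        its pooled response range plus this constant.  The conventional
        default is 5 (spikes/s).
    crop
        Optional half-open time-index interval ``(start, end)``.
    subtract_cc_mean
        Whether to subtract the across-condition mean at every
        (time, neuron) point.
    """

    kernel_ms: float = 20.0
    soft_norm_const: float = 5.0
    crop: tuple[int, int] | None = None
    subtract_cc_mean: bool = True


def smooth(ds: PopulationDataset, kernel_ms: float) -> PopulationDataset:
    """Convolve every (condition, neuron) series with a unit-area Gaussian.

    ``kernel_ms`` is the kernel std in milliseconds; 0 returns the input
    unchanged.
    """
    if kernel_ms < 0:
        raise ValueError(f"kernel_ms must be >= 0; got {kernel_ms}")
    if kernel_ms == 0:
        return ds
    sigma_samples = kernel_ms / ds.dt_ms
    smoothed = gaussian_filter1d(
        ds.rates, sigma_samples, axis=1, mode="reflect", truncate=_TRUNCATE
    )
    return ds.with_rates(smoothed)


def crop(ds: PopulationDataset, start: int, end: int) -> PopulationDataset:
    """Keep the half-open time interval ``[start, end)``."""
    t = ds.n_time
    if not (0 <= start < end <= t):
        raise ValueError(f"crop [{start}, {end}) outside the time range [0, {t})")
    event = ds.event_index
    if event is not None:
        event = event - start if start <= event < end else None
    return PopulationDataset(
        ds.rates[:, start:end],
        ds.dt_ms,
        event_index=event,
        condition_labels=ds.condition_labels,
        neuron_ids=ds.neuron_ids,
    )


def soft_normalize(ds: PopulationDataset, const: float = 5.0) -> PopulationDataset:
    """Divide each neuron by its response range (pooled over conditions and
    time) plus ``const``.

    A large constant leaves low-rate neurons quiet instead of inflating
    them; ``const = 0`` is exact range normalization and requires every
    neuron to be non-constant.
    """
    if const < 0:
        raise ValueError(f"soft-normalization constant must be >= 0; got {const}")
    ranges = ds.rates.max(axis=(0, 1)) - ds.rates.min(axis=(0, 1))
    if const == 0 and np.any(ranges == 0):
        j = int(np.flatnonzero(ranges == 0)[0])
        raise ValueError(
            f"neuron {j} is constant; soft-normalization with const=0 would divide by zero"
        )
    return ds.with_rates(ds.rates / (ranges + const))


def subtract_cc_mean(ds: PopulationDataset) -> PopulationDataset:
    """Subtract the across-condition mean at every (time, neuron) point.

    Idempotent linear projection; with a single condition the result is
    identically zero.
    """
    return ds.with_rates(ds.rates - ds.rates.mean(axis=0, keepdims=True))


def apply(ds: PopulationDataset, config: PreprocessConfig = PreprocessConfig()) -> PopulationDataset:
    """Run the full chain on ``ds`` in the standard order."""
    out = smooth(ds, config.kernel_ms)
    if config.crop is not None:
        out = crop(out, *config.crop)
    out = soft_normalize(out, config.soft_norm_const)
    if config.subtract_cc_mean:
        out = subtract_cc_mean(out)
    return out
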