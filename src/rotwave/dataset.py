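"""Containers for condition-structured firing-rate data.

Axis convention, used everywhere in this package: rate tensors are indexed
``(condition, time, neuron)`` and stacked matrices have rows = time samples,
columns = neurons.  Sampling is on a uniform grid with step ``dt_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = ["PopulationDataset", "StackedMatrix", "stack_conditions", "unstack_conditions"]


@dataclass(frozen=True)
class PopulationDataset:
    """Trial-averaged firing rates for ``c`` conditions, ``t`` time samples
    and ``n`` neurons.

    Parameters
    ----------
    rates
        Real tensor of shape ``(c, t, n)`` in spikes/s or normalized units.
    dt_ms
        Positive sampling step in milliseconds (uniform grid only).
    event_index
        Optional time index of the alignment event (e.g. the go cue); used
        for plot annotation only.
    condition_labels, neuron_ids
        Identifiers matching the tensor dimensions; generated if omitted.
    """

    rates: np.ndarray
    dt_ms: float
    event_index: int | None = None
    condition_labels: tuple[str, ...] = field(default=())
    neuron_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 3:
            raise ValidationError(
                f"rates must have shape (conditions, time, neurons); got ndim={rates.ndim}"
            )
        c, t, n = rates.shape
        if c < 1 or t < 3 or n < 2:
            raise ValidationError(
                "need c >= 1 conditions, t >= 3 time samples and n >= 2 neurons; "
                f"got shape {rates.shape}"
            )
        bad = ~np.isfinite(rates)
        if bad.any():
            ci, ti, ni = (int(v) for v in np.argwhere(bad)[0])
            raise ValidationError(
                f"rates contain a non-finite value at (condition={ci}, time={ti}, neuron={ni})"
            )
        if not float(self.dt_ms) > 0:
            raise ValidationError(f"dt_ms must be positive; got {self.dt_ms}")
        if self.event_index is not None and not (0 <= int(self.event_index) < t):
            raise ValidationError(
                f"event_index {self.event_index} outside the time range [0, {t})"
            )
        labels = tuple(self.condition_labels) or tuple(f"cond{i}" for i in range(c))
        ids = tuple(self.neuron_ids) or tuple(f"n{j:03d}" for j in range(n))
        if len(labels) != c:
            raise ValidationError(
                f"{len(labels)} condition labels for {c} conditions"
            )
        if len(ids) != n:
            raise ValidationError(f"{len(ids)} neuron ids for {n} neurons")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "dt_ms", float(self.dt_ms))
        object.__setattr__(self, "condition_labels", labels)
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_conditions(self) -> int:
        return self.rates.shape[0]

    @property
    def n_time(self) -> int:
        return self.rates.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[2]

    @property
    def time_ms(self) -> np.ndarray:
        """Time axis in ms, origin at sample 0."""
        return np.arange(self.n_time) * self.dt_ms

    def with_rates(self, rates: np.ndarray) -> "PopulationDataset":
        """A copy carrying new rate values (same metadata)."""
        return replace(self, rates=rates)


@dataclass(frozen=True)
class StackedMatrix:
    """Conditions stacked on top of each other: shape ``(c*t, n)``.

    ``boundaries`` records the half-open row range of each condition block in
    condition order; ``dt`` is the time step between consecutive rows within
    a block (ms).
    """

    X: np.ndarray
    boundaries: tuple[tuple[int, int], ...]
    dt: float = 1.0

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValidationError(f"stacked matrix must be 2-D; got ndim={X.ndim}")
        bounds = tuple((int(s), int(e)) for s, e in self.boundaries)
        pos = 0
        for s, e in bounds:
            if s != pos or e <= s:
                raise ValidationError(
                    f"condition blocks must be ordered, disjoint and non-empty; got {bounds}"
                )
            pos = e
        if pos != X.shape[0]:
            raise ValidationError(
                f"blocks cover {pos} rows but the matrix has {X.shape[0]}"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "boundaries", bounds)
        object.__setattr__(self, "dt", float(self.dt))

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)

    def blocks(self):
        """Iterate over per-condition row blocks (views)."""
        for s, e in self.boundaries:
            yield self.X[s:e]


def stack_conditions(ds: PopulationDataset) -> StackedMatrix:
    """Stack the condition slices of ``ds`` into one tall matrix.

    Block ``l`` of the output equals ``ds.rates[l]``; rows are time samples,
    columns neurons.
    """
    c, t, n = ds.rates.shape
    X = ds.rates.reshape(c * t, n)
    bounds = tuple((l * t, (l + 1) * t) for l in range(c))
    return StackedMatrix(X=X, boundaries=bounds, dt=ds.dt_ms)


def unstack_conditions(sm: StackedMatrix) -> np.ndarray:
    """Inverse of :func:`stack_conditions` for equal-length blocks.

    Returns the ``(c, t, n)`` tensor.
    """
    lengths = {e - s for s, e in sm.boundaries}
    if len(lengths) != 1:
        raise ValidationError("blocks have unequal lengths; cannot form a tensor")
    t = lengths.pop()
    return sm.X.reshape(sm.n_blocks, t, sm.X.shape[1])
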