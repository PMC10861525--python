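"""Shuffling controls that degrade structural rotation.

Shuffles inject intra-condition variation while preserving the marginal
content of the data, so a drop in the gyration rotation coordinate after
shuffling shows that the measure responds to cross-condition structure, not
to per-neuron response shapes.  The three procedures here are approximate
reconstructions of the controls used in the rotational-dynamics literature:

condition_swap
    Independently for each neuron, permute which condition each of its
    traces belongs to (per-neuron trace multiset preserved exactly).
time_reverse_half
    Reverse the time axis of a random half of the neurons, in every
    condition.
neuron_condition_permute
    Independently for each neuron, draw each condition's trace from a
    random condition *with replacement*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import PopulationDataset

__all__ = ["ShuffleSpec", "SHUFFLE_KINDS", "shuffle"]

SHUFFLE_KINDS = ("condition_swap", "time_reverse_half", "neuron_condition_permute")


@dataclass(frozen=True)
class ShuffleSpec:
    """Which registered shuffle to run, and the seed making it repeatable."""

    kind: str
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in SHUFFLE_KINDS:
            raise ValueError(
                f"unknown shuffle kind {self.kind!r}; choose from {SHUFFLE_KINDS}"
            )


def shuffle(ds: PopulationDataset, spec: ShuffleSpec) -> PopulationDataset:
    """Apply one shuffling procedure; identical spec => identical output."""
    spec.validate()
    c, t, n = ds.rates.shape
    if spec.kind in ("condition_swap", "neuron_condition_permute") and c < 2:
        raise ValueError(f"{spec.kind} needs at least 2 conditions; got {c}")
    rng = np.random.default_rng(spec.seed)
    out = ds.rates.copy()
    if spec.kind == "condition_swap":
        for j in range(n):
            out[:, :, j] = ds.rates[rng.permutation(c), :, j]
    elif spec.kind == "time_reverse_half":
        half = rng.choice(n, n // 2, replace=False)
        out[:, :, half] = ds.rates[:, ::-1, half]
    else:  # neuron_condition_permute
        for j in range(n):
            out[:, :, j] = ds.rates[rng.integers(0, c, size=c), :, j]
    return ds.with_rates(out)
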