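"""Parameterized travelling-wave generator for synthetic population data.

The model represents each neuron's trial-averaged response as a Gaussian
bump in time,

    f(k, t, sigma) = exp(-((t - k) / sigma)**2),

whose peak time is a linear function of the neuron's position in the
peak-ordered population, ``k(j, a, b) = b*j + a``.  ``b`` (the wave incline,
in samples per neuron index) sets how fast the bump sweeps through the
population and ``a`` shifts the whole wave in time.  A multi-condition
dataset scales the wave by a per-condition amplitude ``A_l`` and perturbs
amplitude, phase and width with per-(condition, neuron) noise:

    rate[l, t, j] = (A_l + eps_A) * exp(-((t - (b*j + a + eps_k))
                                          / (sigma + eps_sigma))**2)

with ``eps_A ~ N(0, sigma_A)``, ``eps_k ~ N(0, sigma_k)`` and
``eps_sigma ~ U(0, sigma_sigma)``.  Noise perturbs wave *parameters*, not
individual samples, so each trace stays smooth.

Default parameters follow the reference synthetic conditions: 8 conditions,
200 neurons, amplitudes evenly spaced in [0.5, 1.0], and a wave that starts
at the window corner (``a = 0``) so that its leading edge is clipped - the
clipping is what gives the decay (real) component of the gyration number
something to measure; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import PopulationDataset

__all__ = ["WaveModelParams", "gaussian_wave", "phase", "generate_dataset"]


@dataclass(frozen=True)
class WaveModelParams:
    """Generative parameters of the multi-condition travelling-wave model.

    ``a``, ``b``, ``sigma`` and the noise scales are expressed in time-sample
    units (the generated dataset uses ``dt_ms = 1``).
    """

    n_neurons: int = 200
    n_time: int = 200
    n_conditions: int = 8
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    a: float = 0.0
    b: float = 1.0
    sigma: float = 10.0
    eps_A: float = 0.0
    eps_k: float = 0.0
    eps_sigma: float = 0.0
    random_amplitudes: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if self.n_time < 3:
            raise ValueError("need at least 3 time samples")
        if self.n_conditions < 1:
            raise ValueError("need at least 1 condition")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")
        lo, hi = self.amplitude_range
        if lo > hi:
            raise ValueError(f"amplitude_range min {lo} exceeds max {hi}")
        for name in ("eps_A", "eps_k", "eps_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gaussian_wave(k: float, t_grid: np.ndarray, sigma: float) -> np.ndarray:
    """Unit-amplitude Gaussian bump peaking at time ``k`` with width ``sigma``."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive; got {sigma}")
    t_grid = np.asarray(t_grid, dtype=float)
    return np.exp(-(((t_grid - k) / sigma) ** 2))


def phase(j, a: float, b: float):
    """Peak time ``b*j + a`` of neuron ``j`` in the ordered population."""
    return b * np.asarray(j, dtype=float) + a


def generate_dataset(params: WaveModelParams) -> PopulationDataset:
    """Draw one synthetic dataset from the travelling-wave model.

    The same ``params`` (including ``seed``) always produce a bit-identical
    tensor; with all noise scales at zero the output is deterministic and
    independent of the seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    c, t, n = params.n_conditions, params.n_time, params.n_neurons
    lo, hi = params.amplitude_range
    if params.random_amplitudes:
        amplitudes = rng.uniform(lo, hi, size=c)
    elif c == 1:
        amplitudes = np.array([hi])
    else:
        amplitudes = np.linspace(lo, hi, c)
    t_grid = np.arange(t, dtype=float)
    j = np.arange(n, dtype=float)
    centers0 = phase(j, params.a, params.b)

    rates = np.empty((c, t, n))
    for l in range(c):
        # one draw per (condition, neuron): noise perturbs wave parameters
        eps_A = rng.normal(0.0, params.eps_A, size=n) if params.eps_A > 0 else np.zeros(n)
        eps_k = rng.normal(0.0, params.eps_k, size=n) if params.eps_k > 0 else np.zeros(n)
        eps_s = rng.uniform(0.0, params.eps_sigma, size=n) if params.eps_sigma > 0 else np.zeros(n)
        centers = centers0 + eps_k
        widths = params.sigma + eps_s
        rates[l] = (amplitudes[l] + eps_A) * np.exp(
            -(((t_grid[:, None] - centers[None, :]) / widths[None, :]) ** 2)
        )
    return PopulationDataset(
        rates,
        dt_ms=1.0,
        condition_labels=tuple(f"cond{l}" for l in range(c)),
        neuron_ids=tuple(f"n{jj:03d}" for jj in range(n)),
    )
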