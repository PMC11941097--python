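"""Stochastic input currents: additive white, input-scaled multiplicative, OU colored.

All three noise processes inject current (pA) into the two *input* neurons
only, resampled every ``resample_dt`` (default 0.1 ms, the simulation
resolution).  ``D`` is the standard deviation of the underlying Gaussian
draw in every family, so families are compared "at equal D":

* ``additive_white`` — an i.i.d. draw from N(0, D^2) each step;
* ``multiplicative_white`` — the same draw scaled by the instantaneous
  signal drive of that input (input gain x signal), modelling synaptic
  transmission variability: strong inputs get proportionally strong noise
  and a silent input gets none;
* ``ou_colored`` — an Ornstein–Uhlenbeck process, mean-reverting to 0 at
  rate ``theta`` (1/ms), giving temporally correlated noise whose
  autocorrelation decays as exp(-theta * lag).

In ``common`` mode a single draw is applied to both inputs each step
(bit-identical values); ``independent`` mode draws separately per input
from the same distribution.

The OU recursion is the Euler step ``z' = z - theta * z * dt + w`` with a
per-step innovation ``w ~ N(0, D^2)`` by default, so the per-step kick has
SD exactly D in every family; the diffusion-style ``sqrt(dt)``-scaled
innovation is available via ``sqrt_dt_innovation``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "NoiseSpec",
    "sample_white",
    "step_ou",
    "noise_currents",
    "generate_noise_currents",
]

_FAMILIES = ("additive_white", "multiplicative_white", "ou_colored")
_MODES = ("common", "independent")


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of the noise process applied to the two input neurons.

    ``D`` is in pA for the additive families and a dimensionless scale for
    the multiplicative family.  ``theta`` (1/ms) is used only by
    ``ou_colored``.
    """

    family: str = "additive_white"
    D: float = 0.0
    theta: float = 1.0
    mode: str = "common"
    seed: int | None = None
    resample_dt: float = 0.1     # ms
    sqrt_dt_innovation: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.family == "ou_colored" and self.theta <= 0:
            raise ValueError("theta must be positive for OU noise")
        if self.resample_dt <= 0:
            raise ValueError("resample_dt must be positive")


def sample_white(D: float, rng: np.random.Generator) -> float:
    """One draw from N(0, D^2); D = 0 degenerates to exactly 0."""
    if D < 0:
        raise ValueError("D must be non-negative")
    if D == 0:
        return 0.0
    return float(rng.normal(0.0, D))


def step_ou(z: float, spec: NoiseSpec, dt: float, rng: np.random.Generator) -> float:
    """Advance the OU state by one step: z' = z + theta * (0 - z) * dt + innovation."""
    if spec.theta <= 0:
        raise ValueError("theta must be positive")
    sd = spec.D * (np.sqrt(dt) if spec.sqrt_dt_innovation else 1.0)
    innovation = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
    return z - spec.theta * z * dt + innovation


def noise_currents(
    spec: NoiseSpec,
    inputs: tuple[float, float],
    rng: np.random.Generator,
    ou_state: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """One step of noise current for the two input neurons.

    ``inputs`` are the signal drives (pA) of the two inputs, used only by
    the multiplicative family.  For ``ou_colored`` the returned pair is the
    advanced OU state given ``ou_state`` (the caller carries the state; see
    :func:`generate_noise_currents` for whole traces).  In ``common`` mode
    both entries come from one draw and are bit-identical for the additive
    families.
    """
    if spec.family == "ou_colored":
        z0 = step_ou(ou_state[0], spec, spec.resample_dt, rng)
        if spec.mode == "common":
            return z0, z0
        z1 = step_ou(ou_state[1], spec, spec.resample_dt, rng)
        return z0, z1

    xi0 = sample_white(spec.D, rng)
    xi1 = xi0 if spec.mode == "common" else sample_white(spec.D, rng)
    if spec.family == "multiplicative_white":
        return inputs[0] * xi0, inputs[1] * xi1
    return xi0, xi1


def _ou_trace(n_steps: int, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Full OU trace from z(0) = 0 via the linear recursion (vectorized)."""
    dt = spec.resample_dt
    sd = spec.D * (np.sqrt(dt) if spec.sqrt_dt_innovation else 1.0)
    w = rng.normal(0.0, sd, n_steps) if sd > 0 else np.zeros(n_steps)
    a = 1.0 - spec.theta * dt
    # z_t = a * z_{t-1} + w_t  <=>  IIR filter with denominator (1, -a)
    return lfilter([1.0], [1.0, -a], w)


def generate_noise_currents(
    spec: NoiseSpec,
    drives: tuple[float, float],
    n_steps: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Precompute the full (n_steps, 2) noise-current series for one run.

    ``drives`` are the constant signal drives (pA) of the two input neurons
    over the run; they scale the multiplicative family and are ignored by
    the additive ones.  Draw order matches the scalar single-step API, so a
    trace generated here is bit-identical to stepping
    :func:`noise_currents` with the same seeded generator.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    out = np.empty((n_steps, 2))
    if spec.family == "ou_colored":
        if spec.mode == "common":
            z = _ou_trace(n_steps, spec, rng)
            out[:, 0] = z
            out[:, 1] = z
        else:
            # scalar API draws z0 then z1 within each step: interleaved order
            dt = spec.resample_dt
            sd = spec.D * (np.sqrt(dt) if spec.sqrt_dt_innovation else 1.0)
            w = rng.normal(0.0, sd, (n_steps, 2)) if sd > 0 else np.zeros((n_steps, 2))
            a = 1.0 - spec.theta * dt
            out[:, 0] = lfilter([1.0], [1.0, -a], w[:, 0])
            out[:, 1] = lfilter([1.0], [1.0, -a], w[:, 1])
        return out

    if spec.mode == "common":
        xi = rng.normal(0.0, spec.D, n_steps) if spec.D > 0 else np.zeros(n_steps)
        xi = np.column_stack([xi, xi])
    else:
        xi = rng.normal(0.0, spec.D, (n_steps, 2)) if spec.D > 0 else np.zeros((n_steps, 2))
    if spec.family == "multiplicative_white":
        xi = xi * np.asarray(drives, dtype=float)
    out[:] = xi
    return out
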