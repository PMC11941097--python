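"""Integrate-and-fire point neurons with exponential postsynaptic currents.

The membrane potential of the leaky neuron obeys

    tau_m * dV/dt = -(V - E_L) + I_total(t)

where ``I_total`` collects the constant bias, synaptic and noise currents.
Currents are expressed in pA under the unit convention that the implied
membrane resistance is 1 GOhm (C_m = 10 pF, tau_m = 10 ms), so 1 pA of
sustained current depolarizes the membrane asymptotically by 1 mV.  Within
one simulation step the drive is held constant and the linear ODE is
advanced with its exact exponential propagator, which keeps spike timing
robust to the step size.  The non-leaky variant drops the decay term and
integrates the drive directly.

A spike is emitted when V crosses ``V_th`` from below; the membrane is then
clamped to ``V_reset`` for the refractory period ``t_ref``.  Synaptic and
noise input is *not* discarded while refractory — postsynaptic currents keep
evolving — only the membrane is frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["NeuronParams", "NeuronState", "step_neuron", "free_decay", "run_neuron_train"]


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one integrate-and-fire neuron.

    Defaults are the parameter set used throughout the circuit study:
    a 10 pF / 10 ms membrane resting at 0 mV, threshold 20 mV, reset
    16 mV, and a constant 18 pA bias current that places the resting
    drive 2 mV below threshold (the sub-threshold substrate that noise
    can push over the edge).
    """

    C_m: float = 10.0            # membrane capacitance, pF
    tau_m: float = 10.0          # membrane time constant, ms
    E_L: float = 0.0             # resting potential, mV
    V_reset: float = 16.0        # post-spike reset potential, mV
    V_th: float = 20.0           # spike threshold, mV
    V_min: float = -1.798e308    # lower clamp on V_m, mV
    I_e: float = 18.0            # constant bias current, pA
    t_ref: float = 2.0           # absolute refractory period, ms
    leaky: bool = True
    refractory_input_discarded: bool = False

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_th:
            raise ValueError(f"V_reset ({self.V_reset}) must be below V_th ({self.V_th})")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.V_min > self.V_reset:
            raise ValueError("V_min must not exceed V_reset")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass(frozen=True)
class NeuronState:
    """Evolving variables of one neuron."""

    V_m: float = 0.0                  # membrane potential, mV
    refractory_remaining: float = 0.0  # ms
    spike_count: int = 0

    def __post_init__(self) -> None:
        if self.refractory_remaining < 0:
            raise ValueError("refractory_remaining must be non-negative")
        if self.spike_count < 0:
            raise ValueError("spike_count must be non-negative")


def free_decay(V: float, params: NeuronParams, dt: float) -> float:
    """Relax the membrane toward rest with no input over ``dt`` ms.

    Returns ``E_L + (V - E_L) * exp(-dt / tau_m)``; only meaningful for the
    leaky neuron.
    """
    if not params.leaky:
        raise ValueError("free_decay is defined for the leaky neuron only")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return params.E_L + (V - params.E_L) * math.exp(-dt / params.tau_m)


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    I_syn: float,
    I_noise: float,
    dt: float,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one step of ``dt`` ms.

    The total drive ``I_e + I_syn + I_noise`` (pA, mapped 1:1 to mV of
    asymptotic depolarization) is held constant during the step.  While
    refractory, V stays clamped at ``V_reset`` and the refractory clock
    counts down; input currents are not integrated into V but are free to
    keep evolving elsewhere (PSC state is owned by the synapses).

    Returns the new state and whether a spike was emitted this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I_total = params.I_e + I_syn + I_noise
    if not math.isfinite(I_total):
        raise ValueError("input currents must be finite")

    # tolerance absorbs float accumulation so t_ref spans exactly round(t_ref/dt) steps
    if state.refractory_remaining > 1e-9:
        remaining = max(state.refractory_remaining - dt, 0.0)
        return replace(state, V_m=params.V_reset, refractory_remaining=remaining), False

    if params.leaky:
        decay = math.exp(-dt / params.tau_m)
        V = params.E_L + (state.V_m - params.E_L) * decay + I_total * (1.0 - decay)
    else:
        V = state.V_m + I_total * dt / params.tau_m
    V = max(V, params.V_min)

    if V >= params.V_th:
        new = NeuronState(
            V_m=params.V_reset,
            refractory_remaining=params.t_ref,
            spike_count=state.spike_count + 1,
        )
        return new, True
    return replace(state, V_m=V), False


def run_neuron_train(
    params: NeuronParams,
    drive_series: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Run one neuron against a per-step drive series; return spike times (ms).

    ``drive_series[k]`` is the *total* injected current (pA) during step k,
    bias included — ``params.I_e`` is ignored here so that a constant series
    of 18 pA reproduces the sub-threshold resting drive exactly.  A spike
    occurring on step k is stamped at time ``(k + 1) * dt``, the end of the
    step on which threshold was crossed.  Deterministic given the series.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drive = np.asarray(drive_series, dtype=float)
    if drive.size and not np.all(np.isfinite(drive)):
        raise ValueError("drive series must be finite")

    p = replace(params, I_e=0.0)
    state = NeuronState(V_m=params.E_L)
    times = []
    for k in range(drive.size):
        state, spiked = step_neuron(state, p, float(drive[k]), 0.0, dt)
        if spiked:
            times.append((k + 1) * dt)
    return np.asarray(times, dtype=float)
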