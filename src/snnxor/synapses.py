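"""Static and Tsodyks–Markram (short-term plasticity) synapses.

Every synapse injects an exponentially decaying postsynaptic current (PSC)
with time constant ``tau_syn``.  A *static* synapse adds its full weight to
the PSC on every presynaptic spike.  A *dynamical* synapse modulates the
released amplitude through two activity-dependent variables:

* ``u`` — utilization (release probability), facilitating: each spike jumps
  ``u -> u + U * (1 - u)`` and ``u`` relaxes back to 0 with ``tau_fac``;
* ``x`` — available resources, depressing: each spike releases the fraction
  ``r = u * x`` (facilitation jump applied first), depletes ``x -> x - r``,
  and ``x`` recovers toward 1 with ``tau_rec``.

The PSC increment is ``weight * r``, so sustained presynaptic firing
depresses transmission (at the default tau_rec = 10 ms >> tau_fac = 1 ms)
while isolated spikes transmit near U * weight.  This is the two-state
reduction of the classic resource model: ``x`` is the recovered fraction and
``1 - x`` the not-yet-recovered remainder, so the resource fractions always
partition unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseState",
    "decay_psc",
    "on_presynaptic_spike",
    "release_sequence",
    "tm_steady_state_release",
]


@dataclass(frozen=True)
class SynapseParams:
    """Constants of one synapse.

    ``weight`` is the signed PSC amplitude in pA (negative for inhibitory
    connections); defaults for the dynamical kind are facilitation 1 ms,
    recovery 10 ms, PSC decay 1 ms, baseline utilization U = 0.5.
    """

    weight: float = 1.0
    kind: str = "dynamical"      # "static" | "dynamical"
    U: float = 0.5               # baseline utilization, dimensionless
    tau_fac: float = 1.0         # facilitation time constant, ms
    tau_rec: float = 10.0        # resource recovery time constant, ms
    tau_syn: float = 1.0         # PSC decay time constant, ms

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamical"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")
        if self.tau_fac <= 0:
            raise ValueError("tau_fac must be positive")
        if not 0.0 <= self.U <= 1.0:
            raise ValueError("U must lie in [0, 1]")


@dataclass(frozen=True)
class SynapseState:
    """Evolving variables of one synapse: utilization, resources, PSC."""

    u: float = 0.0       # current utilization, [0, 1]
    x: float = 1.0       # available resources, [0, 1]
    I_psc: float = 0.0   # postsynaptic current, pA (signed)

    def __post_init__(self) -> None:
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("u must lie in [0, 1]")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x must lie in [0, 1]")


def decay_psc(state: SynapseState, params: SynapseParams, dt: float) -> SynapseState:
    """Relax the synapse over ``dt`` ms with no presynaptic spike.

    The PSC decays with ``tau_syn``; for the dynamical kind, utilization
    relaxes toward 0 with ``tau_fac`` and resources recover toward 1 with
    ``tau_rec``.  ``dt = 0`` is the identity.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    I = state.I_psc * math.exp(-dt / params.tau_syn)
    if params.kind == "static":
        return replace(state, I_psc=I)
    u = state.u * math.exp(-dt / params.tau_fac)
    x = 1.0 - (1.0 - state.x) * math.exp(-dt / params.tau_rec)
    return SynapseState(u=u, x=x, I_psc=I)


def on_presynaptic_spike(state: SynapseState, params: SynapseParams) -> SynapseState:
    """Apply one presynaptic spike.

    Dynamical kind: facilitation jump first (``u += U * (1 - u)``), then
    release ``r = u * x``, deplete resources and add ``weight * r`` to the
    PSC.  Static kind: add the full weight, state variables untouched.
    """
    if params.kind == "static":
        return replace(state, I_psc=state.I_psc + params.weight)
    u = state.u + params.U * (1.0 - state.u)
    r = u * state.x
    return SynapseState(u=u, x=state.x - r, I_psc=state.I_psc + params.weight * r)


def release_sequence(spike_times: np.ndarray, params: SynapseParams) -> np.ndarray:
    """Released fraction per spike of a presynaptic train (exact between-spike relaxation).

    For a static synapse every release is 1 (the full weight).  For the
    dynamical kind the sequence exposes short-term depression: with
    ``tau_rec`` much longer than the inter-spike interval it is
    non-increasing after the first spike.

    Parameters
    ----------
    spike_times : sorted spike times in ms.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted ascending")
    if params.kind == "static":
        return np.ones(t.size)
    state = SynapseState()
    out = np.empty(t.size)
    prev = None
    for i, ti in enumerate(t):
        if prev is not None:
            state = decay_psc(state, params, ti - prev)
        x_before = state.x
        state = on_presynaptic_spike(state, params)
        out[i] = x_before - state.x  # released fraction r = u+ * x
        prev = ti
    return out


def tm_steady_state_release(interval: float, params: SynapseParams,
                            tol: float = 1e-12, max_iter: int = 100_000) -> float:
    """Fixed point of the per-interval utilization/resource map under a regular train.

    Iterates the discrete map (relax over ``interval`` ms, spike) until the
    released fraction changes by less than ``tol``.  Serves as an
    independent check on long simulated trains.
    """
    state = SynapseState()
    last = None
    for _ in range(max_iter):
        after = on_presynaptic_spike(state, params)
        r = state.x - after.x
        if last is not None and abs(r - last) < tol:
            return r
        last = r
        state = decay_psc(after, params, interval)
    return last
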