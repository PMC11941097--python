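"""Compiled clock-driven stepping kernels for the 5-neuron circuit.

These kernels duplicate, for speed, the scalar reference semantics of
:mod:`snnxor.neurons` and :mod:`snnxor.synapses` (a cross-check test holds
the two routes to exact agreement):

* per step, each neuron advances with the exact exponential propagator (or
  plain integration for the non-leaky variant) under the drive held
  constant over the step;
* spikes detected this step update the synapses *after* the PSC decay, so a
  spike influences postsynaptic currents from the next step on — a one-step
  (0.1 ms) synaptic delay;
* while refractory the membrane stays clamped at V_reset but PSCs keep
  evolving (refractory input is not discarded).

Neuron indexing: 0, 1 inputs; 2, 3 hidden; 4 output.  Synapse indexing:
0: in0->h2, 1: in1->h2, 2: in0->h3, 3: in1->h3, 4: h2->out, 5: h3->out.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# presynaptic neuron of each of the 6 synapses
_PRE = np.array([0, 1, 0, 1, 2, 3], dtype=np.int64)


@njit(cache=True)
def _run_circuit(
    sig0, sig1,              # constant signal drive (pA) into input neurons
    noise,                   # (n_steps, 2) noise currents into input neurons
    w,                       # (6,) signed synaptic weights, pA
    ie,                      # (5,) constant bias currents per neuron, pA
    n_steps, dt,
    tau_m, v_th, v_reset, v_min, ref_steps, leaky,
    dynamical, U, tau_syn, tau_fac, tau_rec,
    counts,                  # (5,) int64 out
    raster,                  # (n_steps, 5) uint8 out, or (1, 5) if unused
    record,
):
    decay_m = np.exp(-dt / tau_m)
    d_syn = np.exp(-dt / tau_syn)
    d_fac = np.exp(-dt / tau_fac)
    d_rec = np.exp(-dt / tau_rec)

    V = np.zeros(5)
    ref = np.zeros(5, dtype=np.int64)
    psc = np.zeros(6)
    u = np.zeros(6)
    x = np.ones(6)
    spiked = np.zeros(5, dtype=np.uint8)
    pre = _PRE

    for t in range(n_steps):
        I0 = ie[0] + sig0 + noise[t, 0]
        I1 = ie[1] + sig1 + noise[t, 1]
        I2 = ie[2] + psc[0] + psc[1]
        I3 = ie[3] + psc[2] + psc[3]
        I4 = ie[4] + psc[4] + psc[5]
        for n in range(5):
            spiked[n] = 0
            if ref[n] > 0:
                ref[n] -= 1
                V[n] = v_reset
                continue
            if n == 0:
                I = I0
            elif n == 1:
                I = I1
            elif n == 2:
                I = I2
            elif n == 3:
                I = I3
            else:
                I = I4
            if leaky:
                v = V[n] * decay_m + I * (1.0 - decay_m)
            else:
                v = V[n] + I * dt / tau_m
            if v < v_min:
                v = v_min
            if v >= v_th:
                spiked[n] = 1
                counts[n] += 1
                V[n] = v_reset
                ref[n] = ref_steps
            else:
                V[n] = v
        if record:
            for n in range(5):
                raster[t, n] = spiked[n]
        for s in range(6):
            psc[s] *= d_syn
            if dynamical:
                u[s] *= d_fac
                x[s] = 1.0 - (1.0 - x[s]) * d_rec
        for s in range(6):
            if spiked[pre[s]]:
                if dynamical:
                    u[s] += U * (1.0 - u[s])
                    r = u[s] * x[s]
                    x[s] -= r
                    psc[s] += w[s] * r
                else:
                    psc[s] += w[s]


@njit(cache=True)
def run_single(
    sig0, sig1, noise, w, ie, n_steps, dt,
    tau_m, v_th, v_reset, v_min, ref_steps, leaky,
    dynamical, U, tau_syn, tau_fac, tau_rec, record,
):
    """Simulate one circuit instance; returns (counts, spike raster)."""
    counts = np.zeros(5, dtype=np.int64)
    if record:
        raster = np.zeros((n_steps, 5), dtype=np.uint8)
    else:
        raster = np.zeros((1, 5), dtype=np.uint8)
    _run_circuit(sig0, sig1, noise, w, ie, n_steps, dt,
                 tau_m, v_th, v_reset, v_min, ref_steps, leaky,
                 dynamical, U, tau_syn, tau_fac, tau_rec,
                 counts, raster, record)
    return counts, raster


@njit(cache=True)
def run_noiseless_batch(
    sig0s, sig1s,            # (batch,) signal drives per instance
    ws,                      # (batch, 6) weights per instance
    ie, n_steps, dt,
    tau_m, v_th, v_reset, v_min, ref_steps, leaky,
    dynamical, U, tau_syn, tau_fac, tau_rec,
):
    """Deterministic (D = 0) batch: one circuit per (drive pair, weight set)."""
    batch = sig0s.shape[0]
    counts = np.zeros((batch, 5), dtype=np.int64)
    raster = np.zeros((1, 5), dtype=np.uint8)
    noise = np.zeros((n_steps, 2))
    for b in range(batch):
        _run_circuit(sig0s[b], sig1s[b], noise, ws[b], ie, n_steps, dt,
                     tau_m, v_th, v_reset, v_min, ref_steps, leaky,
                     dynamical, U, tau_syn, tau_fac, tau_rec,
                     counts[b], raster, False)
    return counts
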