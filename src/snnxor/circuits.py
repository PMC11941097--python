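"""The 2-2-1 analog XOR circuits: spiking (LIF) and rate-based (ReLU).

Both circuits share one topology — two input units, two hidden units, one
output unit — and one antisymmetric weight template:

    hidden 1:  +1 * in0  -1 * in1
    hidden 2:  -1 * in0  +1 * in1
    output:    +1 * h1   +1 * h2

scaled by a global ``weight_gain``; the analog inputs x0, x1 in [0, 1] are
scaled by ``input_gain`` and injected as constant currents (no spike
encoding); per-neuron biases are scaled by ``bias_gain`` (default 1).  For
the ReLU network this template makes the noiseless output proportional to
|x0 - x1| — a linear separation of the input square.  The spiking network
runs the same weights through LIF neurons (18 pA sub-threshold bias) and
exponential-PSC synapses, static or Tsodyks–Markram dynamical, producing a
non-linear output surface; its output statistic is the spike count of the
output neuron over the simulation window T.

Noise (see :mod:`snnxor.noise`) is injected into the two input neurons
only, resampled every simulation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .neurons import NeuronParams
from .noise import NoiseSpec, generate_noise_currents

__all__ = [
    "XOR_TEMPLATE_HIDDEN",
    "XOR_TEMPLATE_OUTPUT",
    "CircuitSpec",
    "SimulationResult",
    "build_snn_xor",
    "build_ann_xor",
    "build_nonleaky_snn_xor",
    "ann_forward",
    "ann_noise_average",
    "run_snn",
]

# canonical antisymmetric XOR weight template (rows: hidden units, cols: inputs)
XOR_TEMPLATE_HIDDEN = np.array([[1.0, -1.0], [-1.0, 1.0]])
XOR_TEMPLATE_OUTPUT = np.array([1.0, 1.0])


@dataclass(frozen=True)
class CircuitSpec:
    """Full description of one 2-2-1 XOR circuit (spiking or ReLU)."""

    kind: str = "snn"                    # "snn" | "ann"
    input_gain: float = 1.0
    weight_gain: float = 1.0
    bias_gain: float = 1.0
    W_hidden: np.ndarray = field(default_factory=lambda: XOR_TEMPLATE_HIDDEN.copy())
    W_output: np.ndarray = field(default_factory=lambda: XOR_TEMPLATE_OUTPUT.copy())
    biases: np.ndarray = field(default_factory=lambda: np.zeros(5))
    # spiking-only fields
    synapse: str = "dynamical"           # "static" | "dynamical"
    tau_syn: float = 1.0                 # ms
    U: float = 0.5
    tau_fac: float = 1.0                 # ms
    tau_rec: float = 10.0                # ms
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if self.kind not in ("snn", "ann"):
            raise ValueError(f"unknown circuit kind {self.kind!r}")
        if self.input_gain <= 0 or self.weight_gain < 0:
            raise ValueError("gains must be positive (weight_gain may be 0)")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if np.shape(self.W_hidden) != (2, 2) or np.shape(self.W_output) != (2,):
            raise ValueError("topology is fixed at 2 inputs, 2 hidden, 1 output")
        if np.shape(self.biases) != (5,):
            raise ValueError("biases must have one entry per neuron (5)")
        if self.synapse not in ("static", "dynamical"):
            raise ValueError(f"unknown synapse kind {self.synapse!r}")

    # --- low-level views used by the stepping engine -------------------
    def synapse_weights(self) -> np.ndarray:
        """The six signed PSC amplitudes (pA), weight_gain applied."""
        w = np.empty(6)
        w[0] = self.W_hidden[0, 0]
        w[1] = self.W_hidden[0, 1]
        w[2] = self.W_hidden[1, 0]
        w[3] = self.W_hidden[1, 1]
        w[4] = self.W_output[0]
        w[5] = self.W_output[1]
        return self.weight_gain * w

    def bias_currents(self) -> np.ndarray:
        """Per-neuron constant current: I_e plus the scaled architectural bias."""
        return self.neuron.I_e + self.bias_gain * np.asarray(self.biases, dtype=float)


@dataclass(frozen=True)
class SimulationResult:
    """Spike counts and rates of one spiking run (or one ReLU evaluation)."""

    spike_counts: np.ndarray      # (5,) per-neuron counts over the window
    T: float                      # window length, s
    spike_times: list | None = None  # optional [(neuron_id, time_ms), ...]

    @property
    def rates(self) -> np.ndarray:
        """Per-neuron firing rates in Hz."""
        return np.asarray(self.spike_counts, dtype=float) / self.T

    @property
    def output_count(self) -> int:
        """Spike count of the output neuron (the task statistic C_T)."""
        return int(self.spike_counts[4])


def build_snn_xor(
    input_gain: float,
    weight_gain: float,
    synapse: str = "dynamical",
    tau_syn: float = 1.0,
    **kwargs,
) -> CircuitSpec:
    """Spiking 2-2-1 XOR circuit with the canonical template and default LIF constants.

    Input neuron i receives the constant drive ``I_e (18 pA) + bias +
    input_gain * x_i`` plus noise; hidden and output neurons receive
    ``I_e + bias`` plus synaptic currents.
    """
    return CircuitSpec(kind="snn", input_gain=input_gain, weight_gain=weight_gain,
                       synapse=synapse, tau_syn=tau_syn, **kwargs)


def build_ann_xor(input_gain: float, weight_gain: float, **kwargs) -> CircuitSpec:
    """ReLU 2-2-1 XOR circuit with the canonical template."""
    return CircuitSpec(kind="ann", input_gain=input_gain, weight_gain=weight_gain, **kwargs)


def build_nonleaky_snn_xor(input_gain: float, weight_gain: float) -> CircuitSpec:
    """Non-leaky comparison circuit: static synapses, pure integration.

    Without leak the 18 pA bias would drive every neuron to its
    refractory-limited ceiling and drown the signal, so the bias current is
    confined to the input layer (hidden/output biases cancel I_e) and the
    membrane is clamped at rest (V_min = E_L) so that inhibition rectifies:
    a neuron integrates only the positive part of its net drive, one-sided
    like a ReLU.  Input rates are then linear in the drive, and the
    normalized output surface approaches the ReLU circuit's |x0 - x1|
    separation — increasingly so as noise smooths the spike-count
    discretization.
    """
    neuron = NeuronParams(leaky=False, V_min=0.0)
    biases = np.array([0.0, 0.0, -neuron.I_e, -neuron.I_e, -neuron.I_e])
    return CircuitSpec(kind="snn", input_gain=input_gain, weight_gain=weight_gain,
                       synapse="static", tau_syn=1.0, biases=biases, neuron=neuron)


def ann_forward(spec: CircuitSpec, x0: float, x1: float, noise=(0.0, 0.0)) -> np.ndarray | float:
    """One ReLU forward pass: output activation for input (x0, x1).

    ``noise`` is added to the *scaled* input drive (input_gain * x + noise),
    matching the current-injection convention of the spiking circuit;
    shape (2,) for one draw or (n, 2) for a batch of draws (vectorized).
    Negative intermediate activations are clipped by the ReLU.
    """
    noise = np.asarray(noise, dtype=float)
    drive = np.array([spec.input_gain * x0, spec.input_gain * x1]) + noise
    pre_h = spec.weight_gain * drive @ spec.W_hidden.T + spec.bias_gain * spec.biases[2:4]
    hidden = np.maximum(pre_h, 0.0)
    pre_o = spec.weight_gain * hidden @ spec.W_output + spec.bias_gain * spec.biases[4]
    out = np.maximum(pre_o, 0.0)
    return float(out) if noise.ndim == 1 else out


def ann_noise_average(
    spec: CircuitSpec,
    x0: float,
    x1: float,
    noise_spec: NoiseSpec,
    n_draws: int,
    seed=None,
) -> float:
    """Mean ReLU output over ``n_draws`` independent noise draws.

    Each draw perturbs the scaled input currents exactly as in the spiking
    circuit (multiplicative noise scales with input_gain * x_i); with D = 0
    this equals the noiseless forward value for any n_draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    drives = (spec.input_gain * x0, spec.input_gain * x1)
    draws = generate_noise_currents(noise_spec, drives, n_draws, seed)
    return float(np.mean(ann_forward(spec, x0, x1, draws)))


def run_snn(
    spec: CircuitSpec,
    x0: float,
    x1: float,
    noise_spec: NoiseSpec | None = None,
    T: float = 20.0,
    dt: float = 0.1,
    seed=None,
    record_spikes: bool = False,
) -> SimulationResult:
    """Simulate the spiking circuit for input (x0, x1) over T seconds.

    Advances all five neurons and six synapses on the ``dt`` (ms) clock,
    with a fresh noise value injected into the input neurons every step
    (T = 20 s at 0.1 ms resolution -> 200,000 noise samples per input).
    With D = 0 the run is deterministic regardless of the seed.

    Parameters
    ----------
    seed : overrides ``noise_spec.seed`` when given; may be an int, a
        ``numpy.random.Generator`` or a ``SeedSequence``-spawned child.
    """
    if spec.kind != "snn":
        raise ValueError("run_snn requires a spiking CircuitSpec")
    if T <= 0:
        raise ValueError("T must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T * 1000.0 / dt))
    drives = (spec.input_gain * x0, spec.input_gain * x1)
    if noise_spec is None:
        noise_spec = NoiseSpec(D=0.0)
    if not isinstance(seed, np.random.Generator) and not isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(noise_spec.seed if seed is None else seed)
    else:
        rng = np.random.default_rng(seed)
    noise = generate_noise_currents(noise_spec, drives, n_steps, rng)

    p = spec.neuron
    ref_steps = int(round(p.t_ref / dt))
    counts, raster = _engine.run_single(
        float(drives[0]), float(drives[1]), noise,
        spec.synapse_weights(), spec.bias_currents(), n_steps, dt,
        p.tau_m, p.V_th, p.V_reset, p.V_min, ref_steps, p.leaky,
        spec.synapse == "dynamical", spec.U, spec.tau_syn, spec.tau_fac, spec.tau_rec,
        record_spikes,
    )
    spike_times = None
    if record_spikes:
        steps, neurons = np.nonzero(raster)
        spike_times = [(int(n), (int(t) + 1) * dt) for t, n in zip(steps, neurons)]
    return SimulationResult(spike_counts=counts, T=T, spike_times=spike_times)
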