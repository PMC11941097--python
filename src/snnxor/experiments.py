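"""Protocol drivers: surfaces, gain/boundary grid searches, and noise sweeps.

The full study protocol evaluates a circuit on a uniform grid over the
input square, normalizes the output statistic by its grid maximum, and
scores decision boundaries (b, h) against the analog XOR labels:

* spiking runs integrate 20 s per input at 0.1 ms resolution (200,000
  noise samples per input) and use the output spike count;
* ReLU runs average the output over 20,000 independent noise draws;
* each noise level D is repeated 20 times with fresh seeds and the
  accuracy is averaged over repeats.

Scaled-down problem sizes (shorter windows, fewer repeats) are plain
arguments — the protocol shape is unchanged.

Seeding: one ``SeedSequence(base_seed, spawn_key=(D_index, repeat))`` per
run, spawned into per-grid-point child streams in row-major order.  All
boundaries are scored on the same simulated surface of a run, so a sweep
re-run from its config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from .circuits import CircuitSpec, ann_forward, ann_noise_average, run_snn
from .noise import NoiseSpec
from .task import AccuracySurface, TaskBoundary

logger = logging.getLogger(__name__)

__all__ = [
    "input_grid",
    "boundary_grid",
    "DEFAULT_INPUT_GAINS",
    "DEFAULT_WEIGHT_GAINS",
    "output_surface",
    "snn_surfaces_for_gains",
    "GainSearchResult",
    "grid_search_gains",
    "grid_search_boundary",
    "SweepConfig",
    "SweepResult",
    "sweep_noise",
    "compare_modes",
    "firing_rate_map",
    "run_metadata",
]

DEFAULT_INPUT_GAINS = tuple(range(1, 11))
DEFAULT_WEIGHT_GAINS = tuple(range(5, 151, 5))


def input_grid(n: int = 21) -> np.ndarray:
    """Uniform grid over [0, 1] with n points (default step 0.05)."""
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    return np.linspace(0.0, 1.0, n)


def boundary_grid(step: float = 0.02) -> np.ndarray:
    """Candidate b/h values: step, 2*step, ..., < 1 (endpoints excluded)."""
    vals = np.arange(step, 1.0, step)
    return vals[vals < 1.0 - 1e-12]


# ---------------------------------------------------------------------------
# surfaces


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _engine_args(spec: CircuitSpec, dt: float):
    p = spec.neuron
    return dict(
        ie=spec.bias_currents(),
        tau_m=p.tau_m, v_th=p.V_th, v_reset=p.V_reset, v_min=p.V_min,
        ref_steps=int(round(p.t_ref / dt)), leaky=p.leaky,
        dynamical=spec.synapse == "dynamical",
        U=spec.U, tau_syn=spec.tau_syn, tau_fac=spec.tau_fac, tau_rec=spec.tau_rec,
    )


def _snn_noiseless_counts(spec: CircuitSpec, x0s: np.ndarray, x1s: np.ndarray,
                          T: float, dt: float) -> np.ndarray:
    """Deterministic output-count surface via the batched kernel."""
    X0, X1 = np.meshgrid(x0s, x1s, indexing="ij")
    sig0 = spec.input_gain * X0.ravel()
    sig1 = spec.input_gain * X1.ravel()
    ws = np.broadcast_to(spec.synapse_weights(), (sig0.size, 6)).copy()
    a = _engine_args(spec, dt)
    n_steps = int(round(T * 1000.0 / dt))
    counts = _engine.run_noiseless_batch(
        sig0, sig1, ws, a["ie"], n_steps, dt,
        a["tau_m"], a["v_th"], a["v_reset"], a["v_min"], a["ref_steps"], a["leaky"],
        a["dynamical"], a["U"], a["tau_syn"], a["tau_fac"], a["tau_rec"],
    )
    return counts[:, 4].reshape(X0.shape).astype(float)


def output_surface(
    spec: CircuitSpec,
    noise_spec: NoiseSpec | None = None,
    T: float = 20.0,
    dt: float = 0.1,
    seed=None,
    grid_n: int = 21,
    n_ann_draws: int = 20_000,
) -> AccuracySurface:
    """Evaluate one circuit over the input grid and normalize the output.

    For the spiking circuit the raw statistic is the output-neuron spike
    count per grid point (one independent noise stream per point, spawned
    from ``seed``); for the ReLU circuit it is the noise-averaged output
    activation.  With no noise (``noise_spec`` None or D = 0) both paths
    are deterministic.
    """
    x0s = input_grid(grid_n)
    x1s = input_grid(grid_n)
    noiseless = noise_spec is None or noise_spec.D == 0

    if spec.kind == "ann":
        raw = np.empty((x0s.size, x1s.size))
        if noiseless:
            for i, x0 in enumerate(x0s):
                raw[i] = [ann_forward(spec, x0, x1) for x1 in x1s]
        else:
            ss = _as_seed_sequence(seed)
            children = ss.spawn(x0s.size * x1s.size)
            k = 0
            for i, x0 in enumerate(x0s):
                for j, x1 in enumerate(x1s):
                    raw[i, j] = ann_noise_average(
                        spec, x0, x1, noise_spec, n_ann_draws,
                        np.random.default_rng(children[k]))
                    k += 1
        return AccuracySurface(x0s, x1s, raw)

    if noiseless:
        raw = _snn_noiseless_counts(spec, x0s, x1s, T, dt)
        return AccuracySurface(x0s, x1s, raw)

    ss = _as_seed_sequence(seed)
    children = ss.spawn(x0s.size * x1s.size)
    raw = np.empty((x0s.size, x1s.size))
    k = 0
    for i, x0 in enumerate(x0s):
        for j, x1 in enumerate(x1s):
            res = run_snn(spec, x0, x1, noise_spec, T=T, dt=dt, seed=children[k])
            raw[i, j] = res.output_count
            k += 1
    return AccuracySurface(x0s, x1s, raw)


def snn_surfaces_for_gains(
    base_spec: CircuitSpec,
    gain_pairs: Sequence[tuple[float, float]],
    T: float,
    dt: float = 0.1,
    grid_n: int = 21,
) -> list[AccuracySurface]:
    """Noiseless output-count surfaces for many (input_gain, weight_gain) pairs.

    All (gain pair x grid point) instances run through one batched kernel
    call; used by the gain grid search where per-pair calls would dominate.
    """
    x0s = input_grid(grid_n)
    x1s = input_grid(grid_n)
    X0, X1 = np.meshgrid(x0s, x1s, indexing="ij")
    p0, p1 = X0.ravel(), X1.ravel()
    npts = p0.size
    ngain = len(gain_pairs)

    sig0 = np.empty(ngain * npts)
    sig1 = np.empty(ngain * npts)
    ws = np.empty((ngain * npts, 6))
    template = replace(base_spec, input_gain=1.0, weight_gain=1.0).synapse_weights()
    for g, (ig, wg) in enumerate(gain_pairs):
        sl = slice(g * npts, (g + 1) * npts)
        sig0[sl] = ig * p0
        sig1[sl] = ig * p1
        ws[sl] = wg * template
    a = _engine_args(base_spec, dt)
    n_steps = int(round(T * 1000.0 / dt))
    counts = _engine.run_noiseless_batch(
        sig0, sig1, ws, a["ie"], n_steps, dt,
        a["tau_m"], a["v_th"], a["v_reset"], a["v_min"], a["ref_steps"], a["leaky"],
        a["dynamical"], a["U"], a["tau_syn"], a["tau_fac"], a["tau_rec"],
    )
    out = []
    for g in range(ngain):
        raw = counts[g * npts:(g + 1) * npts, 4].reshape(X0.shape).astype(float)
        out.append(AccuracySurface(x0s, x1s, raw))
    return out


# ---------------------------------------------------------------------------
# grid searches


@dataclass(frozen=True)
class GainSearchResult:
    best_input_gain: float
    best_weight_gain: float
    best_accuracy: float
    table: pd.DataFrame  # columns input_gain, weight_gain, accuracy


def grid_search_gains(
    kind: str = "snn",
    boundary: TaskBoundary = TaskBoundary(0.46, 0.3),
    input_gains: Sequence[float] = DEFAULT_INPUT_GAINS,
    weight_gains: Sequence[float] = DEFAULT_WEIGHT_GAINS,
    synapse: str = "dynamical",
    tau_syn: float = 1.0,
    T: float = 5.0,
    dt: float = 0.1,
    grid_n: int = 21,
    **circuit_kwargs,
) -> GainSearchResult:
    """Exhaustive noiseless accuracy search over (input_gain, weight_gain).

    Each candidate's normalized surface is scored at the fixed ``boundary``;
    ties break toward the lexicographically smallest (input_gain,
    weight_gain).
    """
    pairs = [(float(ig), float(wg)) for ig in input_gains for wg in weight_gains]
    if not pairs:
        raise ValueError("gain grid must be non-empty")
    if kind == "snn":
        base = CircuitSpec(kind="snn", input_gain=1.0, weight_gain=1.0,
                           synapse=synapse, tau_syn=tau_syn, **circuit_kwargs)
        surfaces = snn_surfaces_for_gains(base, pairs, T=T, dt=dt, grid_n=grid_n)
        accs = [s.accuracy(boundary) for s in surfaces]
    elif kind == "ann":
        accs = []
        for ig, wg in pairs:
            spec = CircuitSpec(kind="ann", input_gain=ig, weight_gain=wg, **circuit_kwargs)
            accs.append(output_surface(spec, grid_n=grid_n).accuracy(boundary))
    else:
        raise ValueError(f"unknown circuit kind {kind!r}")

    table = pd.DataFrame(pairs, columns=["input_gain", "weight_gain"])
    table["accuracy"] = accs
    best_idx = int(np.lexsort((table.weight_gain, table.input_gain,
                               -table.accuracy))[0])
    row = table.iloc[best_idx]
    logger.info("gain search best: ig=%g wg=%g acc=%.4f",
                row.input_gain, row.weight_gain, row.accuracy)
    return GainSearchResult(float(row.input_gain), float(row.weight_gain),
                            float(row.accuracy), table)


def grid_search_boundary(
    surface: AccuracySurface,
    b_values: np.ndarray | None = None,
    h_values: np.ndarray | None = None,
) -> tuple[TaskBoundary, float]:
    """Exhaustive (b, h) argmax on a normalized surface; ties to smallest (b, h)."""
    b_values = boundary_grid() if b_values is None else np.asarray(b_values)
    h_values = boundary_grid() if h_values is None else np.asarray(h_values)
    return surface.best_boundary(b_values, h_values)


# ---------------------------------------------------------------------------
# noise sweeps


@dataclass(frozen=True)
class SweepConfig:
    """One accuracy-versus-noise sweep.

    Defaults follow the full protocol (T = 20 s, 20 repeats, 20,000 ReLU
    noise draws, 0.1 ms resolution, 21x21 input grid).
    """

    kind: str = "snn"                          # "snn" | "ann"
    input_gain: float = 5.0
    weight_gain: float = 110.0
    synapse: str = "dynamical"
    tau_syn: float = 1.0                       # ms
    noise_family: str = "multiplicative_white"
    mode: str = "common"
    theta: float = 1.0                         # 1/ms, OU only
    D_values: tuple = (0.0, 1.0, 2.0, 5.0)
    boundaries: tuple = ((0.46, 0.3), (0.4, 0.5), (0.42, 0.4), (0.46, 0.2))
    repeats: int = 20
    T: float = 20.0                            # s
    dt: float = 0.1                            # ms
    grid_n: int = 21
    n_ann_draws: int = 20_000
    base_seed: int = 0
    sqrt_dt_innovation: bool = False

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if any(D < 0 for D in self.D_values):
            raise ValueError("D values must be non-negative")
        if not self.boundaries:
            raise ValueError("at least one boundary is required")

    def circuit(self) -> CircuitSpec:
        return CircuitSpec(kind=self.kind, input_gain=self.input_gain,
                           weight_gain=self.weight_gain, synapse=self.synapse,
                           tau_syn=self.tau_syn)

    def noise(self, D: float) -> NoiseSpec:
        return NoiseSpec(family=self.noise_family, D=D, theta=self.theta,
                         mode=self.mode, resample_dt=self.dt,
                         sqrt_dt_innovation=self.sqrt_dt_innovation)

    @property
    def n_steps_per_input(self) -> int:
        """Simulation steps (= noise samples) per input point."""
        return int(round(self.T * 1000.0 / self.dt))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        for key in ("D_values",):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        if "boundaries" in d:
            d["boundaries"] = tuple((float(b), float(h)) for b, h in d["boundaries"])
        return cls(**d)


@dataclass(frozen=True)
class SweepResult:
    """Accuracy tensor of one sweep, indexed (boundary, D, repeat)."""

    config: SweepConfig
    accuracy: np.ndarray          # (n_boundaries, n_D, repeats)

    @property
    def mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=2)

    @property
    def sd(self) -> np.ndarray:
        return self.accuracy.std(axis=2)

    def best_boundary_per_D(self) -> list[TaskBoundary]:
        """The evaluated boundary with the highest mean accuracy at each D."""
        out = []
        for j in range(self.mean.shape[1]):
            i = int(np.argmax(self.mean[:, j]))
            out.append(TaskBoundary(*self.config.boundaries[i]))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: b, h, D, noise_family, mode, tau_syn, repeat, accuracy."""
        rows = []
        c = self.config
        for i, (b, h) in enumerate(c.boundaries):
            for j, D in enumerate(c.D_values):
                for r in range(c.repeats):
                    rows.append((b, h, D, c.noise_family, c.mode, c.tau_syn,
                                 r, self.accuracy[i, j, r]))
        return pd.DataFrame(rows, columns=["b", "h", "D", "noise_family", "mode",
                                           "tau_syn", "repeat", "accuracy"])


def sweep_noise(config: SweepConfig) -> SweepResult:
    """Run the accuracy-versus-noise protocol.

    For every (D, repeat) one surface is simulated with a fresh seed
    (``SeedSequence(base_seed, spawn_key=(D_index, repeat))``), normalized,
    and scored at every boundary — all boundaries share the run's noise
    realization.
    """
    spec = config.circuit()
    n_b = len(config.boundaries)
    n_D = len(config.D_values)
    acc = np.empty((n_b, n_D, config.repeats))
    boundaries = [TaskBoundary(b, h) for b, h in config.boundaries]
    for j, D in enumerate(config.D_values):
        noise = config.noise(D)
        for r in range(config.repeats):
            seed = np.random.SeedSequence(config.base_seed, spawn_key=(j, r))
            surface = output_surface(spec, noise, T=config.T, dt=config.dt,
                                     seed=seed, grid_n=config.grid_n,
                                     n_ann_draws=config.n_ann_draws)
            for i, bd in enumerate(boundaries):
                acc[i, j, r] = surface.accuracy(bd)
        logger.info("sweep D=%g done: best mean acc %.4f", D, acc[:, j, :].mean(axis=1).max())
    return SweepResult(config=config, accuracy=acc)


def compare_modes(config: SweepConfig) -> dict[str, SweepResult]:
    """Paired common-versus-independent sweep with identical seeds per run."""
    out = {}
    for mode in ("common", "independent"):
        out[mode] = sweep_noise(replace(config, mode=mode))
    return out


def firing_rate_map(
    spec: CircuitSpec,
    noise_spec: NoiseSpec | None = None,
    T: float = 20.0,
    dt: float = 0.1,
    seed=None,
    grid_n: int = 21,
) -> pd.DataFrame:
    """Output-neuron firing rate (Hz) per input grid point.

    Returned as a DataFrame indexed by x0 with x1 columns, ready for CSV
    export / heatmap rendering.
    """
    surface = output_surface(spec, noise_spec, T=T, dt=dt, seed=seed, grid_n=grid_n)
    rates = surface.raw / T
    return pd.DataFrame(rates, index=pd.Index(surface.x0_values, name="x0"),
                        columns=pd.Index(surface.x1_values, name="x1"))


# ---------------------------------------------------------------------------
# provenance


def run_metadata(config, seed=None) -> dict:
    """Config hash + seed + software version, for the JSON sidecar of every output."""
    from . import __version__

    if hasattr(config, "to_dict"):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "snnxor_version": __version__,
    }
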