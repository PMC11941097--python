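# Methods

## The model

The package simulates a minimal 2-2-1 circuit solving the *analog XOR*
task: classify an input pair (x0, x1) ∈ [0, 1]² as HIGH exactly when one of
the two inputs meets or exceeds an input boundary *b*.  Two realizations of
the circuit share one antisymmetric weight template (hidden 1: +in0 − in1;
hidden 2: −in0 + in1; output: +h1 + h2, all times a global weight gain;
inputs times an input gain; biases times a bias gain, default 1):

* a **ReLU network**, whose noiseless output is exactly proportional to
  |x0 − x1| — a linear separation of the input square; and
* a **spiking network** of five leaky integrate-and-fire neurons joined by
  exponential-current synapses, static or Tsodyks–Markram dynamical, whose
  output statistic is the spike count of the output neuron over a window
  *T*.

### Neurons

Each neuron obeys τ_m dV/dt = −(V − E_L) + I_total with C_m = 10 pF,
τ_m = 10 ms, E_L = 0 mV, threshold 20 mV, reset 16 mV, and a constant bias
I_e = 18 pA.  With these constants the implied membrane resistance is
1 GΩ, so currents in pA map one-to-one onto mV of asymptotic
depolarization; the bias parks every neuron 2 mV below threshold — the
sub-threshold substrate on which stochastic resonance acts.  Per step the
linear ODE is advanced with its exact exponential propagator under a drive
held constant over the step, which keeps spike timing robust in dt (the
discretization error is at most one step per spike; absolute spike times
therefore drift by one grid point per spike at high rates, while every
inter-spike interval is dt-accurate).  A spike clamps the membrane at the
reset for a refractory period t_ref = 2.0 ms (a conventional default for
this neuron model; the constant is configurable).  Synaptic and noise
input is *not* discarded during refractoriness: postsynaptic currents keep
evolving while only the membrane is frozen.  The membrane starts at rest
with no burn-in; spikes are counted from t = 0.  A non-leaky variant
integrates the drive directly (V += I·dt/τ_m).

The closed forms used as test oracles: sub-threshold fixed point
V∞ = I_total; inter-spike interval τ_m·ln((I − V_reset)/(I − V_th)) + t_ref
for constant supra-threshold drive.

### Synapses

Every synapse injects an exponentially decaying PSC with time constant
τ_syn (default 1 ms).  The dynamical kind is the two-state reduction of
the Tsodyks–Markram resource model: utilization u facilitates by
u ← u + U(1 − u) on each presynaptic spike (relaxing to 0 with
τ_fac = 1 ms) and resources x deplete by the released fraction r = u·x
(recovering to 1 with τ_rec = 10 ms); the PSC jumps by weight·r.  The
facilitation jump is applied before computing the release, matching the
canonical formulation.  U defaults to 0.5, the reference-simulator default
for this synapse model; the printed sources for this circuit do not state
it.  Inhibition is a negative PSC amplitude through the same machinery.
The synaptic delay is one simulation step (0.1 ms) — a minimal positive
delay that preserves causality; no physiological delay is modeled.

At the default τ_rec ≫ τ_fac the synapse is depressing: under sustained
drive the release sequence is non-increasing after the first spike, with a
steady state equal to the fixed point of the per-interval map (iterated to
1e-12 as the oracle).  The static synapse is the U = 1, τ_rec, τ_fac → 0
limit, verified to 1e-6 in the tests.

### Noise

Three noise processes inject current into the two *input* neurons only,
resampled every 0.1 ms (the simulation resolution), in `common` mode (one
draw applied bit-identically to both inputs) or `independent` mode:

* **additive white** — i.i.d. N(0, D²) per step;
* **multiplicative white** — the same draw scaled by the input's signal
  drive (input gain × x_i), so strong inputs receive proportionally strong
  noise and a silent input none;
* **OU colored** — an Ornstein–Uhlenbeck process mean-reverting to 0 at
  rate θ (1/ms), discretized as z' = z − θz·dt + w.

The per-step innovation w has SD exactly D (no √dt scaling) in all
families, so families are compared "at equal D"; a √dt-scaled innovation is
available behind `sqrt_dt_innovation` for diffusion-style scaling.  Two
consequences of this choice are worth knowing.  First, the OU process's
discrete autocorrelation is (1 − θ·dt)^k; at θ = 1/ms and dt = 0.1 ms this
deviates from the continuum exp(−θ·lag) by ≈ 0.019 at a 1 ms lag, so
autocorrelation checks compare against exp(−θ·dt) at one-step lag (bias
0.005) and against the recursion's own theory at longer lags.  Second,
additive white noise at D = 5 moves the membrane by only ≈ 0.35 mV (SD)
against the 2 mV threshold gap — a ~5.7σ event per step — so a single
neuron at the 18 pA bias stays effectively silent under additive white
noise at that intensity, whereas the OU process (stationary SD ≈ 2.3·D at
these settings) drives it at tens of Hz.  This is the quantitative face of
the qualitative ordering reported for the three families at equal D: OU
strongest, multiplicative strongest *per unit of input drive*, additive
weakest.  The single-neuron sub-threshold demonstration in the acceptance
suite therefore uses the OU family.

### Task metrics

The circuit's raw output statistic over a uniform input grid (default
21 × 21; the evaluation grid used by the original study is not stated) is
normalized by its grid maximum into [0, 1] (an all-zero surface is passed
through with a warning; a min–max variant is not needed since counts are
non-negative) and digitized against an output threshold h ∈ (0, 1);
accuracy is the fraction of grid points whose digitized output matches the
XOR label.  Ties at either threshold count as HIGH, the ≥ convention of
the task's truth table; the written definition of the step function
(Θ(i) = 1 for i > 0) conflicts with that table, and the table governs —
the default grids avoid most exact ties, and where gain-dependent rounding
could still flip a tie the tests use tie-free thresholds.

One property of the boundary landscape matters for interpretation: near
b = 0 or b = 1 one class almost vanishes, so the trivial always-LOW
classifier scores ≈ 1 − 2b(1 − b).  A global (b, h) search therefore
rewards degenerate boundaries (≈ 0.96 for the ReLU surface at b = 0.02).
The ReLU ceiling quoted below restricts b to the non-degenerate band
[0.1, 0.9], where both classes keep ≥ 18% of the square; the spiking
circuit needs no such protection — its best boundary is balanced.

## Protocol

The full protocol simulates each input for T = 20 s at 0.1 ms resolution
(200,000 noise samples per input), repeats each noise level D twenty times
with fresh seeds, and averages; the ReLU circuit instead averages each
input over 20,000 independent noise draws.  Gains are grid-searched
noiselessly at a fixed anchor boundary ((b, h) = (0.46, 0.3), derived from
the ReLU circuit), then the boundary itself over a 0.02-step (b, h) grid.
All boundaries of a sweep are scored on the same simulated surface of a
run.  Seeding is hierarchical: `SeedSequence(base_seed, spawn_key =
(D_index, repeat))` per run, spawned into per-grid-point child streams in
row-major order, so every sweep is bit-reproducible from its config.

Tests and the acceptance script run the same pipeline at reduced problem
sizes chosen to keep spike counts in the hundreds per active grid point:
windows of 1–5 s, 10–30-point gain lattices, 3–10 repeats.  Noiseless
surfaces are deterministic, so shorter windows only coarsen the count
quantization; stochastic checks at these sizes show the direction and
rough size of effects, not third-decimal accuracy values.

## Design choices on genuinely open points

* **Circuit weights.**  The original diagram's numeric connection
  strengths are not recoverable from text, so the canonical antisymmetric
  XOR template is used (overridable in `CircuitSpec`).  Consequences: the
  qualitative picture is reproduced (ReLU linear separation, spiking
  non-linear separation, noise rescuing mis-set boundaries), but
  weight-specific printed settings do not transfer — with this template
  the gain pair (5, 110) sits mid-field rather than at the top of the
  search at the anchor boundary, whose optimum here is (5, 50), with
  (3, 65) the global winner (100% at (b, h) = (0.72, 0.50), a balanced
  boundary).  The headline capability — a five-neuron spiking circuit at
  ≥ 95% where the ReLU twin tops out near 84% — is template-robust.
* **Analog input encoding.**  Inputs are constant currents
  (input gain × x_i) for the whole window; no spike encoding.
* **Contrast measure.**  "Sharper contrast" of an output surface is
  measured as the variance of the normalized surface.  A percentile ratio
  (p90/p50) fails at long τ_syn because the median itself saturates
  upward.
* **Non-leaky comparison circuit.**  Without leak, the 18 pA bias would
  drive every neuron at its refractory ceiling and flatten the output
  surface.  `build_nonleaky_snn_xor` confines the bias current to the
  input layer and clamps the membrane at rest (V_min = E_L), making
  integration one-sided like a ReLU; its noisy normalized surface then
  rank-correlates with the ReLU surface at ρ > 0.97 (ρ ≈ 0.89 noiseless).
* **ReLU noise injection** perturbs the scaled input drive, matching the
  spiking circuit's current-injection convention.

## What the generator does and does not emulate

The noise module is the package's synthetic-data source: it reproduces the
stated noise structure (families, common/independent coupling, 0.1 ms
resampling, equal-D comparability) driving a deterministic circuit.  It
does not model escape noise (fluctuating thresholds), slow parameter
drift, 1/f spectra, stochastic vesicle release, or trial-to-trial
parameter variability — so passing tests certify the circuit-level
stochastic-resonance mechanism under the modeled noise, not robustness of
real neuromorphic hardware or biological circuits.

## Numerical notes and limitations

* dt fixed at 0.1 ms by default; spike times are grid-aligned (no off-grid
  interpolation), and V_min (−1.798e308 by default) is applied before
  threshold detection.
* The compiled stepping kernel duplicates the scalar primitives for speed
  and is held to bit-exact agreement with them by a cross-validation test;
  the scalar refractory bookkeeping carries a 1e-9 ms tolerance so t_ref
  spans exactly round(t_ref/dt) steps despite float accumulation.
* Grid-search tie-breaks are lexicographic toward the smallest candidate.
* Only the 2-2-1 topology is supported; no training, conductance
  synapses, adaptive thresholds, or energy accounting.
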