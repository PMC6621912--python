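# Methods

This note defines the implemented model precisely: equations, parameter
defaults, numerical conventions, and the reasoning behind every design
decision that the equations alone do not fix.

## 1. Neuron and synapse dynamics

**Membrane.** Leaky integrate-and-fire neurons follow

    tau_m dV/dt = -V + I R,

integrated by forward Euler at a fixed timestep dt = 1 ms
(`V <- V + (dt/tau_m)(-V + I)`; currents are expressed directly in mV,
R = 1). A neuron reaching the threshold emits a spike, resets to the
0 mV rest, and is clamped at rest for the refractory period. Defaults:
threshold 16.5 mV, tau_m = 28 ms, refractory 4 ms.

**Post-synaptic currents.** A presynaptic spike opens a square current
pulse lasting 3 ms. Overlapping pulses superpose linearly; a ring
buffer (`PulseBuffer`) tracks open pulses. The pulse amplitude is the
synaptic strength times the presynaptic short-term-plasticity efficacy
*in force when the spike was emitted* (the spike's own depression
affects only subsequent pulses) — the update order would otherwise be
ambiguous within a timestep.

**Short-term plasticity.** Each neuron carries an outgoing efficacy
S ∈ [0, 1] updated by the linearized constant-step rule

    S' = clamp(S - alpha (x - beta), 0, 1),    alpha = 0.007, beta = 0.739,

where x is the binary spike flag: a spike depresses S by
alpha(1 - beta), silence recovers it by alpha·beta.

**Synaptic trace.** Each neuron's trace increments by one per spike and
decays exponentially with tau = 300 ms. Because the ODE is linear, the
per-step map is evaluated in closed form, `X' = X exp(-dt/tau) + x`,
not by Euler — silent decay matches the analytic exponential to
machine precision (asserted at 1e-12 in the tests). Traces serve both
as the features the readout consumes and as the STDP eligibility
signal.

## 2. Reservoir construction

Neurons sit on a 3-D integer lattice (the most-cubic factorization of
the population size, e.g. 500 → 10 × 10 × 5) and are split 4:1 into
excitatory (E) and inhibitory (I) classes uniformly at random. A
directed connection from j to i forms independently with probability

    P(i, j) = C · exp(-D(i,j)/lambda)^2,

with Euclidean lattice distance D and type-pair constants
C(EE, EI, II, IE) = 0.6, 1, 0.2, 1 and lambda = 3 for all pairs.
Weights are fixed per pair type — EE 3, EI 3, IE 4, II 1 — and then
per-neuron incoming E and I weight sums are proportionally rescaled to
the targets 40 and 36 respectively, giving homogeneous recurrent
excitability.

*Scope of normalization (design decision).* Only recurrent synapses are
normalized; input and inter-layer projections keep their fixed
strengths. Folding the sparse input synapses into the excitatory sum
would make a neuron's recurrent excitability depend on whether it
happens to receive input, destroying the homogeneity that normalization
is meant to provide.

Input projections are Bernoulli with density 0.05 and weight 3.
Feature frames are min–max normalized per dimension (fitted on training
data) and delivered as constant current for the frame's duration
(default 1 ms per frame); a seeded Poisson spike encoding (rate ∝
value, up to 200 Hz) is available as an alternative.

*Current-to-potential gain.* Synaptic strengths are dimensionless, so a
single global gain kappa converts summed pulse amplitude to membrane
drive. It is sized so that a volley of ~6 simultaneous strength-3
excitatory pulses at full efficacy lifts a resting neuron to threshold
within the 3-ms pulse window:

    kappa = 16.5 / (6 · 3 · (1 - (1 - 1/28)^3)) ≈ 8.87.

## 3. Winner-take-all encoding layers

Between consecutive reservoirs sits a WTA layer: a dense non-negative
matrix maps the current reservoir spike vector to drives
`gain · W^T x(n)` (a single-step product — WTA inputs do not open 3-ms
pulses); all WTA neurons integrate as LIF units with individually
adapted thresholds. If any neuron is supra-threshold, the one with the
highest membrane potential fires the sole spike and every membrane is
reset to rest (global inhibition at 1-ms resolution; exact ties resolve
to the lowest index). The winner's spike is projected to the next
reservoir through a sparse Bernoulli projection and *does* open a 3-ms
pulse there, like any spike entering an LIF pool.

Training is purely local and layer-wise greedy (earlier encoders frozen
while a later one trains; reservoir weights never change):

- **STDP** on each win: `W' = max(W + eta (X_pre - X_tar), 0)` with
  target trace X_tar = 25 on the winner's incoming weights.
- **Synaptic scaling** after each STDP step: the winner's incoming
  weights are proportionally rescaled to sum to 15. Columns are also
  initialized on this manifold. A fully zeroed column raises an error
  rather than being silently re-inflated.
- **Intrinsic plasticity**: each neuron's threshold offset follows
  `Theta' = Theta exp(-dt/500) + 1.5 x` (mV), spreading wins across
  the layer.

*Step size (design decision).* eta defaults to 2e-4. Scaled weights
have magnitude ≈ target/fan-in = 15/500 = 0.03 while (X_pre − X_tar) is
of order 25 for quiet presynaptic neurons, so a step of 0.01 would
floor an entire winner column in a single depression event; 2e-4 keeps
single-step changes small relative to the weight scale. The value
follows from this magnitude argument, not from task accuracy.

*Gains (design decision).* WTA drive gain defaults to 120 and
inter-layer (WTA → next reservoir) weight to 20, against 3 for frame
inputs. Both were fixed once from a firing-rate health check before
any task evaluation: a WTA layer emits at most one spike per
millisecond, so a single 3-ms pulse must be able to drive deeper
neurons near threshold (w · kappa · (1 − (27/28)^3) summed over the
pulse ≈ threshold requires w ≈ 18); with weight 3 the deeper layers
were silent. Resulting per-layer rates on the synthetic task are
roughly 65 / 12 / 2 Hz.

## 4. Attention readout

After a sequence, the network state is the concatenation x of the
per-layer trace vectors (L layers × N neurons). The readout computes

    A_deep    = softmax(W_deep x)        (one coefficient per layer)
    X_S       = sum_l A_deep[l] X_l      (collapse layers)
    A_spatial = sigmoid(W_spatial x)     (per-neuron gates)
    y         = sigmoid(W_out (X_S ⊙ A_spatial)),

predicting argmax y. Training minimizes softmax cross-entropy over y by
full-batch gradient descent with analytic gradients (verified against
central finite differences at 1e-5 relative tolerance); the network
state is a constant, so no backpropagation through time occurs.
Optional L2 weight decay is available (off by default).

*Standardization (design decision).* Snapshots are conditioned by a
single **global** scalar shift and scale (mean and standard deviation
over all features), not per-feature z-scoring. Deeper layers are
increasingly sparse; per-feature scaling inflates near-silent units to
unit variance and lets the attention memorize training noise (observed:
train accuracy 1.0, test at chance), while the global variant preserves
relative layer magnitudes and generalizes.

## 5. Synthetic tasks

A generator stands in for video-derived feature sequences. Each sample
is a variable-length sequence of 100-dimensional frames: a
4-dimensional latent signal plus a shared random walk (increment sd
0.05), projected through a fixed random matrix and corrupted with
Gaussian noise (sd 0.2). Sequence lengths are log-normal (log-sd 0.6)
clipped to [30, 650] frames, with the log-location solved numerically
so the clipped mean is exactly 157 — matching the summary statistics of
typical egocentric-video corpora without inventing further structure.

Each motif is a mixture of sinusoids in a motif-specific frequency band
plus a latent mean offset (sd 0.5). The offset is required by the
generator's contract that the "motif" variant be separable from
time-averaged features by a linear model: pure zero-mean sinusoid
mixtures are not (measured at chance).

Two variants:

- **motif** — each class has its own motif; time averages are
  informative, so a memoryless baseline is competitive.
- **order** — all classes share the same motifs and differ only in
  their cyclic order over three equal segments; the offsets cancel in
  whole-sequence averages, so a memoryless model degrades toward chance
  and only temporal integration separates the classes.

The memoryless reference (`baselines.py`) is logistic regression on
time-averaged features. Spike-train toys (delayed recall,
pattern pairs) exercise the reservoir and WTA stages directly.

## 6. Resource model

Closed-form counting for three equal-budget architectures (deep LSM:
three 500-neuron layers with 50-wide WTA encoders and a 500-wide
spatial-attention block; flat LSM and LSTM: one 1,500-neuron layer),
100 inputs, 10 classes. Synapses are grouped by training rule
(backprop / fixed random / unsupervised STDP); per-frame forward- and
backward-pass multiplications follow the standard dense or
density-scaled products; memory is 32 bits per weight; energy uses
45-nm per-operation costs (0.9 pJ add, 3.7 pJ multiply, 360 pJ DRAM
access), one multiply plus one add per counted multiplication.

Two conventions exist for the deep LSM's STDP-trained hidden-to-WTA
projections: "full" (dense matrices, as actually simulated:
(l−1)·H_d·W = 50,000) and "sparse" (input-density-scaled:
(l−1)·S_in·H_d·W = 2,500). Both are reported.

*Density discrepancy.* The nominal recurrent density of the comparison
point is 0.1076 (89.24 % sparsity), which the model treats as an input
parameter. The lattice geometry of §2 with the default constants
actually samples a sparser fabric — measured density ≈ 0.044 for a
500-neuron grid (≈ 0.029 at 1,000) — so `count_synapses_sampled`
reports Monte-Carlo counts from real builds alongside the closed forms,
and the two deliberately differ.

## 7. Noise model

Analog weight storage is emulated at two points: Gaussian **write
noise** applied once to the stored static weights (reservoir, input,
inter-layer, WTA), with magnitudes clamped non-negative since the E/I
sign is structural; and Gaussian **read noise** drawn fresh on each
read of the readout/attention weights at inference. With sigma = 0
both paths are bit-identical to the noise-free code path (asserted in
the tests). Per-read noise inside the per-timestep reservoir loop is
out of scope.

## 8. Reproducibility

One master seed hash-derives an independent sub-seed for every
stochastic stage (`derive_seed(master, label)`, BLAKE2b-based), so
changing one module's seed never perturbs another's stream. The
forward pass is a pure function of (config, seed, inputs); pipeline
artifacts carry a config hash and seed in their manifests.

## 9. Limitations

- The readout trains on final-state snapshots only; no
  backpropagation through time, and no intermediate-state pooling.
- The WTA layer allows at most one winner per millisecond; at high
  input rates this caps the code's information rate.
- Real video/CNN features are out of scope; the synthetic generator
  matches dimensionality and sequence statistics only.
- The energy model counts operations and DRAM accesses with flat
  per-operation costs; it ignores control, SRAM, and data-movement
  overheads.
- Reported accuracies come from small test sets (30 sequences); the
  acceptance suite therefore tests against a binomial significance
  threshold rather than a point estimate.
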