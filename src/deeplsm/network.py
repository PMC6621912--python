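"""Assembly and simulation of the full deep liquid state machine.

The deep LSM is a chain of spiking reservoirs (hidden layers) bridged by
winner-take-all encoding layers; there is always one more hidden layer
than WTA layers.  Per timestep,

* layer 1 is driven by the encoded input plus its own recurrent activity
  of the previous step,
* WTA layer k is driven by the current spike vector of hidden layer k,
* hidden layer l > 1 is driven by the current spike of WTA layer l-1
  (through a sparse random projection) plus its own recurrent history.

Spikes enter LIF pools as 3-ms square current pulses scaled by the
presynaptic short-term-plasticity efficacy in force at spike time.  The
readout never sees raw spikes: each hidden neuron exposes its exponential
synaptic trace, and the concatenated per-layer traces form the network
state snapshot ``x_deep`` consumed by the attention readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurodynamics import (
    LIFParams,
    NeuronPopulationState,
    PulseBuffer,
    STPParams,
    TraceParams,
    lif_step,
    stp_update,
    trace_update,
)
from .plasticity import STDPParams
from .reservoir import (
    ConnectivityParams,
    GridSpec,
    SynapseSet,
    build_grid,
    connect_input,
    connect_recurrent,
    normalize_synapses,
    perturb_weights,
    primary_mask,
)
from .wta_layer import WTALayer, wta_step

__all__ = ["DeepLSMConfig", "DeepState", "InputEncoder", "DeepLSM", "derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """Deterministically derive a sub-seed below 2**31 from a master seed.

    Hash-based derivation isolates each stochastic stage: changing the
    seed of one module never perturbs another's random stream.
    """
    import hashlib

    digest = hashlib.blake2b(
        f"{master}/{label}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


# default current-to-potential gain: a simultaneous volley of ~6
# excitatory strength-3 pulses at full efficacy reaches threshold from
# rest within the 3-ms pulse window:
# 16.5 / (6 * 3 * (1 - (1 - 1/28)**3)) ~= 8.87
DEFAULT_KAPPA = 8.87


@dataclass(frozen=True)
class DeepLSMConfig:
    """Architecture and all dynamical parameters of a deep LSM.

    ``hidden_sizes`` lists the reservoir sizes (L entries); ``wta_sizes``
    the widths of the L-1 encoding layers in between.  A single hidden
    layer yields a standard (flat) LSM — no WTA layers.
    """

    n_inputs: int = 100
    hidden_sizes: tuple[int, ...] = (500, 500, 500)
    wta_sizes: tuple[int, ...] = (50, 50)
    lif: LIFParams = field(default_factory=LIFParams)
    stp: STPParams = field(default_factory=STPParams)
    trace: TraceParams = field(default_factory=TraceParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    wta_scale_target: float = 15.0
    # sized so typical reservoir activity (a few percent of neurons
    # spiking) drives the winner several-fold past threshold within the
    # 4-ms refractory cadence
    wta_gain: float = 120.0
    kappa: float = DEFAULT_KAPPA
    input_encoding: str = "current"  # "current" | "poisson"
    max_rate_hz: float = 200.0
    frame_duration_ms: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("at least one hidden layer is required")
        if len(self.wta_sizes) != len(self.hidden_sizes) - 1:
            raise ValueError(
                "need exactly one fewer WTA layer than hidden layers "
                f"({len(self.hidden_sizes)} hidden -> "
                f"{len(self.hidden_sizes) - 1} WTA)"
            )
        if self.input_encoding not in ("current", "poisson"):
            raise ValueError("input_encoding must be 'current' or 'poisson'")
        if self.frame_duration_ms < 1:
            raise ValueError("frame_duration_ms must be >= 1")

    @property
    def n_layers(self) -> int:
        return len(self.hidden_sizes)

    @classmethod
    def preset(cls, name: str, **overrides) -> "DeepLSMConfig":
        """Named reference configurations.

        ``"table2"``: three 1,000-neuron hidden layers with 50-neuron WTA
        layers (the headline simulation sizing).  ``"sec41"``: three
        500-neuron hidden layers with 50-neuron WTA layers (the sizing of
        the cost analysis).
        """
        if name == "table2":
            base = dict(hidden_sizes=(1000, 1000, 1000), wta_sizes=(50, 50))
        elif name == "sec41":
            base = dict(hidden_sizes=(500, 500, 500), wta_sizes=(50, 50))
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)


class InputEncoder:
    """Maps feature frames onto input-layer activity.

    ``fit`` learns per-dimension min/max on training sequences; encoded
    values are clipped to [0, 1].  Mode ``"current"`` delivers the
    normalized value as a constant drive for the frame's duration
    (deterministic); mode ``"poisson"`` draws spikes at a rate
    proportional to the value (up to ``max_rate_hz``), seeded.
    """

    def __init__(self, mode: str = "current", max_rate_hz: float = 200.0,
                 dt_ms: float = 1.0):
        if mode not in ("current", "poisson"):
            raise ValueError("mode must be 'current' or 'poisson'")
        self.mode = mode
        self.max_rate_hz = float(max_rate_hz)
        self.dt_ms = float(dt_ms)
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None

    def fit(self, sequences) -> "InputEncoder":
        frames = np.concatenate([np.atleast_2d(s) for s in sequences], axis=0)
        self.lo = frames.min(axis=0)
        self.hi = frames.max(axis=0)
        return self

    def normalize(self, frame: np.ndarray) -> np.ndarray:
        if self.lo is None or self.hi is None:
            raise RuntimeError("encoder must be fitted before use")
        frame = np.asarray(frame, dtype=float)
        if not np.all(np.isfinite(frame)):
            raise ValueError("features must be finite")
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((frame - self.lo) / span, 0.0, 1.0)

    def encode(self, frame: np.ndarray, rng: np.random.Generator | None = None
               ) -> np.ndarray:
        u = self.normalize(frame)
        if self.mode == "current":
            return u
        if rng is None:
            raise ValueError("poisson encoding requires an RNG")
        p = u * self.max_rate_hz * self.dt_ms / 1000.0
        return (rng.random(u.shape) < p).astype(float)


@dataclass
class DeepState:
    """Snapshot of the network after a sequence.

    ``spikes``/``traces`` hold the final per-layer vectors; ``x_deep`` is
    the concatenated trace snapshot read by the attention network.
    """

    spikes: list
    traces: list

    @property
    def x_deep(self) -> np.ndarray:
        return np.concatenate(self.traces)


class _HiddenLayer:
    """One reservoir: topology, neuron state, and open-pulse bookkeeping."""

    def __init__(self, recurrent: SynapseSet, feed: SynapseSet):
        self.recurrent = recurrent
        self.feed = feed
        self.rec_matrix = recurrent.drive_matrix()
        self.feed_matrix = feed.drive_matrix()
        n = recurrent.n_post
        self.state = NeuronPopulationState.zeros(n)
        self.rec_buffer = PulseBuffer(n)
        self.feed_buffer = PulseBuffer(feed.n_pre)

    def reset(self) -> None:
        self.state = NeuronPopulationState.zeros(self.recurrent.n_post)
        self.rec_buffer.clear()
        self.feed_buffer.clear()

    def refresh_matrices(self) -> None:
        self.recurrent.invalidate()
        self.feed.invalidate()
        self.rec_matrix = self.recurrent.drive_matrix()
        self.feed_matrix = self.feed.drive_matrix()


class DeepLSM:
    """A constructed deep LSM: stacked reservoirs + WTA encoders.

    The forward pass is a pure function of (config, seed, inputs): all
    topology sampling and any stochastic encoding derive from the
    config's master seed.
    """

    def __init__(self, config: DeepLSMConfig):
        self.config = config
        conn = config.connectivity
        self.layers: list[_HiddenLayer] = []
        self.wtas: list[WTALayer] = []

        for l, size in enumerate(config.hidden_sizes):
            gspec = GridSpec.from_size(size, seed=derive_seed(config.seed, f"grid{l}"))
            positions, labels = build_grid(gspec)
            rec = connect_recurrent(
                positions, labels, conn, seed=derive_seed(config.seed, f"rec{l}")
            )
            rec = normalize_synapses(rec, conn.norm_targets)
            n_pre = config.n_inputs if l == 0 else config.wta_sizes[l - 1]
            feed = connect_input(
                n_pre,
                size,
                conn.input_sparsity,
                seed=derive_seed(config.seed, f"feed{l}"),
                weight=conn.input_weight if l == 0 else conn.interlayer_weight,
                projection="input" if l == 0 else "inter-layer",
            )
            self.layers.append(_HiddenLayer(rec, feed))
            self.grids = getattr(self, "grids", [])
            self.grids.append((positions, labels))

        for k, w in enumerate(config.wta_sizes):
            self.wtas.append(
                WTALayer.create(
                    n_pre=config.hidden_sizes[k],
                    n_neurons=w,
                    seed=derive_seed(config.seed, f"wta{k}"),
                    lif=config.lif,
                    stdp=config.stdp,
                    scale_target=config.wta_scale_target,
                    gain=config.wta_gain,
                )
            )

        self.encoder = InputEncoder(
            config.input_encoding, config.max_rate_hz, config.lif.dt
        )
        self.last_wta_winners: list[list[int]] = [[] for _ in self.wtas]

    # -- state management -------------------------------------------------

    def reset_state(self) -> None:
        """Zero membranes, traces, and open pulses; restore STP to 1."""
        for layer in self.layers:
            layer.reset()
        for wta in self.wtas:
            wta.reset()
        self.last_wta_winners = [[] for _ in self.wtas]

    @property
    def primary_masks(self) -> list[np.ndarray]:
        return [primary_mask(layer.feed) for layer in self.layers]

    def snapshot(self) -> DeepState:
        return DeepState(
            spikes=[layer.state.spiked.copy() for layer in self.layers],
            traces=[layer.state.trace.copy() for layer in self.layers],
        )

    # -- simulation --------------------------------------------------------

    def step(self, u_n: np.ndarray) -> DeepState:
        """Advance the whole network one millisecond.

        ``u_n`` is the encoded input of this step: normalized feature
        values (current mode, applied as constant drive) or an input
        spike vector (Poisson mode, opening 3-ms pulses).
        """
        cfg = self.config
        u_n = np.asarray(u_n, dtype=float)
        if u_n.shape != (cfg.n_inputs,):
            raise ValueError(
                f"encoded input length {u_n.shape} does not match n_inputs "
                f"({cfg.n_inputs},)"
            )
        for l, layer in enumerate(self.layers):
            drive = cfg.kappa * (layer.rec_matrix @ layer.rec_buffer.active())
            if l == 0:
                if cfg.input_encoding == "current":
                    drive = drive + cfg.kappa * (layer.feed_matrix @ u_n)
                else:
                    layer.feed_buffer.push(u_n)
                    drive = drive + cfg.kappa * (
                        layer.feed_matrix @ layer.feed_buffer.active()
                    )
            else:
                drive = drive + cfg.kappa * (
                    layer.feed_matrix @ layer.feed_buffer.active()
                )

            prev = layer.state
            new = lif_step(prev, drive, cfg.lif)
            # a spike's pulse carries the efficacy in force when it fired
            layer.rec_buffer.push(new.spiked * prev.stp_s)
            new.stp_s = stp_update(prev.stp_s, new.spiked, cfg.stp)
            new.trace = trace_update(prev.trace, new.spiked, cfg.trace, cfg.lif.dt)
            layer.state = new

            if l < len(self.wtas):
                wta = self.wtas[l]
                winner = wta_step(
                    wta,
                    new.spiked.astype(float),
                    pre_traces=new.trace if wta.training else None,
                )
                onehot = np.zeros(wta.n_neurons)
                if winner is not None:
                    onehot[winner] = 1.0
                    self.last_wta_winners[l].append(winner)
                self.layers[l + 1].feed_buffer.push(onehot)
        return self.snapshot()

    def run_sequence(
        self,
        features: np.ndarray,
        frame_duration_ms: int | None = None,
        reset: bool = True,
        seed: int = 0,
    ) -> DeepState:
        """Present a (frames x features) sequence and return the final state.

        Each frame is held for ``frame_duration_ms`` steps (Poisson mode
        redraws spikes every step).  With ``reset`` the network starts
        from the zero state, treating sequences as independent samples.
        """
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[0] == 0:
            raise ValueError("empty sequence")
        if reset:
            self.reset_state()
        duration = frame_duration_ms or self.config.frame_duration_ms
        rng = (
            np.random.default_rng(derive_seed(seed, "poisson"))
            if self.config.input_encoding == "poisson"
            else None
        )
        state = self.snapshot()
        for frame in features:
            for _ in range(duration):
                u = self.encoder.encode(frame, rng)
                state = self.step(u)
        return state

    def run_dataset(self, sequences, seed: int = 0) -> np.ndarray:
        """Stack the final ``x_deep`` snapshots of many sequences."""
        return np.stack(
            [
                self.run_sequence(s, reset=True, seed=derive_seed(seed, f"seq{i}")).x_deep
                for i, s in enumerate(sequences)
            ]
        )

    # -- training ----------------------------------------------------------

    def train_wta_layers(self, sequences, epochs_per_layer: int = 1,
                         seed: int = 0) -> "DeepLSM":
        """Greedy layer-wise STDP training of the WTA encoders.

        WTA layer k trains while all earlier encoders are frozen;
        reservoir weights never change.  Returns the network with every
        training flag off.
        """
        for k in range(len(self.wtas)):
            for wta in self.wtas:
                wta.training = False
            self.wtas[k].training = True
            for epoch in range(epochs_per_layer):
                for i, s in enumerate(sequences):
                    self.run_sequence(
                        s, reset=True,
                        seed=derive_seed(seed, f"wta{k}e{epoch}s{i}"),
                    )
        for wta in self.wtas:
            wta.training = False
        return self

    # -- noise injection ----------------------------------------------------

    def apply_weight_noise(self, sigma_write: float, seed: int,
                           w_scale: float = 1.0) -> "DeepLSM":
        """Perturb every stored static weight with Gaussian write noise.

        Emulates imprecise programming of an analog weight memory.  With
        ``sigma_write = 0`` the network is untouched.
        """
        if sigma_write == 0:
            return self
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.recurrent = perturb_weights(layer.recurrent, sigma_write, rng, w_scale)
            layer.feed = perturb_weights(layer.feed, sigma_write, rng, w_scale)
            layer.refresh_matrices()
        for wta in self.wtas:
            noisy = wta.weights + rng.normal(0.0, sigma_write * abs(w_scale),
                                             wta.weights.shape)
            wta.weights = np.maximum(noisy, 0.0)
        return self

    # -- diagnostics ---------------------------------------------------------

    def firing_rates(self, sequences, seed: int = 0) -> list[float]:
        """Mean per-neuron firing rate (spikes/ms) of each hidden layer."""
        counts = [0.0 for _ in self.layers]
        steps = 0
        for i, s in enumerate(sequences):
            self.reset_state()
            features = np.atleast_2d(np.asarray(s, dtype=float))
            rng = (
                np.random.default_rng(derive_seed(seed, f"fr{i}"))
                if self.config.input_encoding == "poisson"
                else None
            )
            for frame in features:
                for _ in range(self.config.frame_duration_ms):
                    st = self.step(self.encoder.encode(frame, rng))
                    for l, sp in enumerate(st.spikes):
                        counts[l] += float(np.mean(sp))
                    steps += 1
        return [c / steps for c in counts]
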