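"""Spiking winner-take-all encoding layer.

A WTA layer receives the current spike vector of a reservoir through a
dense, non-negative weight matrix and lets at most one neuron fire per
timestep: among the neurons crossing their (homeostatically adapted)
threshold, the one with the highest membrane potential wins, emits the
sole spike, and globally inhibits the rest by resetting every competitor
to rest within the same step.  In training mode each win triggers the
pre-trace STDP update, synaptic scaling of the winner's incoming weights,
and an intrinsic-plasticity threshold bump, so the layer self-organizes
into a low-dimensional feature code of the reservoir's activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurodynamics import LIFParams
from .plasticity import (
    IntrinsicParams,
    IntrinsicState,
    STDPParams,
    intrinsic_update,
    stdp_update,
    synaptic_scale,
)

__all__ = ["WTALayer", "wta_step", "encode_sequence"]


@dataclass
class WTALayer:
    """State and parameters of one winner-take-all layer.

    ``weights`` is the dense incoming matrix, shape (n_pre, n_neurons),
    kept non-negative; each column is scaled to ``scale_target`` at
    initialization and after every STDP update.
    """

    weights: np.ndarray
    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    intrinsic: IntrinsicState = None  # type: ignore[assignment]
    scale_target: float = 15.0
    gain: float = 120.0
    training: bool = False
    v: np.ndarray = None  # type: ignore[assignment]
    refractory_remaining: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_neurons
        if self.intrinsic is None:
            self.intrinsic = IntrinsicState.zeros(
                n, IntrinsicParams(v_th_base=self.lif.v_th, dt=self.lif.dt)
            )
        if self.v is None:
            self.v = np.full(n, self.lif.v_rest, dtype=float)
        if self.refractory_remaining is None:
            self.refractory_remaining = np.zeros(n)

    @property
    def n_pre(self) -> int:
        return self.weights.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def create(
        cls,
        n_pre: int,
        n_neurons: int,
        seed: int,
        lif: LIFParams | None = None,
        stdp: STDPParams | None = None,
        scale_target: float = 15.0,
        gain: float = 120.0,
    ) -> "WTALayer":
        """Fresh layer with uniform-random weights scaled to the target sum.

        Starting already on the synaptic-scaling manifold keeps the first
        STDP updates consistent with every later one.
        """
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.0, 1.0, size=(n_pre, n_neurons))
        w *= scale_target / w.sum(axis=0, keepdims=True)
        return cls(
            weights=w,
            lif=lif or LIFParams(),
            stdp=stdp or STDPParams(),
            scale_target=scale_target,
            gain=gain,
        )

    def reset(self) -> None:
        """Return membrane state to rest (weights and thresholds persist)."""
        self.v = np.full(self.n_neurons, self.lif.v_rest, dtype=float)
        self.refractory_remaining = np.zeros(self.n_neurons)


def wta_step(
    layer: WTALayer,
    presyn_spikes: np.ndarray,
    pre_traces: np.ndarray | None = None,
) -> int | None:
    """Advance the WTA layer one timestep; return the winner index or None.

    All neurons integrate the drive ``gain * W^T x(n)`` with their
    individual effective thresholds ``v_th_base + theta``.  If any neuron
    is supra-threshold, the one with the highest membrane potential wins
    (ties break to the lowest index), and every membrane potential is
    reset to rest — global inhibition at 1-ms resolution.  In training
    mode the winner's incoming weights receive the STDP + scaling update
    (requiring ``pre_traces``) and all thresholds take an intrinsic-
    plasticity step.
    """
    x = np.asarray(presyn_spikes, dtype=float)
    if x.shape != (layer.n_pre,):
        raise ValueError(
            f"presynaptic vector length {x.shape} does not match layer fan-in "
            f"({layer.n_pre},)"
        )
    p = layer.lif
    drive = layer.gain * (layer.weights.T @ x)

    refractory = layer.refractory_remaining > 0
    v_int = layer.v + (p.dt / p.tau_m) * (-layer.v + drive)
    v_new = np.where(refractory, p.v_rest, v_int)
    threshold = layer.intrinsic.effective_threshold
    supra = (~refractory) & (v_new >= threshold)

    winner: int | None = None
    if supra.any():
        # highest membrane potential among supra-threshold neurons wins;
        # argmax resolves exact ties to the lowest index
        masked = np.where(supra, v_new, -np.inf)
        winner = int(np.argmax(masked))
        v_new = np.full_like(v_new, p.v_rest)  # global inhibition resets all
        refr_new = np.maximum(layer.refractory_remaining - p.dt, 0.0)
        refr_new[winner] = p.tau_ref
    else:
        refr_new = np.maximum(layer.refractory_remaining - p.dt, 0.0)

    layer.v = v_new
    layer.refractory_remaining = refr_new

    if layer.training:
        spiked = np.zeros(layer.n_neurons)
        if winner is not None:
            if pre_traces is None:
                raise ValueError("training mode requires presynaptic traces")
            w = stdp_update(layer.weights[:, winner], pre_traces, layer.stdp)
            layer.weights[:, winner] = synaptic_scale(w, layer.scale_target)
            spiked[winner] = 1.0
        layer.intrinsic = intrinsic_update(layer.intrinsic, spiked)
    return winner


def encode_sequence(layer: WTALayer, reservoir_spike_raster: np.ndarray) -> np.ndarray:
    """Encode a reservoir spike raster (timesteps x neurons) through the WTA.

    Inference-mode map: training must be off, weights and thresholds are
    fixed, and the output raster has at most one active unit per row.
    Deterministic given weights and inputs.
    """
    if layer.training:
        raise ValueError("encode_sequence requires training mode off")
    raster = np.atleast_2d(np.asarray(reservoir_spike_raster))
    layer.reset()
    out = np.zeros((raster.shape[0], layer.n_neurons), dtype=np.int8)
    for t, row in enumerate(raster):
        winner = wta_step(layer, row)
        if winner is not None:
            out[t, winner] = 1
    return out
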