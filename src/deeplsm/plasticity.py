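"""Local plasticity rules training the winner-take-all encoding layers.

Three mechanisms cooperate:

* trace-based STDP — when a winner-take-all neuron fires, each of its
  incoming weights moves by ``eta * (X_pre - X_tar)``: presynaptic
  neurons whose recent activity (trace) exceeds the target level are
  potentiated, quiet ones depressed (pre-trace-only rule);
* synaptic scaling — the winner's incoming weight sum is renormalized to
  a fixed target after every update, preventing runaway potentiation
  while preserving the Hebbian ordering;
* intrinsic plasticity — each spike raises the neuron's firing threshold
  by a homeostatic offset that decays exponentially, spreading wins
  across the layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "STDPParams",
    "IntrinsicParams",
    "IntrinsicState",
    "CollapsedNeuronError",
    "stdp_update",
    "synaptic_scale",
    "intrinsic_update",
]


class CollapsedNeuronError(RuntimeError):
    """Raised when a neuron's incoming weights have all collapsed to zero.

    Scaling such a row is undefined; the caller is told rather than the
    row being silently re-inflated.
    """


@dataclass(frozen=True)
class STDPParams:
    """Pre-trace STDP rule parameters.

    ``x_tar`` is the presynaptic-trace level separating potentiation from
    depression (reference range 25-50); ``eta`` the step magnitude.  The
    default step is small relative to the scaled weight magnitude
    (target sum / fan-in), so one depression event shifts a weight
    gradually instead of flooring a whole column at once.
    """

    eta: float = 2e-4
    x_tar: float = 25.0
    w_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not self.x_tar > 0:
            raise ValueError("x_tar must be positive")


@dataclass(frozen=True)
class IntrinsicParams:
    """Homeostatic threshold adaptation parameters.

    On each spike the offset theta jumps by ``theta_inc`` (mV) and decays
    toward zero with time constant ``tau_theta`` (ms); the effective
    firing threshold is ``v_th_base + theta``.
    """

    v_th_base: float = 16.5
    theta_inc: float = 1.5
    tau_theta: float = 500.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_inc < 0:
            raise ValueError("theta_inc must be non-negative")
        if not self.tau_theta > 0:
            raise ValueError("tau_theta must be positive")


@dataclass
class IntrinsicState:
    """Per-neuron homeostatic threshold offsets."""

    theta: np.ndarray
    params: IntrinsicParams

    @classmethod
    def zeros(cls, n: int, params: IntrinsicParams | None = None) -> "IntrinsicState":
        return cls(theta=np.zeros(n), params=params or IntrinsicParams())

    @property
    def effective_threshold(self) -> np.ndarray:
        return self.params.v_th_base + self.theta


def stdp_update(
    weights_into_winner: np.ndarray,
    pre_traces: np.ndarray,
    params: STDPParams,
) -> np.ndarray:
    """Apply the pre-trace STDP step to the winner's incoming weights.

    ``W' = max(W + eta * (X_pre - X_tar), w_min)``.  Invoked only when a
    postsynaptic neuron fires; depression arises from the same rule when
    the presynaptic trace sits below target.
    """
    w = np.asarray(weights_into_winner, dtype=float)
    x = np.asarray(pre_traces, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights and presynaptic traces must have equal length")
    return np.maximum(w + params.eta * (x - params.x_tar), params.w_min)


def synaptic_scale(weights_into_neuron: np.ndarray, target_sum: float) -> np.ndarray:
    """Rescale a neuron's incoming weights so they sum to ``target_sum``.

    Proportional rescale: relative ordering is preserved exactly.  An
    all-zero row signals a collapsed neuron and raises
    :class:`CollapsedNeuronError` instead of being silently re-inflated.
    """
    w = np.asarray(weights_into_neuron, dtype=float)
    total = w.sum()
    if total <= 0:
        raise CollapsedNeuronError(
            "all incoming weights are zero; cannot scale a collapsed neuron"
        )
    return w * (target_sum / total)


def intrinsic_update(state: IntrinsicState, spiked: np.ndarray) -> IntrinsicState:
    """One homeostasis step: exponential decay plus spike-triggered jump.

    ``theta' = theta * exp(-dt/tau) + theta_inc * x``; with no spikes the
    offset follows the analytic exponential exactly.
    """
    p = state.params
    theta = state.theta * np.exp(-p.dt / p.tau_theta) + p.theta_inc * np.asarray(
        spiked, dtype=float
    )
    return replace(state, theta=theta)
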