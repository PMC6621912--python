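"""Single-timestep update rules for populations of leaky integrate-and-fire neurons.

The reservoir neurons follow the classic LIF membrane equation

    tau_m * dV/dt = -V + I * R

integrated with forward Euler at a fixed 1-ms timestep.  A presynaptic
spike injects a square pulse of current (magnitude proportional to the
synaptic strength) for the 3 ms following the spike.  Two per-neuron
auxiliary variables accompany the membrane state:

* a short-term-plasticity efficacy ``S`` in [0, 1] that scales the
  neuron's outgoing pulse amplitude and moves by a constant step
  ``S' = S - alpha * (x - beta)`` (linearized short-term plasticity);
* a synaptic trace ``X`` that increments by one on each spike and decays
  exponentially with time constant ``tau_trace``; the traces are the
  features seen by the readout and the eligibility signal for STDP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LIFParams",
    "STPParams",
    "TraceParams",
    "NeuronPopulationState",
    "PulseBuffer",
    "lif_step",
    "psc_drive",
    "stp_update",
    "trace_update",
]

#: duration (ms) of the square post-synaptic current pulse after a spike
PSC_PULSE_MS = 3


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire membrane parameters.

    Defaults are the reference operating point: 16.5 mV threshold, 28 ms
    membrane time constant, 4 ms refractory period, 1 ms timestep, rest
    at 0 mV.
    """

    v_th: float = 16.5
    tau_m: float = 28.0
    tau_ref: float = 4.0
    v_rest: float = 0.0
    dt: float = 1.0
    #: membrane resistance entering I*R; currents are already expressed as
    #: potentials (mV) throughout, so this stays 1 unless a user models
    #: explicit currents.
    r_mem: float = 1.0

    def __post_init__(self) -> None:
        if not self.v_th > self.v_rest:
            raise ValueError("v_th must exceed v_rest")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class STPParams:
    """Linearized short-term plasticity: constant-step efficacy update."""

    alpha: float = 0.007
    beta: float = 0.739

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class TraceParams:
    """Exponentially decaying spike-count trace."""

    tau_trace: float = 300.0

    def __post_init__(self) -> None:
        if not self.tau_trace > 0:
            raise ValueError("tau_trace must be positive")


@dataclass
class NeuronPopulationState:
    """Per-neuron state of one layer.

    Attributes
    ----------
    v : membrane potentials (mV)
    refractory_remaining : refractory countdown (ms), 0 when excitable
    spiked : binary spike flags x(n) of the current step
    stp_s : short-term-plasticity efficacies in [0, 1]
    trace : synaptic traces (dimensionless spike counts)
    """

    v: np.ndarray
    refractory_remaining: np.ndarray
    spiked: np.ndarray
    stp_s: np.ndarray
    trace: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "NeuronPopulationState":
        """Resting state: V at rest, fully recovered efficacy, empty traces."""
        return cls(
            v=np.zeros(n),
            refractory_remaining=np.zeros(n),
            spiked=np.zeros(n, dtype=np.int8),
            stp_s=np.ones(n),
            trace=np.zeros(n),
        )

    @property
    def n(self) -> int:
        return self.v.shape[0]

    def validate(self) -> None:
        n = self.n
        for name in ("refractory_remaining", "spiked", "stp_s", "trace"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"state field {name!r} has mismatched length")
        if np.any(self.stp_s < 0) or np.any(self.stp_s > 1):
            raise ValueError("stp_s must lie in [0, 1]")
        if np.any(self.trace < 0):
            raise ValueError("trace must be non-negative")
        if np.any(self.refractory_remaining < 0):
            raise ValueError("refractory_remaining must be non-negative")


def lif_step(
    state: NeuronPopulationState,
    input_drive: np.ndarray,
    params: LIFParams,
    v_th: np.ndarray | float | None = None,
) -> NeuronPopulationState:
    """Advance the membrane equation one Euler step and emit spikes.

    Non-refractory neurons integrate ``V <- V + (dt/tau_m) * (-V + drive)``;
    a neuron reaching threshold spikes, resets to rest and becomes
    refractory for ``tau_ref`` ms.  Refractory neurons are clamped at rest
    and only count down.

    Parameters
    ----------
    v_th : optional per-neuron effective threshold overriding
        ``params.v_th`` (used by winner-take-all layers whose intrinsic
        plasticity raises thresholds individually).

    Returns a new state; ``stp_s`` and ``trace`` are carried over untouched
    (they have their own update rules).
    """
    input_drive = np.asarray(input_drive, dtype=float)
    if input_drive.shape != state.v.shape:
        raise ValueError(
            f"input_drive length {input_drive.shape} does not match "
            f"population size {state.v.shape}"
        )
    if not np.all(np.isfinite(input_drive)):
        raise ValueError("input_drive must be finite")
    threshold = params.v_th if v_th is None else v_th

    refractory = state.refractory_remaining > 0
    v_int = state.v + (params.dt / params.tau_m) * (-state.v + input_drive)
    v_new = np.where(refractory, params.v_rest, v_int)
    spiked = (~refractory) & (v_new >= threshold)

    v_new = np.where(spiked, params.v_rest, v_new)
    refr_new = np.where(
        spiked,
        params.tau_ref,
        np.maximum(state.refractory_remaining - params.dt, 0.0),
    )
    return replace(
        state,
        v=v_new,
        refractory_remaining=refr_new,
        spiked=spiked.astype(np.int8),
    )


class PulseBuffer:
    """Ring buffer of recent presynaptic pulse amplitudes.

    Each spike opens a square current pulse lasting ``PSC_PULSE_MS``
    timesteps.  ``push`` records the per-neuron pulse amplitudes released
    this step (spike flags already multiplied by the efficacy in force);
    ``active`` sums the amplitudes of all pulses still open, so
    overlapping pulses from the same neuron superpose linearly.
    """

    def __init__(self, n_neurons: int, duration: int = PSC_PULSE_MS):
        if duration < 0:
            raise ValueError("pulse duration must be non-negative")
        self.duration = int(duration)
        self._slots: list[np.ndarray] = [
            np.zeros(n_neurons) for _ in range(self.duration)
        ]

    def push(self, amplitudes: np.ndarray) -> None:
        self._slots.insert(0, np.asarray(amplitudes, dtype=float))
        del self._slots[self.duration:]

    def active(self) -> np.ndarray:
        """Summed amplitude of all pulses open at the current step."""
        return np.sum(self._slots, axis=0)

    def clear(self) -> None:
        self._slots = [np.zeros_like(s) for s in self._slots]


def psc_drive(
    recent_spikes: np.ndarray,
    synapses,
    recent_stp: np.ndarray | None = None,
    kappa: float = 1.0,
) -> np.ndarray:
    """Summed square-pulse drive (mV) onto each postsynaptic neuron.

    Parameters
    ----------
    recent_spikes : array (k, n_pre), k <= 3
        Spike flags of the last k timesteps, most recent first; each spike
        contributes for exactly the 3 steps following it.
    synapses : SynapseSet or (n_post, n_pre) matrix
        Signed connection weights (inhibitory presynaptic neurons enter
        negatively; ``SynapseSet.drive_matrix`` bakes the sign in).
    recent_stp : array (k, n_pre), optional
        Presynaptic efficacies in force at each of those steps; defaults
        to 1 (no short-term plasticity).
    kappa : global current-to-potential scale.
    """
    recent_spikes = np.atleast_2d(np.asarray(recent_spikes, dtype=float))
    if recent_spikes.shape[0] > PSC_PULSE_MS:
        recent_spikes = recent_spikes[:PSC_PULSE_MS]
    if recent_stp is None:
        recent_stp = np.ones_like(recent_spikes)
    else:
        recent_stp = np.atleast_2d(np.asarray(recent_stp, dtype=float))
        recent_stp = recent_stp[: recent_spikes.shape[0]]
    matrix = synapses.drive_matrix() if hasattr(synapses, "drive_matrix") else synapses
    amplitude = (recent_spikes * recent_stp).sum(axis=0)
    return kappa * (matrix @ amplitude)


def stp_update(
    stp_s: np.ndarray, spiked: np.ndarray, params: STPParams
) -> np.ndarray:
    """Constant-step efficacy update, clamped to [0, 1].

    ``S' = clamp(S - alpha * (x - beta))``: a spike depresses the efficacy
    by ``alpha * (1 - beta)``, silence recovers it by ``alpha * beta``.
    The step never depends on the current efficacy, which is the point of
    the linearized rule.
    """
    s = np.asarray(stp_s, dtype=float) - params.alpha * (
        np.asarray(spiked, dtype=float) - params.beta
    )
    return np.clip(s, 0.0, 1.0)


def trace_update(
    trace: np.ndarray,
    spiked: np.ndarray,
    params: TraceParams,
    dt: float = 1.0,
) -> np.ndarray:
    """Exact exponential trace decay plus unit increment per spike.

    The trace ODE is linear, so the per-step map is computed in closed
    form (``X' = X * exp(-dt/tau) + x``) rather than by Euler — no
    step-size error, and silent decay matches the analytic exponential
    to machine precision.
    """
    decay = np.exp(-dt / params.tau_trace)
    return np.asarray(trace, dtype=float) * decay + np.asarray(spiked, dtype=float)
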