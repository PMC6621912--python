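"""Construction of 3-D grid reservoirs with distance-dependent connectivity.

Neurons are placed on an integer lattice and split 4:1 into excitatory and
inhibitory populations.  A directed recurrent connection from neuron j to
neuron i forms with probability

    P = C_pair * exp(-D(i, j) / lambda)^2

where D is the Euclidean lattice distance and (C, lambda) depend on the
ordered pre/post type pair (EE, EI, IE, II).  Recurrent weights are fixed
per pair type and then normalized so every neuron's summed incoming
excitatory weight (and, separately, inhibitory weight) hits a common
target — homogeneous excitability across the pool.  Input projections are
sparse Bernoulli; neurons receiving at least one input synapse are the
"primary" population, the rest are auxiliary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GridSpec",
    "ConnectivityParams",
    "SynapseSet",
    "build_grid",
    "grid_dims",
    "connect_recurrent",
    "connect_input",
    "normalize_synapses",
    "NoisyWeightStore",
    "perturb_weights",
]

PAIR_TYPES = ("EE", "EI", "IE", "II")


def grid_dims(n: int) -> tuple[int, int, int]:
    """Most-cubic integer factorization of a population size.

    E.g. 1000 -> (10, 10, 10), 500 -> (10, 10, 5).  Chosen by minimizing
    the spread between the largest and smallest factor over all ordered
    3-factorizations.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    best = None
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(m ** 0.5) + 1):
            if m % b:
                continue
            c = m // b
            cand = (a, b, c)
            score = (c - a, c * b)  # minimize spread, then flatness
            if best is None or score < best[0]:
                best = (score, cand)
    assert best is not None
    a, b, c = best[1]
    return (c, b, a)


@dataclass(frozen=True)
class GridSpec:
    """3-D lattice layout and excitatory/inhibitory split of one reservoir."""

    dims: tuple[int, int, int]
    ei_ratio: tuple[int, int] = (4, 1)
    seed: int = 0

    @classmethod
    def from_size(cls, n: int, seed: int = 0) -> "GridSpec":
        return cls(dims=grid_dims(n), seed=seed)

    @property
    def size(self) -> int:
        d = self.dims
        return int(d[0] * d[1] * d[2])

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError("dims must be three positive integers")
        e, i = self.ei_ratio
        if self.size % (e + i):
            raise ValueError(
                f"population size {self.size} not divisible by {e + i} "
                "(exact E:I split impossible)"
            )


@dataclass(frozen=True)
class ConnectivityParams:
    """Distance-dependent recurrent connectivity and projection settings.

    ``c``/``lam`` give the maximum connection probability and distance
    scale per ordered type pair; ``w_fixed`` the fixed synaptic strength
    per pair.  ``norm_targets`` are the per-neuron incoming weight-sum
    targets for excitatory and inhibitory recurrent synapses.
    """

    c: dict = field(
        default_factory=lambda: {"EE": 0.6, "EI": 1.0, "II": 0.2, "IE": 1.0}
    )
    lam: dict = field(
        default_factory=lambda: {"EE": 3.0, "EI": 3.0, "II": 3.0, "IE": 3.0}
    )
    w_fixed: dict = field(
        default_factory=lambda: {"EE": 3.0, "EI": 3.0, "IE": 4.0, "II": 1.0}
    )
    input_sparsity: float = 0.05
    input_weight: float = 3.0
    # WTA->hidden projections carry single sparse spikes; the weight is
    # sized so one pulse lifts a target neuron to threshold (~16.5 mV
    # after 3 Euler steps at the default gain), letting the encoded
    # feature stream ignite the deeper reservoirs.
    interlayer_weight: float = 20.0
    norm_targets: tuple[float, float] = (40.0, 36.0)  # (E, I)

    def __post_init__(self) -> None:
        for pt in PAIR_TYPES:
            if not 0.0 <= self.c[pt] <= 1.0:
                raise ValueError("connection probabilities must lie in [0, 1]")
            if not self.lam[pt] > 0:
                raise ValueError("lambda must be positive")
            if not self.w_fixed[pt] > 0:
                raise ValueError("fixed weights must be positive")
        if not 0.0 <= self.input_sparsity <= 1.0:
            raise ValueError("input_sparsity must lie in [0, 1]")
        if any(t <= 0 for t in self.norm_targets):
            raise ValueError("normalization targets must be positive")


@dataclass
class SynapseSet:
    """Sparse directed weighted connections of one projection.

    ``weight`` holds non-negative magnitudes; ``excitatory`` flags the
    presynaptic sign (inhibitory synapses enter drive computation
    negatively).  ``pair_type`` (recurrent sets only) labels each synapse
    EE/EI/IE/II.
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    excitatory: np.ndarray
    n_pre: int
    n_post: int
    projection: str = "recurrent"
    pair_type: np.ndarray | None = None
    _matrix: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return int(self.pre.shape[0])

    def drive_matrix(self) -> sp.csr_matrix:
        """Signed (n_post, n_pre) CSR matrix for drive computation."""
        if self._matrix is None:
            signed = np.where(self.excitatory, self.weight, -self.weight)
            self._matrix = sp.csr_matrix(
                (signed, (self.post, self.pre)), shape=(self.n_post, self.n_pre)
            )
        return self._matrix

    def invalidate(self) -> None:
        self._matrix = None

    def summary(self) -> dict:
        out = {"projection": self.projection, "n_synapses": len(self)}
        if self.pair_type is not None:
            for pt in PAIR_TYPES:
                out[pt] = int(np.sum(self.pair_type == pt))
        return out


def build_grid(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lattice positions and E/I labels for one reservoir.

    Returns ``(positions, is_excitatory)``: integer (n, 3) coordinates in
    row-major order and a boolean mask with exactly 4/5 of neurons
    excitatory, assignment uniformly random under the spec's seed.
    """
    n = spec.size
    grid = np.indices(spec.dims).reshape(3, n).T.astype(int)
    e, i = spec.ei_ratio
    n_exc = n * e // (e + i)
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=n_exc, replace=False)] = True
    return grid, labels


def connect_recurrent(
    positions: np.ndarray,
    is_excitatory: np.ndarray,
    params: ConnectivityParams,
    seed: int,
) -> SynapseSet:
    """Sample distance-dependent recurrent synapses (no self-connections).

    Each ordered pair (pre j, post i) connects independently with
    probability ``C_pair * exp(-D/lambda)^2``; the weight is the fixed
    strength of the pair type.  The i->j and j->i directions are sampled
    independently.
    """
    n = positions.shape[0]
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff.astype(float) ** 2).sum(axis=-1))  # D[post, pre]

    pre_e = is_excitatory[None, :]
    post_e = is_excitatory[:, None]
    prob = np.empty((n, n))
    wmat = np.empty((n, n))
    masks = {
        "EE": pre_e & post_e,
        "EI": pre_e & ~post_e,
        "IE": ~pre_e & post_e,
        "II": ~pre_e & ~post_e,
    }
    for pt, mask in masks.items():
        p = params.c[pt] * np.exp(-dist / params.lam[pt]) ** 2
        prob = np.where(mask, p, prob)
        wmat = np.where(mask, params.w_fixed[pt], wmat)
    np.fill_diagonal(prob, 0.0)

    rng = np.random.default_rng(seed)
    conn = rng.random((n, n)) < prob
    post, pre = np.nonzero(conn)
    pair = np.where(
        is_excitatory[pre],
        np.where(is_excitatory[post], "EE", "EI"),
        np.where(is_excitatory[post], "IE", "II"),
    )
    return SynapseSet(
        pre=pre,
        post=post,
        weight=wmat[post, pre].copy(),
        excitatory=is_excitatory[pre].copy(),
        n_pre=n,
        n_post=n,
        projection="recurrent",
        pair_type=pair,
    )


def connection_probability(
    distance: float, pair_type: str, params: ConnectivityParams
) -> float:
    """Closed-form connection probability at a given lattice distance."""
    return params.c[pair_type] * np.exp(-distance / params.lam[pair_type]) ** 2


def connect_input(
    n_inputs: int,
    n_post: int,
    input_sparsity: float,
    seed: int,
    weight: float = 3.0,
    projection: str = "input",
) -> SynapseSet:
    """Sparse Bernoulli input projection.

    Every (input, neuron) pair connects independently with probability
    ``input_sparsity``.  All input synapses are excitatory with a fixed
    weight.  Neurons with at least one input synapse form the primary
    population (see :func:`primary_mask`).
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be at least 1")
    if not 0.0 <= input_sparsity <= 1.0:
        raise ValueError("input_sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    conn = rng.random((n_post, n_inputs)) < input_sparsity
    post, pre = np.nonzero(conn)
    return SynapseSet(
        pre=pre,
        post=post,
        weight=np.full(post.shape, float(weight)),
        excitatory=np.ones(post.shape, dtype=bool),
        n_pre=n_inputs,
        n_post=n_post,
        projection=projection,
    )


def primary_mask(input_synapses: SynapseSet) -> np.ndarray:
    """Boolean mask of primary neurons (>= 1 incoming input synapse)."""
    mask = np.zeros(input_synapses.n_post, dtype=bool)
    mask[input_synapses.post] = True
    return mask


def normalize_synapses(
    synapses: SynapseSet,
    norm_targets: tuple[float, float],
) -> SynapseSet:
    """Scale incoming weights so per-neuron E and I sums hit their targets.

    For every postsynaptic neuron, incoming excitatory weights are
    rescaled proportionally so they sum to the excitatory target, and
    incoming inhibitory weights likewise to the inhibitory target.  A
    neuron with no incoming synapse of a class is left unmodified for
    that class.
    """
    target_e, target_i = norm_targets
    weight = synapses.weight.astype(float).copy()
    for target, mask in ((target_e, synapses.excitatory), (target_i, ~synapses.excitatory)):
        if not mask.any():
            continue
        sums = np.bincount(
            synapses.post[mask], weights=weight[mask], minlength=synapses.n_post
        )
        scale = np.ones(synapses.n_post)
        nz = sums > 0
        scale[nz] = target / sums[nz]
        weight[mask] *= scale[synapses.post[mask]]
    out = SynapseSet(
        pre=synapses.pre,
        post=synapses.post,
        weight=weight,
        excitatory=synapses.excitatory,
        n_pre=synapses.n_pre,
        n_post=synapses.n_post,
        projection=synapses.projection,
        pair_type=synapses.pair_type,
    )
    return out


def perturb_weights(synapses: SynapseSet, sigma: float, rng: np.random.Generator,
                    w_scale: float = 1.0) -> SynapseSet:
    """Write-noise: store each weight with additive Gaussian error.

    Models imprecise programming of an analog weight store.  ``sigma = 0``
    returns the magnitudes unchanged (bit-for-bit).  Magnitudes are kept
    non-negative; the E/I sign is structural and unaffected.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return synapses
    noisy = synapses.weight + rng.normal(0.0, sigma * abs(w_scale), synapses.weight.shape)
    return SynapseSet(
        pre=synapses.pre,
        post=synapses.post,
        weight=np.maximum(noisy, 0.0),
        excitatory=synapses.excitatory,
        n_pre=synapses.n_pre,
        n_post=synapses.n_post,
        projection=synapses.projection,
        pair_type=synapses.pair_type,
    )


class NoisyWeightStore:
    """Weight storage with Gaussian read and write noise.

    Emulates an analog (e.g. memristive) weight memory: every ``read``
    returns the stored values plus fresh N(0, sigma_read * |w_scale|)
    noise without mutating storage; every ``write`` stores the new values
    plus N(0, sigma_write * |w_scale|) noise.  With both sigmas zero the
    store is transparent — reads and writes reproduce noise-free
    behavior exactly.
    """

    def __init__(
        self,
        weights: np.ndarray,
        sigma_read: float = 0.0,
        sigma_write: float = 0.0,
        seed: int = 0,
        w_scale: float = 1.0,
    ):
        if sigma_read < 0 or sigma_write < 0:
            raise ValueError("noise sigmas must be non-negative")
        self.sigma_read = float(sigma_read)
        self.sigma_write = float(sigma_write)
        self.w_scale = float(w_scale)
        self._rng = np.random.default_rng(seed)
        self._w = np.array(weights, dtype=float, copy=True)
        if self.sigma_write:
            self._w += self._rng.normal(
                0.0, self.sigma_write * abs(self.w_scale), self._w.shape
            )

    def read(self) -> np.ndarray:
        if self.sigma_read == 0:
            return self._w.copy()
        return self._w + self._rng.normal(
            0.0, self.sigma_read * abs(self.w_scale), self._w.shape
        )

    def write(self, new_weights: np.ndarray) -> None:
        w = np.array(new_weights, dtype=float, copy=True)
        if self.sigma_write:
            w += self._rng.normal(0.0, self.sigma_write * abs(self.w_scale), w.shape)
        self._w = w
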