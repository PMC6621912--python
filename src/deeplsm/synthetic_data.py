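"""Synthetic labeled feature sequences and spike-train toy tasks.

Stands in for CNN-derived video descriptors: each sample is a
variable-length sequence of 100-dimensional feature frames whose class
is carried by a low-dimensional temporal motif (class-specific sinusoid
mixtures plus a shared random walk) projected into the feature space and
corrupted with Gaussian noise.  Sequence lengths follow a log-normal
distribution clipped to [30, 650] frames with its mean solved to 157 —
the summary statistics of typical first-person video corpora.

Two variants exist: ``"motif"`` (classes differ in motif frequencies —
separable even from time-averaged features) and ``"order"`` (classes
share the same motifs and differ only in their temporal order, so
time-averaged features are uninformative and temporal integration is
required).  Spike-train toys (delayed recall, pattern pairs) exercise
the reservoir and WTA stages directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "SyntheticTaskSpec",
    "generate_sequences",
    "generate_spike_toys",
    "solve_lognormal_mu",
    "sample_lengths",
    "write_dataset",
]


def _clipped_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Closed-form mean of a log-normal clipped (not truncated) to [lo, hi]."""
    a, b = (np.log(lo) - mu) / sigma, (np.log(hi) - mu) / sigma
    body = np.exp(mu + sigma**2 / 2) * (norm.cdf(b - sigma) - norm.cdf(a - sigma))
    return lo * norm.cdf(a) + hi * (1 - norm.cdf(b)) + body


def solve_lognormal_mu(mean: float, sigma: float, lo: float, hi: float) -> float:
    """Solve the log-scale location so the clipped distribution has ``mean``."""
    if not lo < mean < hi:
        raise ValueError("target mean must lie strictly inside the length bounds")
    f = lambda mu: _clipped_lognormal_mean(mu, sigma, lo, hi) - mean
    return brentq(f, np.log(lo) - 2, np.log(hi) + 2)


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Class-conditional sequence generator settings."""

    n_classes: int = 3
    n_dims: int = 100
    len_min: int = 30
    len_max: int = 650
    len_mean: float = 157.0
    len_sigma: float = 0.6        # log-scale spread of the length law
    n_latent: int = 4             # latent motif dimensionality
    noise_sd: float = 0.2
    drift_sd: float = 0.05        # shared random-walk increment sd
    offset_sd: float = 0.5        # sd of each motif's latent mean offset
    n_train: int = 60
    n_test: int = 30
    variant: str = "motif"        # "motif" | "order"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not self.len_min < self.len_mean < self.len_max:
            raise ValueError("length mean must lie inside [len_min, len_max]")
        if self.variant not in ("motif", "order"):
            raise ValueError("variant must be 'motif' or 'order'")
        if self.n_train % self.n_classes or self.n_test % self.n_classes:
            raise ValueError("train/test counts must balance across classes")


def sample_lengths(spec: SyntheticTaskSpec, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw n sequence lengths from the clipped log-normal law."""
    mu = solve_lognormal_mu(spec.len_mean, spec.len_sigma,
                            spec.len_min, spec.len_max)
    raw = rng.lognormal(mu, spec.len_sigma, size=n)
    return np.clip(np.round(raw), spec.len_min, spec.len_max).astype(int)


def _motif(t: np.ndarray, bank) -> np.ndarray:
    """Latent motif: sinusoid mixture around a motif-specific mean offset."""
    freqs, phases, offset = bank
    return (
        np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])
        + offset[None, :]
    )


def _class_latents(spec: SyntheticTaskSpec, rng: np.random.Generator):
    """Per-motif (frequency, phase, mean-offset) banks, fixed per dataset.

    Each motif has a distinct frequency band and a latent mean offset —
    a spatial signature in feature space on top of the temporal one.  In
    the ``"order"`` variant the motifs are shared by all classes, so the
    offsets cancel in whole-sequence averages and only the temporal
    order separates the classes.
    """
    banks = []
    for c in range(spec.n_classes):
        # distinct, well-separated frequency band per motif (cycles/frame)
        base = 0.01 * (c + 1)
        freqs = base * (1 + 0.5 * np.arange(spec.n_latent))
        phases = rng.uniform(0, 2 * np.pi, spec.n_latent)
        offset = rng.normal(0, spec.offset_sd, spec.n_latent)
        banks.append((freqs, phases, offset))
    return banks


def _one_sequence(spec, length, label, proj, banks, rng):
    t = np.arange(length, dtype=float)
    if spec.variant == "motif":
        latent = _motif(t, banks[label])
    else:
        # shared motifs, class-specific cyclic order over equal segments
        n_seg = spec.n_classes
        order = np.roll(np.arange(n_seg), -label)
        bounds = np.linspace(0, length, n_seg + 1).astype(int)
        latent = np.zeros((length, spec.n_latent))
        for seg, motif_id in enumerate(order):
            lo, hi = bounds[seg], bounds[seg + 1]
            latent[lo:hi] = _motif(t[lo:hi] - lo, banks[motif_id])
    drift = np.cumsum(rng.normal(0, spec.drift_sd, (length, spec.n_latent)), axis=0)
    features = (latent + drift) @ proj.T
    if spec.noise_sd > 0:
        features = features + rng.normal(0, spec.noise_sd, features.shape)
    return features


def generate_sequences(spec: SyntheticTaskSpec):
    """Generate the train/test dataset.

    Returns ``(train_seqs, train_labels, test_seqs, test_labels)``;
    classes are exactly balanced and everything is a pure function of
    the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    proj = rng.normal(0, 1 / np.sqrt(spec.n_latent),
                      (spec.n_dims, spec.n_latent))
    banks = _class_latents(spec, rng)

    def make(n_total):
        per_class = n_total // spec.n_classes
        labels = np.repeat(np.arange(spec.n_classes), per_class)
        lengths = sample_lengths(spec, n_total, rng)
        seqs = [
            _one_sequence(spec, int(lengths[i]), int(labels[i]), proj, banks, rng)
            for i in range(n_total)
        ]
        return seqs, labels

    train_seqs, train_labels = make(spec.n_train)
    test_seqs, test_labels = make(spec.n_test)
    return train_seqs, train_labels, test_seqs, test_labels


def generate_spike_toys(task: str, params: dict | None = None, seed: int = 0):
    """Spike-train toy datasets for the network's intermediate stages.

    ``"delayed-recall"``: each trial presents one of two Poisson cue
    patterns for ``cue_ms``, followed by ``delay_ms`` of low-rate
    background; the label is the cue identity, probing temporal memory
    (with ``delay_ms = 0`` a memoryless readout suffices — the control).
    ``"pattern-pair"``: trials repeat one of two frozen Poisson template
    rasters, for WTA feature-differentiation tests.

    Returns ``(rasters, labels)`` with rasters (timesteps x channels).
    """
    p = {
        "n_channels": 20,
        "n_trials": 40,
        "cue_ms": 50,
        "delay_ms": 100,
        "cue_rate": 0.2,        # spikes/ms on the active channel group
        "background_rate": 0.01,
        "template_ms": 100,
    }
    p.update(params or {})
    rng = np.random.default_rng(seed)
    n_ch = p["n_channels"]
    labels = np.tile([0, 1], p["n_trials"] // 2 + 1)[: p["n_trials"]]
    rasters = []
    if task == "delayed-recall":
        half = n_ch // 2
        for lab in labels:
            cue = rng.random((p["cue_ms"], n_ch)) < p["background_rate"]
            active = slice(0, half) if lab == 0 else slice(half, n_ch)
            cue[:, active] = rng.random((p["cue_ms"], half)) < p["cue_rate"]
            delay = rng.random((p["delay_ms"], n_ch)) < p["background_rate"]
            rasters.append(np.concatenate([cue, delay]).astype(np.int8))
    elif task == "pattern-pair":
        templates = [
            (rng.random((p["template_ms"], n_ch)) < p["cue_rate"]).astype(np.int8)
            for _ in range(2)
        ]
        rasters = [templates[lab].copy() for lab in labels]
    else:
        raise ValueError("task must be 'delayed-recall' or 'pattern-pair'")
    return rasters, labels


def write_dataset(directory: str | Path, sequences, labels) -> Path:
    """Write one CSV per sequence plus a manifest (path, label, length)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (seq, lab) in enumerate(zip(sequences, labels)):
        path = directory / f"seq_{i:04d}.csv"
        np.savetxt(path, seq, delimiter=",")
        rows.append(f"{path.name},{int(lab)},{seq.shape[0]}")
    manifest = directory / "manifest.csv"
    manifest.write_text("path,label,length\n" + "\n".join(rows) + "\n")
    return manifest
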