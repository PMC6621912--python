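"""Serialization: HDF5 state containers and delimited-text rasters."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .attention_readout import AttentionParams
from .reservoir import SynapseSet

__all__ = [
    "save_raster_text",
    "load_raster_text",
    "save_snapshots",
    "load_snapshots",
    "save_topology",
    "load_topology",
    "save_readout",
    "load_readout",
]


def save_raster_text(path: str | Path, raster: np.ndarray) -> None:
    """Spike raster or trace trajectory as delimited text (rows = timesteps)."""
    np.savetxt(path, np.atleast_2d(raster), delimiter=",", fmt="%.10g")


def load_raster_text(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_snapshots(path: str | Path, snapshots: np.ndarray,
                   labels: np.ndarray, n_layers: int) -> None:
    """Persist deep-state trace snapshots with their labels."""
    with h5py.File(path, "w") as f:
        f.create_dataset("x_deep", data=np.asarray(snapshots))
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        f.attrs["n_layers"] = int(n_layers)


def load_snapshots(path: str | Path):
    with h5py.File(path, "r") as f:
        return f["x_deep"][...], f["labels"][...], int(f.attrs["n_layers"])


def _write_synapses(group: h5py.Group, syn: SynapseSet) -> None:
    group.create_dataset("pre", data=syn.pre)
    group.create_dataset("post", data=syn.post)
    group.create_dataset("weight", data=syn.weight)
    group.create_dataset("excitatory", data=syn.excitatory)
    group.attrs["n_pre"] = syn.n_pre
    group.attrs["n_post"] = syn.n_post
    group.attrs["projection"] = syn.projection


def _read_synapses(group: h5py.Group) -> SynapseSet:
    return SynapseSet(
        pre=group["pre"][...],
        post=group["post"][...],
        weight=group["weight"][...],
        excitatory=group["excitatory"][...],
        n_pre=int(group.attrs["n_pre"]),
        n_post=int(group.attrs["n_post"]),
        projection=str(group.attrs["projection"]),
    )


def save_topology(path: str | Path, net) -> None:
    """Persist a network's positions, labels, sparse projections, and WTA weights."""
    with h5py.File(path, "w") as f:
        for l, layer in enumerate(net.layers):
            g = f.create_group(f"layer{l}")
            pos, labels = net.grids[l]
            g.create_dataset("positions", data=pos)
            g.create_dataset("is_excitatory", data=labels)
            _write_synapses(g.create_group("recurrent"), layer.recurrent)
            _write_synapses(g.create_group("feed"), layer.feed)
        for k, wta in enumerate(net.wtas):
            g = f.create_group(f"wta{k}")
            g.create_dataset("weights", data=wta.weights)
            g.create_dataset("theta", data=wta.intrinsic.theta)


def load_topology(path: str | Path) -> dict:
    """Read a topology container back into plain arrays/SynapseSets."""
    out: dict = {"layers": [], "wtas": []}
    with h5py.File(path, "r") as f:
        l = 0
        while f"layer{l}" in f:
            g = f[f"layer{l}"]
            out["layers"].append(
                {
                    "positions": g["positions"][...],
                    "is_excitatory": g["is_excitatory"][...],
                    "recurrent": _read_synapses(g["recurrent"]),
                    "feed": _read_synapses(g["feed"]),
                }
            )
            l += 1
        k = 0
        while f"wta{k}" in f:
            g = f[f"wta{k}"]
            out["wtas"].append(
                {"weights": g["weights"][...], "theta": g["theta"][...]}
            )
            k += 1
    return out


def save_readout(path: str | Path, params: AttentionParams) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("w_deep", data=params.w_deep)
        f.create_dataset("w_spatial", data=params.w_spatial)
        f.create_dataset("w_out", data=params.w_out)
        if params.mean is not None:
            f.create_dataset("mean", data=params.mean)
            f.create_dataset("scale", data=params.scale)


def load_readout(path: str | Path) -> AttentionParams:
    with h5py.File(path, "r") as f:
        return AttentionParams(
            w_deep=f["w_deep"][...],
            w_spatial=f["w_spatial"][...],
            w_out=f["w_out"][...],
            mean=f["mean"][...] if "mean" in f else None,
            scale=f["scale"][...] if "scale" in f else None,
        )
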