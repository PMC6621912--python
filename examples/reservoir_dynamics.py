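"""Tour of a single spiking reservoir: topology, dynamics, and traces.

Builds one 500-neuron reservoir on a 10 x 10 x 5 lattice, inspects its
distance-dependent connectivity, then drives it with a random feature
sequence and reports firing rates and the synaptic-trace state the
readout would see.

Run:  python examples/reservoir_dynamics.py
"""

import numpy as np

from deeplsm.network import DeepLSM, DeepLSMConfig
from deeplsm.reservoir import (
    ConnectivityParams,
    GridSpec,
    build_grid,
    connect_recurrent,
    connection_probability,
)

# --- connectivity: probability falls off with lattice distance -------------

params = ConnectivityParams()
print("connection probability vs. distance (excitatory -> excitatory):")
for d in range(0, 7):
    print(f"  D = {d}:  P = {connection_probability(d, 'EE', params):.4f}")

spec = GridSpec.from_size(500, seed=0)
positions, is_excitatory = build_grid(spec)
recurrent = connect_recurrent(positions, is_excitatory, params, seed=1)
print(f"\nlattice {spec.dims}, {int(is_excitatory.sum())} excitatory / "
      f"{int((~is_excitatory).sum())} inhibitory neurons")
summary = recurrent.summary()
print("recurrent synapses by pre/post type:",
      {k: summary[k] for k in ('EE', 'EI', 'IE', 'II')})
density = len(recurrent) / (500 * 499)
print(f"overall recurrent density: {density:.4f}")

# --- dynamics: drive a single-reservoir network with random features -------

config = DeepLSMConfig(n_inputs=100, hidden_sizes=(500,), wta_sizes=(),
                       seed=0)
net = DeepLSM(config)
rng = np.random.default_rng(2)
sequence = rng.random((200, 100))  # 200 frames of 100-dim features
net.encoder.fit([sequence])

rate = net.firing_rates([sequence])[0]
print(f"\nmean firing rate over 200 ms: {1000 * rate:.1f} Hz per neuron")

state = net.run_sequence(sequence)
traces = state.traces[0]
print(f"final synaptic traces: mean {traces.mean():.2f}, "
      f"max {traces.max():.2f}, {int((traces > 0).sum())}/500 neurons active")

# traces integrate spike history with a 300-ms time constant: after
# 600 ms of silence the state has decayed by ~e^-2
faded = net.run_sequence(np.zeros((600, 100)), reset=False).traces[0]
print(f"after 600 ms of silence: mean trace {faded.mean():.2f} "
      f"(ratio {faded.mean() / traces.mean():.3f}, e^-2 = {np.exp(-2):.3f})")
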