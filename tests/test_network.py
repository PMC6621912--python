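"""Integration tests for the assembled deep LSM on small configurations."""

import numpy as np
import pytest

from deeplsm.network import (
    DEFAULT_KAPPA,
    DeepLSM,
    DeepLSMConfig,
    InputEncoder,
    derive_seed,
)
from deeplsm.reservoir import ConnectivityParams


def tiny_config(**overrides):
    base = dict(
        n_inputs=10,
        hidden_sizes=(50, 50),
        wta_sizes=(10,),
        seed=0,
    )
    base.update(overrides)
    return DeepLSMConfig(**base)


def random_sequence(frames, dims, seed):
    return np.random.default_rng(seed).random((frames, dims))


def fitted_net(config, seqs):
    net = DeepLSM(config)
    net.encoder.fit(seqs)
    return net


class TestDeriveSeed:
    def test_deterministic_and_bounded(self):
        a = derive_seed(42, "grid0")
        assert a == derive_seed(42, "grid0")
        assert 0 <= a < 2**31

    def test_labels_isolate_streams(self):
        assert derive_seed(42, "grid0") != derive_seed(42, "grid1")
        assert derive_seed(42, "grid0") != derive_seed(43, "grid0")


class TestConfig:
    def test_layer_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DeepLSMConfig(hidden_sizes=(50, 50), wta_sizes=())

    def test_unknown_encoding_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(input_encoding="rate")

    def test_presets(self):
        assert DeepLSMConfig.preset("table2").hidden_sizes == (1000,) * 3
        assert DeepLSMConfig.preset("sec41").hidden_sizes == (500,) * 3
        with pytest.raises(ValueError):
            DeepLSMConfig.preset("nope")


class TestInputEncoder:
    def test_requires_fit(self):
        with pytest.raises(RuntimeError):
            InputEncoder().normalize(np.zeros(3))

    def test_normalization_clips_to_unit_interval(self):
        enc = InputEncoder().fit([np.array([[0.0, -1.0], [2.0, 1.0]])])
        u = enc.normalize(np.array([5.0, -5.0]))
        assert np.allclose(u, [1.0, 0.0])
        u = enc.normalize(np.array([1.0, 0.0]))
        assert np.allclose(u, [0.5, 0.5])

    def test_poisson_requires_rng(self):
        enc = InputEncoder(mode="poisson").fit([np.ones((2, 3))])
        with pytest.raises(ValueError):
            enc.encode(np.ones(3), rng=None)

    def test_nonfinite_features_rejected(self):
        enc = InputEncoder().fit([np.ones((2, 3))])
        with pytest.raises(ValueError):
            enc.normalize(np.array([1.0, np.nan, 0.0]))


class TestForwardPass:
    def test_quiescent_without_input(self):
        seq = np.zeros((50, 10))
        net = fitted_net(tiny_config(), [np.ones((2, 10)), seq])
        state = net.run_sequence(seq)
        assert np.all(state.x_deep == 0.0)
        assert all(np.all(s == 0) for s in state.spikes)

    def test_deterministic_rebuild_and_run(self):
        seq = random_sequence(80, 10, seed=1)
        a = fitted_net(tiny_config(), [seq]).run_sequence(seq)
        b = fitted_net(tiny_config(), [seq]).run_sequence(seq)
        assert np.array_equal(a.x_deep, b.x_deep)

    def test_network_seed_changes_topology_and_response(self):
        seq = random_sequence(80, 10, seed=1)
        a = fitted_net(tiny_config(seed=0), [seq]).run_sequence(seq)
        b = fitted_net(tiny_config(seed=1), [seq]).run_sequence(seq)
        assert not np.array_equal(a.x_deep, b.x_deep)

    def test_distinct_inputs_separate(self):
        s1 = random_sequence(80, 10, seed=2)
        s2 = random_sequence(80, 10, seed=3)
        net = fitted_net(tiny_config(), [s1, s2])
        x1 = net.run_sequence(s1).x_deep
        x2 = net.run_sequence(s2).x_deep
        assert x1.sum() > 0  # the liquid responds at all
        assert not np.array_equal(x1, x2)

    def test_reset_between_sequences_restores_purity(self):
        s1 = random_sequence(60, 10, seed=4)
        s2 = random_sequence(60, 10, seed=5)
        net = fitted_net(tiny_config(), [s1, s2])
        first = net.run_sequence(s1).x_deep
        net.run_sequence(s2)
        again = net.run_sequence(s1).x_deep
        assert np.array_equal(first, again)

    def test_traces_fade_within_five_time_constants(self):
        burst = random_sequence(60, 10, seed=6)
        net = fitted_net(tiny_config(), [burst])
        peak = net.run_sequence(burst).x_deep
        assert peak.max() > 0
        silence = np.zeros((1500, 10))  # 5 * tau_trace of silent input
        faded = net.run_sequence(silence, reset=False).x_deep
        assert faded.max() < 0.01 * peak.max()

    def test_x_deep_nonnegative_and_concatenated(self):
        seq = random_sequence(50, 10, seed=7)
        net = fitted_net(tiny_config(), [seq])
        state = net.run_sequence(seq)
        assert state.x_deep.shape == (100,)
        assert np.all(state.x_deep >= 0.0)
        assert np.array_equal(state.x_deep[:50], state.traces[0])

    def test_run_dataset_stacks_snapshots(self):
        seqs = [random_sequence(40, 10, seed=s) for s in range(3)]
        net = fitted_net(tiny_config(), seqs)
        X = net.run_dataset(seqs)
        assert X.shape == (3, 100)

    def test_wrong_input_length_rejected(self):
        net = fitted_net(tiny_config(), [np.ones((2, 10))])
        with pytest.raises(ValueError):
            net.step(np.zeros(7))

    def test_empty_sequence_rejected(self):
        net = fitted_net(tiny_config(), [np.ones((2, 10))])
        with pytest.raises(ValueError):
            net.run_sequence(np.zeros((0, 10)))

    def test_single_layer_degenerates_to_flat_lsm(self):
        cfg = tiny_config(hidden_sizes=(50,), wta_sizes=())
        seq = random_sequence(50, 10, seed=8)
        net = fitted_net(cfg, [seq])
        assert net.wtas == []
        assert net.run_sequence(seq).x_deep.shape == (50,)

    def test_recurrence_ablation_builds_and_runs(self):
        conn = ConnectivityParams(
            c={"EE": 0.0, "EI": 0.0, "IE": 0.0, "II": 0.0}
        )
        net = fitted_net(tiny_config(connectivity=conn),
                         [random_sequence(30, 10, seed=9)])
        assert all(len(layer.recurrent) == 0 for layer in net.layers)
        net.run_sequence(random_sequence(30, 10, seed=9))

    def test_poisson_encoding_seeded(self):
        cfg = tiny_config(input_encoding="poisson")
        seq = random_sequence(60, 10, seed=10)
        net = fitted_net(cfg, [seq])
        a = net.run_sequence(seq, seed=1).x_deep
        b = net.run_sequence(seq, seed=1).x_deep
        assert np.array_equal(a, b)


class TestTrainingAndNoise:
    def test_zero_epochs_leaves_wta_untouched(self):
        seqs = [random_sequence(40, 10, seed=11)]
        net = fitted_net(tiny_config(), seqs)
        before = net.wtas[0].weights.copy()
        net.train_wta_layers(seqs, epochs_per_layer=0)
        assert np.array_equal(net.wtas[0].weights, before)

    def test_training_moves_weights_but_keeps_scaling(self):
        seqs = [random_sequence(120, 10, seed=12)]
        net = fitted_net(tiny_config(), seqs)
        before = net.wtas[0].weights.copy()
        net.train_wta_layers(seqs, epochs_per_layer=1, seed=0)
        assert not np.array_equal(net.wtas[0].weights, before)
        assert np.allclose(net.wtas[0].weights.sum(axis=0), 15.0, atol=1e-9)
        assert not net.wtas[0].training

    def test_zero_write_noise_is_identity(self):
        seq = random_sequence(50, 10, seed=13)
        net = fitted_net(tiny_config(), [seq])
        before = net.run_sequence(seq).x_deep
        net.apply_weight_noise(0.0, seed=0)
        assert np.array_equal(net.run_sequence(seq).x_deep, before)

    def test_write_noise_perturbs_response(self):
        seq = random_sequence(50, 10, seed=14)
        net = fitted_net(tiny_config(), [seq])
        before = net.run_sequence(seq).x_deep
        net.apply_weight_noise(0.2, seed=0)
        assert not np.array_equal(net.run_sequence(seq).x_deep, before)

    def test_firing_rates_reports_one_rate_per_layer(self):
        seqs = [random_sequence(30, 10, seed=15)]
        net = fitted_net(tiny_config(), seqs)
        rates = net.firing_rates(seqs)
        assert len(rates) == 2
        assert all(0.0 <= r <= 1.0 for r in rates)


def test_default_kappa_matches_sizing_rationale():
    # ~6 simultaneous strength-3 pulses at full efficacy reach threshold
    # from rest within the 3-ms pulse window
    target = 16.5 / (6 * 3 * (1 - (1 - 1 / 28.0) ** 3))
    assert DEFAULT_KAPPA == pytest.approx(target, abs=0.005)
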