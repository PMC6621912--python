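"""Unit tests for grid construction and distance-dependent connectivity.

The Monte-Carlo connectivity check follows the binomial-oracle recipe:
10,000 independent draws per (distance, pair-type) bin, empirical
frequency within 3 standard errors of the closed-form probability
C * exp(-D/lambda)^2.
"""

import numpy as np
import pytest

from deeplsm.reservoir import (
    ConnectivityParams,
    GridSpec,
    NoisyWeightStore,
    SynapseSet,
    build_grid,
    connect_input,
    connect_recurrent,
    connection_probability,
    grid_dims,
    normalize_synapses,
    perturb_weights,
    primary_mask,
)


class TestGridDims:
    def test_cubes_factor_exactly(self):
        assert grid_dims(1000) == (10, 10, 10)
        assert grid_dims(125) == (5, 5, 5)
        assert grid_dims(27) == (3, 3, 3)

    def test_most_cubic_for_non_cubes(self):
        assert sorted(grid_dims(500)) == [5, 10, 10]
        assert sorted(grid_dims(50)) == [2, 5, 5]

    def test_product_is_preserved(self):
        for n in (30, 60, 100, 360, 500, 1000):
            assert int(np.prod(grid_dims(n))) == n

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            grid_dims(0)


class TestGridSpec:
    def test_exact_ei_split(self):
        for n, n_e in ((125, 100), (500, 400), (1000, 800)):
            _, labels = build_grid(GridSpec.from_size(n))
            assert labels.sum() == n_e
            assert labels.size == n

    def test_split_impossible_rejected(self):
        # 27 is not divisible by 5, so an exact 4:1 split cannot exist
        with pytest.raises(ValueError):
            GridSpec.from_size(27)

    def test_labels_deterministic_under_seed(self):
        _, a = build_grid(GridSpec.from_size(125, seed=3))
        _, b = build_grid(GridSpec.from_size(125, seed=3))
        _, c = build_grid(GridSpec.from_size(125, seed=4))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_positions_fill_the_lattice(self):
        pos, _ = build_grid(GridSpec(dims=(5, 5, 5)))
        assert pos.shape == (125, 3)
        assert len({tuple(p) for p in pos}) == 125


class TestConnectionProbability:
    def test_hand_values(self):
        p = ConnectivityParams()
        # C_EE * exp(-D/lambda)^2 = 0.6 * e^-2 at D = 3, lambda = 3
        assert connection_probability(3.0, "EE", p) == pytest.approx(
            0.6 * np.exp(-2.0), abs=1e-12
        )
        assert connection_probability(0.0, "EE", p) == pytest.approx(0.6)
        assert connection_probability(3.0, "EI", p) == pytest.approx(
            np.exp(-2.0), abs=1e-12
        )

    def test_monotonically_decreasing_in_distance(self):
        p = ConnectivityParams()
        probs = [connection_probability(d, "IE", p) for d in range(8)]
        assert all(a > b for a, b in zip(probs, probs[1:]))


def _pair_draws(distance, excitatory, n_trials, seed0):
    """Directed connection draws between isolated neuron pairs.

    Each build places 20 pairs far apart (cross-pair probability is
    numerically zero) with partners at the requested distance; every
    partner-to-partner direction is one Bernoulli draw.
    """
    n_pairs = 20
    pos = np.zeros((2 * n_pairs, 3), dtype=int)
    pos[:, 0] = np.repeat(np.arange(n_pairs) * 1000, 2)
    pos[1::2, 2] = distance
    labels = np.full(2 * n_pairs, excitatory, dtype=bool)
    params = ConnectivityParams()
    hits = 0
    builds = n_trials // (2 * n_pairs)
    for b in range(builds):
        syn = connect_recurrent(pos, labels, params, seed=seed0 + b)
        partner = syn.pre ^ 1  # partner of neuron i is i XOR 1
        hits += int(np.sum(syn.post == partner))
    return hits, builds * 2 * n_pairs  # 2 ordered directions per pair


@pytest.mark.parametrize(
    "distance,excitatory,pair_type",
    [(1, True, "EE"), (3, True, "EE"), (6, True, "EE"), (3, False, "II")],
)
def test_empirical_connection_frequency_within_3_se(distance, excitatory,
                                                    pair_type):
    p_true = connection_probability(float(distance), pair_type,
                                    ConnectivityParams())
    hits, total = _pair_draws(distance, excitatory, 20000, seed0=1000 * distance)
    assert total >= 10000
    se = np.sqrt(p_true * (1 - p_true) / total)
    assert abs(hits / total - p_true) < 3 * se


@pytest.fixture(scope="module")
def small_build():
    pos, labels = build_grid(GridSpec.from_size(125, seed=0))
    syn = connect_recurrent(pos, labels, ConnectivityParams(), seed=1)
    return pos, labels, syn


class TestConnectRecurrent:
    def test_no_self_connections(self, small_build):
        _, _, syn = small_build
        assert not np.any(syn.pre == syn.post)

    def test_fixed_weights_per_pair_type(self, small_build):
        _, _, syn = small_build
        w = ConnectivityParams().w_fixed
        for pt in ("EE", "EI", "IE", "II"):
            mask = syn.pair_type == pt
            assert mask.any()
            assert np.all(syn.weight[mask] == w[pt])

    def test_excitatory_flag_follows_presynaptic_type(self, small_build):
        _, labels, syn = small_build
        assert np.array_equal(syn.excitatory, labels[syn.pre])

    def test_deterministic_under_seed(self, small_build):
        pos, labels, syn = small_build
        again = connect_recurrent(pos, labels, ConnectivityParams(), seed=1)
        assert np.array_equal(syn.pre, again.pre)
        assert np.array_equal(syn.post, again.post)

    def test_drive_matrix_signs(self, small_build):
        _, _, syn = small_build
        m = syn.drive_matrix().toarray()
        exc_cols = np.unique(syn.pre[syn.excitatory])
        inh_cols = np.unique(syn.pre[~syn.excitatory])
        assert np.all(m[:, exc_cols] >= 0)
        assert np.all(m[:, inh_cols] <= 0)


class TestNormalization:
    def _toy(self, weights, excitatory):
        n = len(weights)
        return SynapseSet(
            pre=np.arange(n),
            post=np.zeros(n, dtype=int),
            weight=np.asarray(weights, dtype=float),
            excitatory=np.asarray(excitatory, dtype=bool),
            n_pre=n,
            n_post=1,
        )

    def test_proportional_rescale_hand_values(self):
        syn = self._toy([2.0, 6.0], [True, True])
        out = normalize_synapses(syn, (10.0, 36.0))
        assert np.allclose(out.weight, [2.5, 7.5], atol=1e-12)

    def test_mixed_classes_hit_both_targets(self):
        syn = self._toy([2.0, 6.0, 4.0], [True, True, False])
        out = normalize_synapses(syn, (40.0, 36.0))
        assert out.weight[:2].sum() == pytest.approx(40.0, abs=1e-9)
        assert out.weight[2] == pytest.approx(36.0, abs=1e-9)

    def test_full_grid_incoming_sums_hit_targets(self):
        pos, labels = build_grid(GridSpec.from_size(125, seed=2))
        syn = normalize_synapses(
            connect_recurrent(pos, labels, ConnectivityParams(), seed=3),
            (40.0, 36.0),
        )
        for target, mask in ((40.0, syn.excitatory), (36.0, ~syn.excitatory)):
            sums = np.bincount(syn.post[mask], weights=syn.weight[mask],
                               minlength=125)
            present = np.zeros(125, dtype=bool)
            present[syn.post[mask]] = True
            assert np.allclose(sums[present], target, atol=1e-9)

    def test_neuron_without_class_left_unmodified(self):
        syn = self._toy([5.0], [True])  # no inhibitory synapses at all
        out = normalize_synapses(syn, (40.0, 36.0))
        assert out.weight[0] == pytest.approx(40.0)


class TestConnectInput:
    def test_sparsity_within_3_se(self):
        syn = connect_input(100, 500, 0.05, seed=4)
        n_draws = 100 * 500
        se = np.sqrt(0.05 * 0.95 / n_draws)
        assert abs(len(syn) / n_draws - 0.05) < 3 * se

    def test_all_excitatory_fixed_weight(self):
        syn = connect_input(10, 50, 0.2, seed=5, weight=3.0)
        assert np.all(syn.excitatory)
        assert np.all(syn.weight == 3.0)

    def test_primary_mask_matches_posts(self):
        syn = connect_input(10, 50, 0.1, seed=6)
        mask = primary_mask(syn)
        assert np.array_equal(np.nonzero(mask)[0], np.unique(syn.post))

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError):
            connect_input(10, 50, 1.5, seed=0)


class TestNoiseModels:
    def test_zero_sigma_store_is_transparent(self):
        w = np.arange(12.0).reshape(3, 4)
        store = NoisyWeightStore(w, sigma_read=0.0, sigma_write=0.0, seed=0)
        assert np.array_equal(store.read(), w)
        store.write(2 * w)
        assert np.array_equal(store.read(), 2 * w)

    def test_read_noise_statistics(self):
        w = np.zeros(20000)
        store = NoisyWeightStore(w, sigma_read=0.1, seed=7)
        diff = store.read() - w
        assert abs(diff.mean()) < 3 * 0.1 / np.sqrt(diff.size)
        assert diff.std() == pytest.approx(0.1, rel=0.05)

    def test_repeated_reads_draw_fresh_noise(self):
        store = NoisyWeightStore(np.zeros(10), sigma_read=0.1, seed=8)
        assert not np.array_equal(store.read(), store.read())

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoisyWeightStore(np.zeros(3), sigma_read=-0.1)

    def test_perturb_zero_sigma_identity(self):
        syn = connect_input(10, 50, 0.2, seed=9)
        out = perturb_weights(syn, 0.0, np.random.default_rng(0))
        assert out is syn

    def test_perturb_keeps_magnitudes_nonnegative(self):
        syn = connect_input(10, 50, 0.5, seed=10, weight=0.01)
        out = perturb_weights(syn, 1.0, np.random.default_rng(1))
        assert np.all(out.weight >= 0.0)
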