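import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedaar.datasets import ClientDataset
from fedaar.nn import ModelSpec
from fedaar.plu import (
    PLUHyper,
    PrototypeSet,
    average_local_prototypes,
    batch_prototypes,
    gamma_coefficient,
    local_update,
    pgreg_loss,
    update_global_prototypes,
)


def proto_set(rows, available, support):
    return PrototypeSet(np.asarray(rows, float), np.asarray(available, bool), np.asarray(support))


class TestBatchPrototypes:
    def test_mean_of_two_points(self):
        ps = batch_prototypes(np.array([[1.0, 1.0], [3.0, 3.0]]), np.array([1, 1]), 2)
        np.testing.assert_allclose(ps.protos[0], [2.0, 2.0])
        assert not ps.available[1]
        assert ps.support.tolist() == [2, 0]

    def test_singleton_class_equals_feature_row(self):
        feats = np.array([[0.5, -1.0, 2.0]])
        ps = batch_prototypes(feats, np.array([3]), 3)
        np.testing.assert_allclose(ps.protos[2], feats[0])

    def test_permutation_invariance(self, rng):
        feats = rng.normal(size=(10, 4))
        labels = rng.integers(1, 4, size=10)
        perm = rng.permutation(10)
        a = batch_prototypes(feats, labels, 3)
        b = batch_prototypes(feats[perm], labels[perm], 3)
        np.testing.assert_allclose(a.protos, b.protos)
        np.testing.assert_array_equal(a.support, b.support)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            batch_prototypes(np.zeros((1, 2)), np.array([5]), 3)


class TestPGRegLoss:
    def test_zero_when_equal(self):
        ps = proto_set([[1, 2], [3, 4]], [True, True], [1, 1])
        assert pgreg_loss(ps, ps) == 0.0

    def test_three_four_five(self):
        local = proto_set([[0.0, 0.0]], [True], [1])
        glob = proto_set([[3.0, 4.0]], [True], [1])
        assert pgreg_loss(local, glob) == pytest.approx(5.0)

    def test_disjoint_availability_contributes_zero(self):
        local = proto_set([[1, 1], [0, 0]], [True, False], [1, 0])
        glob = proto_set([[9, 9], [2, 2]], [False, True], [0, 1])
        assert pgreg_loss(local, glob) == 0.0

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pgreg_loss(proto_set([[1, 2]], [True], [1]), proto_set([[1, 2, 3]], [True], [1]))

    def test_nonnegative_and_zero_iff_equal(self, rng):
        a = proto_set(rng.normal(size=(3, 4)), [True, True, False], [2, 1, 0])
        b = proto_set(rng.normal(size=(3, 4)), [True, True, True], [1, 1, 1])
        assert pgreg_loss(a, b) > 0.0


class TestGamma:
    def test_equal_distances_give_half(self):
        glob = proto_set([[0.0, 0.0], [2.0, 0.0]], [True, True], [1, 1])
        # pbar equidistant from both prototypes
        assert gamma_coefficient(np.array([1.0, 5.0]), glob, 1) == pytest.approx(0.5)

    def test_exp_ratio_values(self):
        # distances a - b = +1 and -1: direct evaluation of the exp ratio
        glob = proto_set([[0.0, 0.0], [3.0, 0.0]], [True, True], [1, 1])
        g_plus = gamma_coefficient(np.array([2.0, 0.0]), glob, 1)   # a=2, b=1
        assert g_plus == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)
        g_minus = gamma_coefficient(np.array([1.0, 0.0]), glob, 1)  # a=1, b=2
        assert g_minus == pytest.approx(1 / (1 + math.exp(1)), abs=1e-9)
        assert g_plus == pytest.approx(0.731059, abs=1e-6)
        assert g_minus == pytest.approx(0.268941, abs=1e-6)

    def test_logistic_matches_direct_exp_ratio(self, rng):
        for _ in range(200):
            protos = rng.normal(size=(3, 4))
            glob = proto_set(protos, [True] * 3, [1] * 3)
            pbar = rng.normal(size=4)
            c = int(rng.integers(1, 4))
            got = gamma_coefficient(pbar, glob, c)
            others = [j for j in range(3) if j != c - 1]
            dists = [np.linalg.norm(protos[j] - protos[c - 1]) for j in others]
            cp = others[int(np.argmin(dists))]
            a = np.linalg.norm(pbar - protos[c - 1])
            b = np.linalg.norm(pbar - protos[cp])
            direct = math.exp(a) / (math.exp(a) + math.exp(b))
            assert got == pytest.approx(direct, abs=1e-12)
            assert 0.0 < got < 1.0

    def test_monotone_in_intra_class_distance(self):
        glob = proto_set([[0.0, 0.0], [4.0, 0.0]], [True, True], [1, 1])
        gammas = [
            gamma_coefficient(np.array([x, 0.0]), glob, 1) for x in (0.0, 0.5, 1.0, 1.5)
        ]
        assert all(g1 < g2 for g1, g2 in zip(gammas, gammas[1:]))

    def test_single_available_class_rejected(self):
        glob = proto_set([[0.0, 0.0], [1.0, 1.0]], [True, False], [1, 0])
        with pytest.raises(ValueError):
            gamma_coefficient(np.zeros(2), glob, 1)


class TestAveragePrototypes:
    def test_weighted_mean_by_hand(self):
        a = proto_set([[0.0, 0.0]], [True], [1])
        b = proto_set([[4.0, 4.0]], [True], [3])
        out = average_local_prototypes([a, b])
        np.testing.assert_allclose(out.protos[0], [3.0, 3.0])
        assert out.support[0] == 4

    def test_single_client_unchanged(self):
        a = proto_set([[1.5, -2.0]], [True], [7])
        out = average_local_prototypes([a])
        np.testing.assert_allclose(out.protos, a.protos)

    def test_zero_support_unavailable(self):
        a = proto_set([[1.0, 1.0], [0, 0]], [True, False], [2, 0])
        b = proto_set([[3.0, 3.0], [0, 0]], [True, False], [2, 0])
        out = average_local_prototypes([a, b])
        assert not out.available[1]


class TestGlobalUpdate:
    def test_fixed_point(self):
        glob = proto_set([[1.0, 1.0], [3.0, 3.0]], [True, True], [1, 1])
        out = update_global_prototypes(glob, glob.copy())
        np.testing.assert_allclose(out.protos, glob.protos)

    def test_midpoint_with_half_gamma(self):
        # single available global class -> gamma falls back to 0.5
        glob = proto_set([[0.0, 0.0], [9, 9]], [True, False], [1, 0])
        pbar = proto_set([[2.0, 2.0], [0, 0]], [True, False], [1, 0])
        out = update_global_prototypes(glob, pbar)
        np.testing.assert_allclose(out.protos[0], [1.0, 1.0])

    def test_empty_global_adopts_pbar_directly(self):
        glob = PrototypeSet.empty(2, 2)
        pbar = proto_set([[5.0, 5.0], [0, 0]], [True, False], [3, 0])
        out = update_global_prototypes(glob, pbar)
        np.testing.assert_allclose(out.protos[0], [5.0, 5.0])
        assert out.available[0] and not out.available[1]

    def test_update_is_convex_combination(self, rng):
        protos = rng.normal(size=(4, 3))
        glob = proto_set(protos, [True] * 4, [1] * 4)
        pbar = proto_set(rng.normal(size=(4, 3)), [True] * 4, [2] * 4)
        out = update_global_prototypes(glob, pbar)
        for c in range(4):
            seg = out.protos[c] - glob.protos[c]
            full = pbar.protos[c] - glob.protos[c]
            # colinear and between the endpoints
            t = seg @ full / (full @ full)
            assert 0.0 <= t <= 1.0
            np.testing.assert_allclose(seg, t * full, atol=1e-9)

    def test_missing_pbar_class_keeps_old_prototype(self):
        glob = proto_set([[1.0, 1.0], [2.0, 2.0]], [True, True], [1, 1])
        pbar = proto_set([[0.0, 0.0], [0, 0]], [True, False], [1, 0])
        out = update_global_prototypes(glob, pbar)
        np.testing.assert_allclose(out.protos[1], [2.0, 2.0])


class TestLocalUpdate:
    @pytest.fixture()
    def setup(self, tiny_spec, tiny_federation):
        from fedaar.nn import init_model

        clients, _ = tiny_federation
        _, w = init_model(tiny_spec)
        return tiny_spec, clients[0], w

    def test_lambda_zero_matches_plain_ce_bitwise(self, setup):
        """With lambda = 0 the prototype machinery must not perturb training:
        the delta equals a plain cross-entropy run bit for bit."""
        spec, ds, w = setup
        glob = PrototypeSet(
            np.random.default_rng(0).normal(size=(4, 8)),
            np.ones(4, dtype=bool),
            np.ones(4, dtype=np.int64),
        )
        h0 = PLUHyper(lambda_pgreg=0.0, batch_size=32, learning_rate=1e-3)
        d0, _, _ = local_update(w, ds, glob, h0, spec, round_idx=0, seed=9)
        d1, _, _ = local_update(w, ds, None, h0, spec, round_idx=0, seed=9)
        np.testing.assert_array_equal(d0, d1)

    def test_pgreg_engages_with_global_prototypes(self, setup):
        spec, ds, w = setup
        glob = PrototypeSet(
            np.random.default_rng(0).normal(size=(4, 8)),
            np.ones(4, dtype=bool),
            np.ones(4, dtype=np.int64),
        )
        h = PLUHyper(lambda_pgreg=0.5, batch_size=32, learning_rate=1e-3)
        d_reg, _, trace = local_update(w, ds, glob, h, spec, round_idx=0, seed=9)
        h0 = PLUHyper(lambda_pgreg=0.0, batch_size=32, learning_rate=1e-3)
        d_plain, _, _ = local_update(w, ds, glob, h0, spec, round_idx=0, seed=9)
        assert trace.pgreg[0] > 0.0
        assert not np.array_equal(d_reg, d_plain)

    def test_lambda_inactive_while_global_empty(self, setup):
        spec, ds, w = setup
        h = PLUHyper(lambda_pgreg=0.5, batch_size=32, learning_rate=1e-3)
        _, _, trace = local_update(
            w, ds, PrototypeSet.empty(4, 8), h, spec, round_idx=0, seed=9
        )
        assert all(p == 0.0 for p in trace.pgreg)

    def test_support_counts_bounded_by_dataset(self, setup):
        spec, ds, w = setup
        h = PLUHyper(batch_size=32, learning_rate=1e-3)
        _, protos, _ = local_update(w, ds, None, h, spec, round_idx=0, seed=9)
        assert protos.support.sum() <= len(ds)
        assert np.all(protos.available == (protos.support > 0))

    @pytest.mark.parametrize("epochs", [1, 2])
    def test_step_count(self, setup, epochs):
        spec, ds, w = setup
        h = PLUHyper(local_epochs=epochs, batch_size=32, learning_rate=1e-3)
        _, _, trace = local_update(w, ds, None, h, spec, round_idx=0, seed=9)
        assert trace.n_steps == epochs * math.ceil(len(ds) / 32)

    def test_empty_dataset_rejected(self, setup):
        spec, _, w = setup
        empty = ClientDataset(np.zeros((0, 40, 6)), np.zeros(0, dtype=int), "e")
        with pytest.raises(ValueError):
            local_update(w, empty, None, PLUHyper(), spec)

    def test_head_gradient_unaffected_by_pgreg_first_step(self, setup):
        """PGReg acts on features only; the first optimisation step's head
        rows must match a lambda = 0 run exactly."""
        spec, ds, w = setup
        glob = PrototypeSet(
            np.random.default_rng(3).normal(size=(4, 8)),
            np.ones(4, dtype=bool),
            np.ones(4, dtype=np.int64),
        )
        big = len(ds)  # single batch -> single step comparison
        h_reg = PLUHyper(lambda_pgreg=1.0, batch_size=big, learning_rate=1e-3)
        h_0 = PLUHyper(lambda_pgreg=0.0, batch_size=big, learning_rate=1e-3)
        d_reg, _, _ = local_update(w, ds, glob, h_reg, spec, round_idx=0, seed=4)
        d_0, _, _ = local_update(w, ds, glob, h_0, spec, round_idx=0, seed=4)
        n_head = 4 * 8 + 4
        np.testing.assert_allclose(d_reg[-n_head:], d_0[-n_head:], atol=1e-12)
        assert not np.allclose(d_reg[:-n_head], d_0[:-n_head])


@settings(max_examples=30, deadline=None)
@given(
    a=st.floats(0.0, 20.0),
    b=st.floats(0.0, 20.0),
)
def test_gamma_in_unit_interval(a, b):
    """gamma = 1/(1+exp(b-a)) stays strictly inside (0, 1) for any distances."""
    glob = proto_set([[0.0, 0.0], [0.0, b + 1.0]], [True, True], [1, 1])
    pbar_c = np.array([a, 0.0])
    g = gamma_coefficient(pbar_c, glob, 1)
    assert 0.0 < g < 1.0
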