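"""Network construction, forward contracts, gradients and the model archive."""

import numpy as np
import pytest

from ognet import architecture as A
from ognet.alphabet_io import (
    EncodedBatch,
    EncodedSequence,
    GroupLabelMap,
    pad_and_batch,
)


def random_batch(rng, lengths, l_max=None):
    l_max = l_max or max(max(lengths), 36)
    mat = np.zeros((len(lengths), l_max), dtype=np.int64)
    for i, n in enumerate(lengths):
        mat[i, :n] = rng.integers(1, 27, size=n)
    return EncodedBatch(matrix=mat, lengths=np.array(lengths))


class TestModelConfig:
    def test_default_feature_vector_size(self):
        cfg = A.ModelConfig(variant="deepnog", n_groups=10)
        assert cfg.embedding_dim == 10
        assert cfg.filter_sizes == (8, 12, 16, 20, 24, 28, 32, 36)
        assert cfg.filters_per_size == 150
        assert cfg.n_filters_total == 8 * 150 == 1200
        assert cfg.dropout_p == 0.3

    def test_best_baseline_parametrization(self):
        cfg = A.deepfam_best_config(10)
        assert cfg.n_filters_total == 2000
        assert cfg.hidden_units == 2000

    def test_light_baseline_parametrization(self):
        cfg = A.deepfam_light_config(10)
        assert cfg.filters_per_size == 150
        assert cfg.hidden_units == 1500

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(variant="nope", n_groups=3),
            dict(variant="deepnog", n_groups=1),
            dict(variant="deepnog", n_groups=3, filter_sizes=(8, 8)),
            dict(variant="deepnog", n_groups=3, filter_sizes=(12, 8)),
            dict(variant="deepnog", n_groups=3, dropout_p=1.0),
            dict(variant="deepnog", n_groups=3, hidden_units=10),
            dict(variant="deepfam", n_groups=3, hidden_units=0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            A.ModelConfig(**kwargs)


class TestBuild:
    def test_embedding_has_padding_row_pinned_to_zero(self, tiny_deepnog):
        emb = tiny_deepnog.params["embedding"]
        assert emb.shape == (27, 6)
        assert (emb[0] == 0).all()
        assert np.abs(emb[1:]).sum() > 0

    def test_baseline_pools_over_l_minus_k_plus_1_units(self, tiny_deepfam):
        onehot = np.zeros((2, 60, 21), dtype=np.float32)
        onehot[:, :, 0] = 1.0
        logits, cache = A._forward_deepfam(tiny_deepfam, onehot, False, None, True)
        # with K=8 and fixed length 60 there are 53 pooled-over units
        assert cache["caches"][1]["col"].shape[1] == 60 - 8 + 1

    def test_build_rejects_wrong_variant(self):
        cfg = A.ModelConfig(variant="deepfam", n_groups=3, hidden_units=5)
        with pytest.raises(ValueError):
            A.build_deepnog(cfg)


class TestCountParameters:
    def test_toy_closed_form_by_hand(self):
        # (26+1)*2 + 3*(2*2+1) + (1*3)*4 + 4 = 54 + 15 + 12 + 4 = 85
        cfg = A.ModelConfig(
            variant="deepnog", n_groups=4, embedding_dim=2,
            filter_sizes=(2,), filters_per_size=3,
        )
        assert A.count_parameters(cfg) == 85

    def test_doubling_filters_doubles_conv_and_classifier_terms(self):
        base = A.ModelConfig(variant="deepnog", n_groups=4, embedding_dim=2,
                             filter_sizes=(2,), filters_per_size=3)
        double = A.ModelConfig(variant="deepnog", n_groups=4, embedding_dim=2,
                               filter_sizes=(2,), filters_per_size=6)
        embed, c_out = 27 * 2, 4
        assert A.count_parameters(double) - embed - c_out == 2 * (
            A.count_parameters(base) - embed - c_out
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration_of_allocated_arrays(self, seed):
        rng = np.random.default_rng(seed)
        variant = rng.choice(["deepnog", "deepfam"])
        n_sizes = int(rng.integers(1, 5))
        sizes = tuple(sorted(rng.choice(np.arange(2, 40), size=n_sizes, replace=False)))
        cfg = A.ModelConfig(
            variant=variant,
            n_groups=int(rng.integers(2, 30)),
            embedding_dim=int(rng.integers(1, 16)),
            filter_sizes=tuple(int(k) for k in sizes),
            filters_per_size=int(rng.integers(1, 20)),
            hidden_units=int(rng.integers(1, 50)) if variant == "deepfam" else 0,
        )
        state = A.build_model(cfg, seed=seed)
        brute_force = sum(v.size for v in state.params.values())
        assert A.count_parameters(cfg) == brute_force


class TestPredictProba:
    def test_symmetric_logits(self):
        assert A.predict_proba(np.array([[0.0, 0.0]]))[0].tolist() == [0.5, 0.5]

    def test_closed_form_softmax(self):
        p = A.predict_proba(np.array([[np.log(1.0), np.log(3.0)]]))[0]
        assert p == pytest.approx([0.25, 0.75])

    def test_rows_sum_to_one_and_argmax_preserved(self, rng):
        logits = rng.normal(size=(40, 7)) * 30
        p = A.predict_proba(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p.argmax(axis=1) == logits.argmax(axis=1)).all()


class TestForwardContracts:
    def test_padding_invariance(self, tiny_deepnog, rng):
        seq = rng.integers(1, 27, size=50)
        short = np.zeros((1, 50), dtype=np.int64)
        short[0] = seq
        long = np.zeros((1, 500), dtype=np.int64)
        long[0, :50] = seq
        l1 = A.forward(tiny_deepnog, EncodedBatch(short, np.array([50])))
        l2 = A.forward(tiny_deepnog, EncodedBatch(long, np.array([50])))
        np.testing.assert_allclose(l1, l2, rtol=1e-5)

    def test_batch_composition_invariance(self, tiny_deepnog, rng):
        batch = random_batch(rng, [40, 200, 77])
        together = A.forward(tiny_deepnog, batch)
        for i, n in enumerate([40, 200, 77]):
            alone = EncodedBatch(batch.matrix[i:i + 1, :max(n, 36)],
                                 batch.lengths[i:i + 1])
            solo = A.forward(tiny_deepnog, alone)
            np.testing.assert_allclose(solo[0], together[i], rtol=1e-5)

    def test_permuting_rows_permutes_logits(self, tiny_deepnog, rng):
        batch = random_batch(rng, [60, 60, 60])
        perm = [2, 0, 1]
        out = A.forward(tiny_deepnog, batch)
        out_p = A.forward(
            tiny_deepnog,
            EncodedBatch(batch.matrix[perm], batch.lengths[perm]),
        )
        np.testing.assert_allclose(out[perm], out_p, rtol=1e-5)

    def test_single_residue_input_is_finite(self, tiny_deepnog):
        batch = pad_and_batch([EncodedSequence(np.array([5]), 1)])
        logits = A.forward(tiny_deepnog, batch)
        assert np.isfinite(logits).all()

    def test_out_of_alphabet_index_is_an_error(self, tiny_deepnog):
        bad = EncodedBatch(np.full((1, 36), 27, dtype=np.int64), np.array([36]))
        with pytest.raises(ValueError, match="alphabet"):
            A.forward(tiny_deepnog, bad)

    def test_underpadded_batch_is_an_error(self, tiny_deepnog, rng):
        batch = random_batch(rng, [5], l_max=5)
        with pytest.raises(ValueError, match="padded"):
            A.forward(tiny_deepnog, batch)

    def test_dropout_only_active_in_training(self, tiny_deepnog, rng):
        batch = random_batch(rng, [50])
        a = A.forward(tiny_deepnog, batch, training=False)
        b = A.forward(tiny_deepnog, batch, training=False)
        np.testing.assert_array_equal(a, b)
        t1 = A.forward(tiny_deepnog, batch, training=True,
                       dropout_rng=np.random.default_rng(1))
        t2 = A.forward(tiny_deepnog, batch, training=True,
                       dropout_rng=np.random.default_rng(2))
        assert not np.allclose(t1, t2)


class TestSelfNormalizationAtInit:
    def test_post_selu_statistics_near_zero_mean_unit_variance(self, rng):
        cfg = A.ModelConfig(variant="deepnog", n_groups=5, filters_per_size=30)
        state = A.build_deepnog(cfg, seed=0)
        batch = random_batch(rng, [200] * 32)
        _, cache = A._forward_deepnog(state, batch, False, None, True)
        for c in cache["caches"]:
            act = A.selu(c["pre"])  # all windows are valid here (equal lengths)
            assert abs(act.mean()) < 0.3
            assert 0.5 < act.var() < 1.5


class TestGradients:
    @pytest.mark.parametrize("variant", ["deepnog", "deepfam"])
    def test_analytic_gradients_match_finite_differences(self, variant, rng):
        if variant == "deepnog":
            cfg = A.ModelConfig(variant="deepnog", n_groups=3, embedding_dim=4,
                                filter_sizes=(2, 3), filters_per_size=3, dropout_p=0.0)
            state = A.build_deepnog(cfg, seed=1)
            batch = random_batch(rng, [12, 7, 3, 12], l_max=12)
        else:
            cfg = A.ModelConfig(variant="deepfam", n_groups=3, filter_sizes=(2, 3),
                                filters_per_size=3, dropout_p=0.0, hidden_units=5,
                                fixed_length=15)
            state = A.build_deepfam(cfg, seed=1)
            batch = np.zeros((4, 15, 21), dtype=np.float64)
            for b in range(4):
                n = rng.integers(5, 16)
                batch[b, np.arange(n), rng.integers(0, 21, size=n)] = 1.0
        for k in state.params:
            state.params[k] = state.params[k].astype(np.float64)
        y = rng.integers(0, 3, size=4 if variant == "deepfam" else 4)
        bufs = {k: v.copy() for k, v in state.buffers.items()}

        def loss_fn():
            st = A.ModelState(cfg, state.params, {k: v.copy() for k, v in bufs.items()})
            fwd = A._forward_deepnog if variant == "deepnog" else A._forward_deepfam
            logits, _ = fwd(st, batch, True, None, False)
            p = A.predict_proba(logits)
            return float(-np.log(p[np.arange(len(y)), y] + 1e-12).mean())

        _, grads = A.loss_and_grads(state, batch, y)
        state.buffers = bufs
        eps = 1e-5
        for name, arr in state.params.items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp = loss_fn()
                arr[i] = old - eps
                lm = loss_fn()
                arr[i] = old
                num[i] = (lp - lm) / (2 * eps)
            if name == "embedding":
                num[0] = 0.0  # the padding row is frozen by design
            diff = np.abs(num - grads[name])
            # small slack for max-pool argmax flips under the finite perturbation
            assert (diff <= 2e-3 + 2e-2 * np.abs(grads[name])).mean() > 0.95, name
            assert diff.max() < 5e-3, name


class TestModelArchive:
    def test_roundtrip_preserves_predictions(self, tiny_deepnog, tmp_path, rng):
        label_map = GroupLabelMap.from_groups(["a", "b", "c", "d"])
        path = tmp_path / "m.ognet"
        A.save_model(tiny_deepnog, label_map, path)
        loaded, lmap = A.load_model(path)
        assert lmap.group_ids == label_map.group_ids
        batch = random_batch(rng, [50, 80])
        np.testing.assert_array_equal(
            A.forward(tiny_deepnog, batch), A.forward(loaded, batch)
        )

    def test_save_load_save_is_bit_stable(self, tiny_deepnog, tmp_path):
        label_map = GroupLabelMap.from_groups(["a", "b", "c", "d"])
        p1, p2 = tmp_path / "m1.ognet", tmp_path / "m2.ognet"
        A.save_model(tiny_deepnog, label_map, p1)
        loaded, lmap = A.load_model(p1)
        A.save_model(loaded, lmap, p2)
        l2, _ = A.load_model(p2)
        for k in tiny_deepnog.params:
            np.testing.assert_array_equal(tiny_deepnog.params[k], l2.params[k])

    def test_label_map_size_mismatch_is_an_error(self, tiny_deepnog, tmp_path):
        with pytest.raises(ValueError, match="group"):
            A.save_model(tiny_deepnog, GroupLabelMap.from_groups(["a", "b"]),
                         tmp_path / "m.ognet")

    def test_tampered_weight_shape_is_an_error(self, tiny_deepnog, tmp_path):
        label_map = GroupLabelMap.from_groups(["a", "b", "c", "d"])
        path = tmp_path / "m.ognet"
        bad = tiny_deepnog.copy()
        bad.params["out_b"] = np.zeros(9, dtype=np.float32)
        A.save_model(bad, label_map, path)
        with pytest.raises(ValueError, match="out_b"):
            A.load_model(path)
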