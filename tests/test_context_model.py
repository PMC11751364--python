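"""Genome sentences, attention maths, forward contracts, BCE, training."""

import numpy as np
import pytest

from contextgo.context_model import (
    ContextTransformer,
    GenomeSentence,
    ModelConfig,
    ScoreMatrix,
    assign_owner_windows,
    attention,
    bce_loss,
    build_sentences,
    multi_head,
    predict,
    train,
    window_spans,
)
from contextgo.ontology import AnnotationSet, LabelVocabulary


class TestBuildSentences:
    def test_one_sentence_per_contig(self):
        order = {
            "a": ("g1", 0), "b": ("g1", 1), "c": ("g1", 2),
            "x": ("g2", 0), "y": ("g2", 1),
        }
        sents = build_sentences(order)
        assert [s.genome_id for s in sents] == ["g1", "g2"]
        assert sents[0].protein_ids == ["a", "b", "c"]
        assert sents[1].protein_ids == ["x", "y"]

    def test_gapped_indices_sorted_numerically(self):
        order = {"a": ("g", 7), "b": ("g", 0), "c": ("g", 2)}
        assert build_sentences(order)[0].protein_ids == ["b", "c", "a"]

    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_sentences({"a": ("g", 0), "b": ("g", 0)})


class TestWindowing:
    def test_short_sentence_single_window(self):
        assert window_spans(5, 10, 4) == [(0, 5)]

    def test_hand_enumerated_overlap_case(self):
        """12 positions, window 8, overlap 4: windows [0..7] and [4..11];
        position 5 is most central in the first, position 9 in the second."""
        spans = window_spans(12, 8, 4)
        assert spans == [(0, 8), (4, 12)]
        owners = assign_owner_windows(spans, 12)
        assert owners[5] == 0
        assert owners[9] == 1

    def test_every_position_owned(self):
        for n in (13, 20, 33):
            spans = window_spans(n, 8, 4)
            owners = assign_owner_windows(spans, n)
            assert all(o is not None for o in owners)
            for i, o in enumerate(owners):
                s, e = spans[o]
                assert s <= i < e


class TestAttention:
    def test_single_token_weight_one(self):
        Q = K = V = np.array([[1.0, 2.0]])
        out, w = attention(Q, K, V)
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(out, V)

    def test_identical_keys_uniform_weights(self):
        rng = np.random.default_rng(0)
        Q = rng.standard_normal((4, 3))
        K = np.tile(rng.standard_normal(3), (4, 1))
        V = rng.standard_normal((4, 3))
        out, w = attention(Q, K, V)
        np.testing.assert_allclose(w, np.full((4, 4), 0.25), atol=1e-12)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)))

    def test_three_token_case_matches_hand_formula(self):
        rng = np.random.default_rng(42)
        Q, K, V = (rng.standard_normal((3, 2)) for _ in range(3))
        out, w = attention(Q, K, V)
        # step-by-step: scores, scale, softmax, weighted values
        d_k = 2
        for i in range(3):
            raw = np.array([Q[i] @ K[j] for j in range(3)]) / np.sqrt(d_k)
            e = np.exp(raw - raw.max())
            p = e / e.sum()
            np.testing.assert_allclose(w[i], p, atol=1e-12)
            np.testing.assert_allclose(out[i], p @ V, atol=1e-12)

    def test_rows_sum_to_one_over_unmasked(self):
        rng = np.random.default_rng(1)
        Q, K, V = (rng.standard_normal((2, 5, 4)) for _ in range(3))
        mask = np.array([[True, True, True, False, False]] * 2)
        _, w = attention(Q, K, V, mask)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w[..., 3:] == 0)

    def test_all_masked_rejected(self):
        Q = K = V = np.zeros((1, 2, 3))
        with pytest.raises(ValueError):
            attention(Q, K, V, np.array([[False, False]]))


class TestMultiHead:
    def _params(self, rng, d):
        p = {}
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[name] = rng.standard_normal((d, d))
        for name in ("bq", "bk", "bv", "bo"):
            p[name] = rng.standard_normal(d)
        return p

    def test_single_head_equals_attention_plus_output_map(self):
        rng = np.random.default_rng(2)
        d = 6
        p = self._params(rng, d)
        X = rng.standard_normal((1, 4, d))
        out = multi_head(X, p, n_heads=1)
        Q, K, V = (X @ p[f"W{c}"] + p[f"b{c}"] for c in "qkv")
        direct, _ = attention(Q, K, V)
        np.testing.assert_allclose(out, direct @ p["Wo"] + p["bo"], atol=1e-10)

    def test_output_shape_matches_input(self):
        rng = np.random.default_rng(3)
        p = self._params(rng, 8)
        for n in (1, 3, 7):
            X = rng.standard_normal((2, n, 8))
            assert multi_head(X, p, n_heads=4).shape == X.shape

    def test_head_concatenation_layout(self):
        """With identity Q/K/V maps and one-hot value columns, each head's
        output occupies its own d_k-wide block of the concatenation."""
        d, h = 4, 2
        p = {
            "Wq": np.eye(d), "Wk": np.eye(d), "Wv": np.eye(d),
            "Wo": np.eye(d),
            "bq": np.zeros(d), "bk": np.zeros(d), "bv": np.zeros(d),
            "bo": np.zeros(d),
        }
        X = np.array([[[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]]])
        out = multi_head(X, p, n_heads=h)
        # identical tokens -> uniform attention -> output == value == X
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(d_e=10, n_heads=4)


def _tiny_model(m=3, d=8, seed=0, **kw) -> ContextTransformer:
    vocab = LabelVocabulary("MF", [f"GO:000000{i+1}" for i in range(m)])
    cfg = ModelConfig(
        d_e=d, n_heads=2, n_layers=2, max_sentence_len=6, d_ff=12,
        seed=seed, **kw,
    )
    return ContextTransformer(cfg, vocab)


class TestForward:
    def test_zero_weights_give_half_scores(self):
        model = _tiny_model()
        model.zero_params()
        tokens = np.random.default_rng(0).standard_normal((2, 4, 8))
        mask = np.ones((2, 4), bool)
        scores, _ = model.forward(tokens, mask)
        np.testing.assert_allclose(scores, 0.5, atol=1e-12)

    def test_scores_strictly_inside_unit_interval(self):
        model = _tiny_model(seed=5)
        tokens = np.random.default_rng(1).standard_normal((3, 5, 8))
        scores, _ = model.forward(tokens, np.ones((3, 5), bool))
        assert np.all(scores > 0) and np.all(scores < 1)

    def test_permutation_equivariance_without_positions(self):
        model = _tiny_model(use_position_embeddings=False)
        rng = np.random.default_rng(2)
        tokens = rng.standard_normal((1, 5, 8))
        mask = np.ones((1, 5), bool)
        perm = rng.permutation(5)
        base, _ = model.forward(tokens, mask)
        permed, _ = model.forward(tokens[:, perm], mask)
        np.testing.assert_allclose(permed, base[:, perm], atol=1e-10)

    def test_positions_break_equivariance(self):
        model = _tiny_model(use_position_embeddings=True)
        rng = np.random.default_rng(2)
        tokens = rng.standard_normal((1, 5, 8))
        mask = np.ones((1, 5), bool)
        perm = np.array([4, 0, 1, 2, 3])
        base, _ = model.forward(tokens, mask)
        permed, _ = model.forward(tokens[:, perm], mask)
        assert not np.allclose(permed, base[:, perm], atol=1e-6)

    def test_padding_invariance(self):
        """Extra padded slots change no real protein's score (1e-6)."""
        model = _tiny_model(seed=9)
        rng = np.random.default_rng(3)
        tokens = rng.standard_normal((1, 3, 8))
        base, _ = model.forward(tokens, np.ones((1, 3), bool))
        padded = np.concatenate(
            [tokens, rng.standard_normal((1, 3, 8))], axis=1
        )
        mask = np.array([[True, True, True, False, False, False]])
        out, _ = model.forward(padded, mask)
        np.testing.assert_allclose(out[:, :3], base, atol=1e-6)

    def test_width_mismatch_rejected(self):
        model = _tiny_model()
        with pytest.raises(ValueError, match="d_e"):
            model.forward(np.zeros((1, 2, 5)), np.ones((1, 2), bool))


class TestBceLoss:
    def test_half_score_single_positive_is_ln2(self):
        assert bce_loss(np.array([[0.5]]), np.array([[1.0]])) == pytest.approx(
            np.log(2)
        )

    def test_near_perfect_prediction_vanishes(self):
        for eps in (1e-2, 1e-4, 1e-6):
            y = np.array([[1.0, 0.0, 1.0]])
            s = np.array([[1 - eps, eps, 1 - eps]])
            assert bce_loss(s, y) < 3 * 2 * eps

    def test_random_case_matches_hand_formula(self):
        rng = np.random.default_rng(7)
        s = rng.uniform(0.05, 0.95, (4, 3))
        y = (rng.random((4, 3)) < 0.5).astype(float)
        expect = 0.0
        for i in range(4):
            row = 0.0
            for j in range(3):
                row -= y[i, j] * np.log(s[i, j]) + (1 - y[i, j]) * np.log(
                    1 - s[i, j]
                )
            expect += row / 4
        assert bce_loss(s, y) == pytest.approx(expect, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the full network agree with central
        differences on a handful of coordinates of every parameter."""
        model = _tiny_model(seed=4)
        rng = np.random.default_rng(5)
        tokens = rng.standard_normal((2, 3, 8))
        mask = np.array([[True, True, True], [True, True, False]])
        targets = (rng.random((2, 3, 3)) < 0.4).astype(float)

        def loss_fn():
            scores, _ = model.forward(tokens, mask)
            N = mask.sum()
            s = np.clip(scores, 1e-12, 1 - 1e-12)
            return float(
                -(
                    (targets * np.log(s) + (1 - targets) * np.log(1 - s))
                    * mask[..., None]
                ).sum()
                / N
            )

        _, grads, dtok = model.loss_and_grads(tokens, mask, targets, train=False)
        h = 1e-6
        par_rng = np.random.default_rng(6)
        for name, arr in model.params.items():
            flat = arr.ravel()
            for idx in par_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_fn()
                flat[idx] = orig - h
                down = loss_fn()
                flat[idx] = orig
                num = (up - down) / (2 * h)
                assert grads[name].ravel()[idx] == pytest.approx(
                    num, rel=1e-4, abs=1e-7
                ), name
        # token gradients too (used for joint fc-pooler training)
        for (b, i, j) in [(0, 0, 2), (1, 1, 5)]:
            orig = tokens[b, i, j]
            tokens[b, i, j] = orig + h
            up = loss_fn()
            tokens[b, i, j] = orig - h
            down = loss_fn()
            tokens[b, i, j] = orig
            assert dtok[b, i, j] == pytest.approx(
                (up - down) / (2 * h), rel=1e-4, abs=1e-7
            )


def _toy_training_setup(seed=0):
    rng = np.random.default_rng(seed)
    vocab = LabelVocabulary("MF", ["GO:0000001", "GO:0000002"])
    centroids = rng.standard_normal((2, 8)) * 2
    sentences, emb, annos = [], {}, {}
    for g in range(8):
        pids = []
        for i in range(4):
            pid = f"g{g}p{i}"
            cls = (g + i) % 2
            emb[pid] = centroids[cls] + 0.1 * rng.standard_normal(8)
            annos[pid] = {vocab.terms[cls]}
            pids.append(pid)
        sentences.append(GenomeSentence(f"g{g}", pids))
    return sentences, emb, AnnotationSet(annos, propagated=True), vocab


class TestTraining:
    def test_loss_decreases_and_history_reproducible(self):
        sentences, emb, annos, vocab = _toy_training_setup()
        cfg = ModelConfig(
            d_e=8, n_heads=2, n_layers=1, max_sentence_len=4, d_ff=16,
            learning_rate=5e-3, epochs=6, batch_size=4, seed=3,
        )
        model, hist = train(sentences, emb, annos, vocab, cfg)
        assert hist.train_loss[5] < hist.train_loss[0]
        _, hist2 = train(sentences, emb, annos, vocab, cfg)
        assert hist.train_loss == hist2.train_loss
        assert hist.val_loss == hist2.val_loss

    def test_empty_corpus_and_vocab_rejected(self):
        sentences, emb, annos, vocab = _toy_training_setup()
        cfg = ModelConfig(d_e=8, n_heads=2, max_sentence_len=4)
        with pytest.raises(ValueError):
            train([], emb, annos, vocab, cfg)
        with pytest.raises(ValueError):
            train(sentences, emb, annos, LabelVocabulary("MF", []), cfg)


class TestPredict:
    def test_row_count_and_singleton_path(self):
        sentences, emb, annos, vocab = _toy_training_setup()
        cfg = ModelConfig(
            d_e=8, n_heads=2, n_layers=1, max_sentence_len=4, seed=0
        )
        model = ContextTransformer(cfg, vocab)
        sm = predict(sentences, model, emb)
        assert len(sm.protein_ids) == sum(len(s) for s in sentences)
        single = GenomeSentence("solo", [sentences[0].protein_ids[0]])
        sm1 = predict([single], model, emb)
        tokens = emb[single.protein_ids[0]][None, None, :]
        direct, _ = model.forward(tokens, np.ones((1, 1), bool))
        np.testing.assert_allclose(sm1.scores[0], direct[0, 0], atol=1e-12)

    def test_full_sentence_equals_unwindowed_forward(self):
        """When max_sentence_len covers the sentence, windowed prediction
        reduces to one direct full-length forward pass."""
        sentences, emb, annos, vocab = _toy_training_setup()
        cfg = ModelConfig(
            d_e=8, n_heads=2, n_layers=1, max_sentence_len=10, seed=1
        )
        model = ContextTransformer(cfg, vocab)
        s = sentences[0]
        sm = predict([s], model, emb)
        tokens = np.stack([emb[p] for p in s.protein_ids])[None]
        direct, _ = model.forward(tokens, np.ones((1, len(s)), bool))
        np.testing.assert_allclose(sm.scores, direct[0], atol=1e-12)

    def test_missing_embedding_listed(self):
        sentences, emb, annos, vocab = _toy_training_setup()
        cfg = ModelConfig(d_e=8, n_heads=2, max_sentence_len=4)
        model = ContextTransformer(cfg, vocab)
        bad = dict(emb)
        del bad["g0p0"]
        with pytest.raises(KeyError, match="g0p0"):
            predict(sentences, model, bad)
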