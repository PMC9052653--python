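"""Core model math: composition, loss, gradients, training, persistence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import definition2vec as d2v
from definition2vec.corpus import DefinitionMap
from definition2vec.sgns import (
    UnigramTable,
    _iter_pairs,
    init_params,
)


def make_params(rng, dim, n_terms, n_def, beta, scale=0.8):
    return d2v.ModelParams(
        dim=dim,
        U_free=rng.normal(0, scale, (n_terms, dim)),
        V_ctx=rng.normal(0, scale, (n_terms, dim)),
        Z=rng.normal(0, scale, (n_def, dim)),
        beta=beta,
    )


class TestSigmoid:
    def test_zero(self):
        assert d2v.sigmoid(0.0) == 0.5

    def test_extreme_arguments_stable(self):
        assert d2v.sigmoid(700.0) == pytest.approx(1.0)
        assert d2v.sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)

    @given(st.floats(-500, 500))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, x):
        assert d2v.sigmoid(x) + d2v.sigmoid(-x) == pytest.approx(1.0)


class TestPairLoss:
    def test_orthogonal_context_pair_is_ln2(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert d2v.pair_loss(u, v, 1) == pytest.approx(math.log(2))

    def test_aligned_context_pair_vanishes(self):
        u = np.array([30.0, 0.0])
        assert d2v.pair_loss(u, u, 1) == pytest.approx(0.0, abs=1e-300)

    def test_negative_pair_value(self):
        u, v = np.array([1.0, 0.0]), np.array([2.0, 0.0])
        assert d2v.pair_loss(u, v, 0) == pytest.approx(2.1269280110429727)

    def test_nonnegative_and_stable(self):
        u = np.array([1000.0])
        assert d2v.pair_loss(u, u, 0) == pytest.approx(1e6)
        assert d2v.pair_loss(u, -u, 1) == pytest.approx(1e6)


class TestComposeTargetVector:
    def _setup(self, f, beta, dim=2):
        rng = np.random.default_rng(3)
        params = make_params(rng, dim, 3, 4, beta)
        defs = DefinitionMap(def_vocab=["a", "b", "c", "d"], defs={0: [1, 3]})
        return params, [f, 5, 5], defs

    def test_zero_frequency_gives_definition_mean(self):
        params, freq, defs = self._setup(f=0, beta=2.0)
        out = d2v.compose_target_vector(0, params, freq, defs)
        np.testing.assert_array_equal(out, params.Z[[1, 3]].mean(axis=0))

    def test_beta_zero_gives_free_vector(self):
        params, freq, defs = self._setup(f=9, beta=0.0)
        np.testing.assert_array_equal(
            d2v.compose_target_vector(0, params, freq, defs), params.U_free[0]
        )

    def test_hand_worked_blend(self):
        # f=4, beta=2: (2*(1,0) + 2*(0,1)) / 4 = (0.5, 0.5)
        params, freq, defs = self._setup(f=4, beta=2.0)
        params.U_free[0] = [1.0, 0.0]
        params.Z[1] = [0.0, 2.0]
        params.Z[3] = [0.0, 0.0]  # mean = (0, 1)
        out = d2v.compose_target_vector(0, params, freq, defs)
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_no_definition_gives_free_vector(self):
        params, freq, defs = self._setup(f=4, beta=2.0)
        np.testing.assert_array_equal(
            d2v.compose_target_vector(1, params, freq, defs), params.U_free[1]
        )

    def test_degenerate_corner_f0_beta0(self):
        params, freq, defs = self._setup(f=0, beta=0.0)
        np.testing.assert_array_equal(
            d2v.compose_target_vector(0, params, freq, defs), params.U_free[0]
        )

    def test_distance_to_free_vector_shrinks_with_frequency(self):
        deltas = []
        for f in [1, 10, 100, 10000]:
            params, freq, defs = self._setup(f=f, beta=10.0, dim=4)
            out = d2v.compose_target_vector(0, params, freq, defs)
            deltas.append(np.linalg.norm(out - params.U_free[0]))
        assert all(a > b for a, b in zip(deltas, deltas[1:]))


class TestSampleNegatives:
    def test_k_zero(self):
        rng = np.random.default_rng(0)
        table = UnigramTable([3, 1])
        assert len(d2v.sample_negatives(rng, 0, table, set())) == 0

    def test_single_term_forced(self):
        rng = np.random.default_rng(0)
        table = UnigramTable([7])
        assert list(d2v.sample_negatives(rng, 3, table, set())) == [0, 0, 0]

    def test_exclusion_respected(self):
        rng = np.random.default_rng(1)
        table = UnigramTable([5, 5, 5])
        draws = d2v.sample_negatives(rng, 200, table, {0})
        assert 0 not in set(int(x) for x in draws)

    def test_fully_excluded_raises(self):
        rng = np.random.default_rng(1)
        table = UnigramTable([5, 5])
        with pytest.raises(ValueError, match="support"):
            d2v.sample_negatives(rng, 1, table, {0, 1})

    def test_empirical_frequency_matches_distribution(self):
        # unigram probs {a: 0.75, b: 0.25} at exponent 1; binomial 3-SE band
        rng = np.random.default_rng(7)
        table = UnigramTable([75, 25], exponent=1.0)
        n = 100_000
        draws = d2v.sample_negatives(rng, n, table, set())
        p_hat = np.mean(np.asarray(draws) == 0)
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(p_hat - 0.75) < 3 * se


class TestSgdStepGradients:
    """Analytic updates must match finite differences of the summed loss."""

    @staticmethod
    def total_loss(params, t, ctx, negs, freq, defs):
        u = d2v.compose_target_vector(t, params, freq, defs)
        loss = d2v.pair_loss(u, params.V_ctx[ctx], 1)
        for j in negs:
            loss += d2v.pair_loss(u, params.V_ctx[j], 0)
        return loss

    def fd_grad(self, params, block, row, t, ctx, negs, freq, defs, h=1e-6):
        grad = np.empty(params.dim)
        arr = getattr(params, block)
        for c in range(params.dim):
            orig = arr[row, c]
            arr[row, c] = orig + h
            up = self.total_loss(params, t, ctx, negs, freq, defs)
            arr[row, c] = orig - h
            down = self.total_loss(params, t, ctx, negs, freq, defs)
            arr[row, c] = orig
            grad[c] = (up - down) / (2 * h)
        return grad

    def check_instance(self, rng, dim, K, f, beta, n_def_words):
        n_terms = 6
        params = make_params(rng, dim, n_terms, 5, beta)
        t, ctx = 0, 1
        negs = [int(x) for x in rng.integers(2, n_terms, size=K)]
        freq = [f, 3, 2, 5, 1, 4]
        dwords = [int(x) for x in rng.integers(0, 5, size=n_def_words)]
        defs = DefinitionMap(
            def_vocab=list("abcde"), defs={0: dwords} if dwords else {}
        )
        before = params.copy()
        d2v.sgd_step(t, ctx, negs, params, freq, defs, lr=1.0)

        def assert_close(analytic, fd):
            denom = max(np.linalg.norm(fd), 1e-6)
            assert np.linalg.norm(analytic - fd) / denom < 1e-5

        assert_close(
            before.U_free[t] - params.U_free[t],
            self.fd_grad(before, "U_free", t, t, ctx, negs, freq, defs),
        )
        for x in {ctx, *negs}:
            assert_close(
                before.V_ctx[x] - params.V_ctx[x],
                self.fd_grad(before, "V_ctx", x, t, ctx, negs, freq, defs),
            )
        for w in set(dwords):
            assert_close(
                before.Z[w] - params.Z[w],
                self.fd_grad(before, "Z", w, t, ctx, negs, freq, defs),
            )

    @pytest.mark.parametrize("beta", [0.0, 2.0, 10.0])
    @pytest.mark.parametrize("f", [0, 1, 4, 100])
    @pytest.mark.parametrize("n_def", [0, 1, 3])
    def test_gradients_match_finite_differences(self, beta, f, n_def):
        rng = np.random.default_rng(hash((beta, f, n_def)) % 2**31)
        for K in (1, 5):
            dim = int(rng.integers(3, 9))
            self.check_instance(rng, dim, K, f, beta, n_def)

    def test_lr_zero_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(5)
        params = make_params(rng, 3, 4, 2, beta=2.0)
        defs = DefinitionMap(def_vocab=["a", "b"], defs={0: [0, 1]})
        before = params.copy()
        d2v.sgd_step(0, 1, [2, 3], params, [2, 1, 1, 1], defs, lr=0.0)
        np.testing.assert_array_equal(before.U_free, params.U_free)
        np.testing.assert_array_equal(before.V_ctx, params.V_ctx)
        np.testing.assert_array_equal(before.Z, params.Z)

    def test_beta_zero_matches_textbook_skipgram_update(self):
        rng = np.random.default_rng(6)
        params = make_params(rng, 4, 5, 3, beta=0.0)
        defs = DefinitionMap(def_vocab=["a", "b", "c"], defs={0: [0, 2]})
        before = params.copy()
        lr = 0.1
        t, ctx, negs = 0, 2, [3, 4]
        d2v.sgd_step(t, ctx, negs, params, [3, 1, 1, 1, 1], defs, lr)
        # independent textbook computation
        u = before.U_free[t]
        grad_u = np.zeros(4)
        for x, label in [(ctx, 1.0), (negs[0], 0.0), (negs[1], 0.0)]:
            gx = d2v.sigmoid(float(u @ before.V_ctx[x])) - label
            grad_u += gx * before.V_ctx[x]
            np.testing.assert_allclose(
                params.V_ctx[x], before.V_ctx[x] - lr * gx * u, rtol=0, atol=1e-15
            )
        np.testing.assert_allclose(
            params.U_free[t], u - lr * grad_u, rtol=0, atol=1e-15
        )
        np.testing.assert_array_equal(params.Z, before.Z)  # untouched at beta=0

    def test_repeated_definition_word_updated_once_per_occurrence(self):
        rng = np.random.default_rng(8)
        base = make_params(rng, 3, 4, 3, beta=5.0)
        base.Z[2] = base.Z[1]  # identical rows => identical composed vector
        freq = [4, 2, 2, 2]
        single = base.copy()
        double = base.copy()
        d2v.sgd_step(0, 1, [2], single,
                     freq, DefinitionMap(["a", "b", "c"], {0: [1, 2]}), 0.05)
        d2v.sgd_step(0, 1, [2], double,
                     freq, DefinitionMap(["a", "b", "c"], {0: [1, 1]}), 0.05)
        # with the doubled word, its row absorbs both occurrence updates
        delta_single = base.Z[1] - single.Z[1]
        delta_double = base.Z[1] - double.Z[1]
        np.testing.assert_allclose(delta_double, 2 * delta_single, atol=1e-15)


class TestTraining:
    def test_empty_corpus_rejected(self, tiny_setup):
        vocab, _corpus, defs = tiny_setup
        with pytest.raises(ValueError, match="empty"):
            d2v.train(d2v.Corpus([]), defs, vocab, d2v.TrainConfig(epochs=1))

    def test_smoke_changes_parameters(self, tiny_setup):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=1, dim=8, window=2, negatives=2, seed=4)
        params, losses = d2v.train(corpus, defs, vocab, cfg)
        rng = np.random.default_rng(cfg.seed)
        init = init_params(len(vocab), len(defs.def_vocab), cfg, rng)
        assert not np.array_equal(params.U_free, init.U_free)
        assert len(losses) == 1 and np.isfinite(losses[0])

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            d2v.TrainConfig(epochs=0)

    def test_compiled_loop_matches_sequential_sgd_steps(self, tiny_setup):
        """The training kernel must reproduce a literal per-pair loop of
        sample_negatives + sgd_step sharing the same random stream."""
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=2, dim=8, window=2, negatives=3,
                              seed=11, beta=4.0)
        params, _ = d2v.train(corpus, defs, vocab, cfg)

        rng = np.random.default_rng(cfg.seed)
        manual = init_params(len(vocab), len(defs.def_vocab), cfg, rng)
        table = UnigramTable(vocab.freq, cfg.neg_exponent)
        for _epoch in range(cfg.epochs):
            for doc in corpus.documents:
                for _tpos, t, ctx in _iter_pairs(doc, cfg.window):
                    negs = d2v.sample_negatives(rng, cfg.negatives, table, {t, ctx})
                    d2v.sgd_step(t, ctx, negs, manual, vocab.freq, defs, cfg.lr)
        np.testing.assert_allclose(params.U_free, manual.U_free, atol=1e-10)
        np.testing.assert_allclose(params.V_ctx, manual.V_ctx, atol=1e-10)
        np.testing.assert_allclose(params.Z, manual.Z, atol=1e-10)

    def test_beta_zero_reduces_to_plain_skipgram(self, tiny_setup):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=2, dim=8, window=2, negatives=3,
                              seed=2, beta=0.0)
        p1, l1 = d2v.train(corpus, defs, vocab, cfg)
        p2, l2 = d2v.train_skipgram(corpus, defs, vocab, cfg)
        np.testing.assert_array_equal(p1.U_free, p2.U_free)
        np.testing.assert_array_equal(p1.V_ctx, p2.V_ctx)
        np.testing.assert_array_equal(p1.Z, p2.Z)
        assert l1 == l2

    def test_fixed_seed_is_bit_deterministic(self, tiny_setup):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=2, dim=8, window=2, seed=13)
        p1, l1 = d2v.train(corpus, defs, vocab, cfg)
        p2, l2 = d2v.train(corpus, defs, vocab, cfg)
        np.testing.assert_array_equal(p1.U_free, p2.U_free)
        np.testing.assert_array_equal(p1.V_ctx, p2.V_ctx)
        np.testing.assert_array_equal(p1.Z, p2.Z)
        assert l1 == l2

    def test_loss_decreases_on_tiny_corpus(self, tiny_setup):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=5, dim=8, window=2, seed=3)
        _params, losses = d2v.train(corpus, defs, vocab, cfg)
        assert losses[-1] <= losses[0]


class TestFinalizeAndOov:
    def test_embeddings_recomputable_from_parameters(self, tiny_setup):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=1, dim=8, window=2, seed=4, beta=3.0)
        params, _ = d2v.train(corpus, defs, vocab, cfg)
        table = d2v.finalize_embeddings(params, vocab, vocab.freq, defs)
        for i, term in enumerate(vocab.terms):
            np.testing.assert_array_equal(
                table[term], d2v.compose_target_vector(i, params, vocab.freq, defs)
            )
            if not defs.get(i):
                np.testing.assert_array_equal(table[term], params.U_free[i])

    def test_beta_zero_table_is_free_table(self, tiny_setup):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=1, dim=8, window=2, seed=4, beta=0.0)
        params, _ = d2v.train(corpus, defs, vocab, cfg)
        table = d2v.finalize_embeddings(params, vocab, vocab.freq, defs)
        np.testing.assert_array_equal(table.vectors, params.U_free)

    def test_oov_mean_and_consistency_with_compose(self):
        rng = np.random.default_rng(2)
        params = make_params(rng, 3, 2, 4, beta=7.0)
        defs = DefinitionMap(def_vocab=["a", "b", "c", "d"], defs={})
        np.testing.assert_array_equal(
            d2v.embed_oov(["b"], params, defs), params.Z[1]
        )
        params.Z[0] = [1.0, 0.0, 0.0]
        params.Z[1] = [0.0, 1.0, 0.0]
        np.testing.assert_allclose(
            d2v.embed_oov(["a", "b"], params, defs), [0.5, 0.5, 0.0]
        )
        # equals the composed target vector at frequency 0
        defs2 = DefinitionMap(def_vocab=["a", "b", "c", "d"], defs={0: [2, 3, 2]})
        np.testing.assert_array_equal(
            d2v.embed_oov(["c", "d", "c"], params, defs2),
            d2v.compose_target_vector(0, params, [0, 1], defs2),
        )

    def test_oov_unresolvable_words(self, caplog):
        rng = np.random.default_rng(2)
        params = make_params(rng, 3, 2, 2, beta=7.0)
        defs = DefinitionMap(def_vocab=["a", "b"], defs={})
        with caplog.at_level("WARNING"):
            out = d2v.embed_oov(["zzz", "a"], params, defs)
        np.testing.assert_array_equal(out, params.Z[0])
        with pytest.raises(ValueError, match="resolved"):
            d2v.embed_oov(["zzz"], params, defs)


class TestPersistence:
    def test_word2vec_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        table = d2v.EmbeddingTable(
            terms=["alpha", "beta_blocker", "gamma"],
            vectors=rng.normal(size=(3, 5)),
        )
        path = tmp_path / "emb.txt"
        table.save_word2vec(path)
        loaded = d2v.EmbeddingTable.load_word2vec(path)
        assert loaded.terms == table.terms
        np.testing.assert_array_equal(loaded.vectors, table.vectors)
        header = path.read_text(encoding="utf-8").splitlines()[0]
        assert header == "3 5"

    def test_checkpoint_round_trip_exact(self, tiny_setup, tmp_path):
        vocab, corpus, defs = tiny_setup
        cfg = d2v.TrainConfig(epochs=1, dim=8, window=2, seed=4, beta=3.0)
        params, _ = d2v.train(corpus, defs, vocab, cfg)
        path = tmp_path / "model.npz"
        d2v.sgns.save_checkpoint(path, params, vocab, defs, cfg)
        params2, vocab2, defs2, cfg2 = d2v.sgns.load_checkpoint(path)
        assert cfg2 == cfg
        assert vocab2.terms == vocab.terms and vocab2.freq == vocab.freq
        assert defs2.def_vocab == defs.def_vocab and defs2.defs == defs.defs
        np.testing.assert_array_equal(params2.U_free, params.U_free)
        np.testing.assert_array_equal(params2.V_ctx, params.V_ctx)
        np.testing.assert_array_equal(params2.Z, params.Z)
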