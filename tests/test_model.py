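"""Encoder math, hierarchy composition, scoring, ranking, checkpoints."""

import numpy as np
import pytest

from neurodict.model import (
    EncoderParams,
    ModelConfig,
    NeuralDictionary,
    ScoreDistribution,
    batch_score,
    compose_final_embeddings,
    elu,
    encode_phrase,
    ensemble_scores,
    load_checkpoint,
    save_checkpoint,
    score_concepts,
    top_k,
)
from neurodict.ontology import build_ancestry_matrix
from neurodict.train import _forward_backward
from neurodict.wordvec import WordVectorTable, make_fixture_vectors

from conftest import ancestry_row_oracle, random_dag


def random_params(seed, word_dim=6, filters=7, concept_dim=5):
    rng = np.random.Generator(np.random.PCG64(seed))
    return EncoderParams(
        W=rng.standard_normal((filters, word_dim)),
        b=rng.standard_normal(filters),
        U=rng.standard_normal((concept_dim, filters)),
    )


def straight_line_encode(params, X):
    """Independent re-computation of v = max_t ELU(Wx+b); e = normalize(ReLU(Uv))."""
    acts = []
    for t in range(X.shape[0]):
        z = params.W @ X[t] + params.b
        acts.append(np.where(z > 0, z, np.exp(z) - 1.0))
    v = np.max(np.stack(acts), axis=0)
    r = np.maximum(params.U @ v, 0.0)
    n = np.linalg.norm(r)
    return v, (r / n if n > 1e-12 else np.zeros_like(r))


def tiny_model(seed=0, n_concepts=4, use_hierarchy=False, use_negatives=False,
               word_dim=6, concept_dim=5, filters=7, ancestry=None, ids=None):
    rng = np.random.Generator(np.random.PCG64(seed))
    ids = ids or [f"C:{i}" for i in range(n_concepts)]
    table = make_fixture_vectors([f"w{i}" for i in range(10)], dim=word_dim, seed=seed)
    cfg = ModelConfig(
        word_dim=word_dim, concept_dim=concept_dim, conv_filters=filters,
        use_hierarchy=use_hierarchy, use_negatives=use_negatives, seed=seed,
    )
    rows = len(ids) + (1 if use_negatives else 0)
    return NeuralDictionary(
        cfg, ids, random_params(seed, word_dim, filters, concept_dim),
        rng.standard_normal((rows, concept_dim)), rng.standard_normal(rows),
        ancestry, table,
    )


class TestEncodePhrase:
    def test_single_token_pooling_is_identity(self):
        p = random_params(0)
        x = np.random.default_rng(1).standard_normal((1, 6))
        enc = encode_phrase(p, x)
        assert np.array_equal(enc.pooled, elu(p.W @ x[0] + p.b))

    def test_pooling_idempotent_on_repeats(self):
        p = random_params(0)
        x = np.random.default_rng(2).standard_normal(6)
        one = encode_phrase(p, np.stack([x]))
        two = encode_phrase(p, np.stack([x, x]))
        assert np.array_equal(one.embedding, two.embedding)

    def test_matches_straight_line_formula(self):
        p = random_params(3)
        X = np.random.default_rng(4).standard_normal((3, 6))
        enc = encode_phrase(p, X)
        v, e = straight_line_encode(p, X)
        assert np.allclose(enc.pooled, v, atol=1e-12)
        assert np.allclose(enc.embedding, e, atol=1e-12)

    def test_token_order_invariance_exact(self):
        p = random_params(5)
        X = np.random.default_rng(6).standard_normal((4, 6))
        fwd = encode_phrase(p, X).embedding
        rev = encode_phrase(p, X[::-1]).embedding
        assert np.array_equal(fwd, rev)

    def test_unit_norm_or_zero(self):
        p = random_params(7)
        for s in range(20):
            X = np.random.default_rng(s).standard_normal((3, 6))
            n = np.linalg.norm(encode_phrase(p, X).embedding)
            assert n == pytest.approx(1.0, abs=1e-9) or n == 0.0

    def test_degenerate_all_negative_maps_to_zero(self):
        # U <= 0 and v >= 0 force every ReLU input non-positive
        p = random_params(8)
        p.U[:] = -np.abs(p.U)
        X = np.abs(np.random.default_rng(9).standard_normal((2, 6))) + 1.0
        enc = encode_phrase(p, X)
        assert np.array_equal(enc.embedding, np.zeros_like(enc.embedding))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_phrase(random_params(0), np.zeros((0, 6)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_phrase(random_params(0), np.zeros((2, 5)))


class TestComposeFinalEmbeddings:
    def test_ablation_returns_input_bitwise(self):
        raw = np.random.default_rng(0).standard_normal((5, 3))
        assert compose_final_embeddings(raw, None, use_hierarchy=False) is raw

    def test_chain_sums_ancestor_rows(self, chain_ontology):
        am = build_ancestry_matrix(chain_ontology)
        raw = np.random.default_rng(1).standard_normal((3, 4))
        H = compose_final_embeddings(raw, am, True)
        i = {cid: am.row_of[cid] for cid in ("root", "c1", "c2")}
        want = raw[i["c2"]] + raw[i["c1"]] + raw[i["root"]]
        assert np.allclose(H[i["c2"]], want, atol=1e-12)

    def test_diamond_averages_parents(self, diamond_ontology):
        am = build_ancestry_matrix(diamond_ontology)
        raw = np.random.default_rng(2).standard_normal((4, 4))
        H = compose_final_embeddings(raw, am, True)
        i = am.row_of
        want = raw[i["c"]] + 0.5 * raw[i["a"]] + 0.5 * raw[i["b"]] + raw[i["root"]]
        assert np.allclose(H[i["c"]], want, atol=1e-12)

    def test_none_row_passes_through(self, chain_ontology):
        am = build_ancestry_matrix(chain_ontology)
        raw = np.random.default_rng(3).standard_normal((4, 4))  # 3 concepts + NONE
        H = compose_final_embeddings(raw, am, True)
        assert np.array_equal(H[3], raw[3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recursive_embedding_definition(self, seed):
        onto = random_dag(int(10 + 4 * seed), seed)
        am = build_ancestry_matrix(onto)
        raw = np.random.default_rng(seed).standard_normal((len(onto), 6))
        H = compose_final_embeddings(raw, am, True)

        memo = {}

        def final(cid):  # final(i) = raw(i) + mean over parents of final(p)
            if cid not in memo:
                r = raw[am.row_of[cid]].copy()
                parents = onto[cid].parents
                if parents:
                    r += np.mean([final(p) for p in parents], axis=0)
                memo[cid] = r
            return memo[cid]

        for cid in onto.concepts:
            assert np.abs(H[am.row_of[cid]] - final(cid)).max() < 1e-8


class TestScoring:
    def test_softmax_sums_to_one(self):
        m = tiny_model(0)
        dist = score_concepts(m, ["w0", "w3"])
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (dist.probs >= 0).all()

    def test_equal_rows_equal_biases_split_evenly(self):
        m = tiny_model(1, n_concepts=2)
        m.raw_embeddings[1] = m.raw_embeddings[0]
        m.bias[:] = 0.0
        dist = score_concepts(m, ["w1"])
        assert np.allclose(dist.probs, [0.5, 0.5], atol=1e-12)

    def test_matches_straight_line_softmax(self):
        m = tiny_model(2)
        phrase = ["w0", "w5", "w2"]
        _, e = straight_line_encode(m.params, m.word_table.encode_tokens(phrase))
        logits = m.raw_embeddings @ e + m.bias  # flat model: H == raw
        want = np.exp(logits - logits.max())
        want /= want.sum()
        assert np.allclose(score_concepts(m, phrase).probs, want, atol=1e-12)

    def test_batch_score_agrees_with_single(self):
        m = tiny_model(3, use_negatives=True)
        phrases = [["w0"], ["w1", "w2"], ["w3", "w4", "w5"]]
        batch = batch_score(m, phrases)
        for i, ph in enumerate(phrases):
            assert np.allclose(batch[i], score_concepts(m, ph).probs, atol=1e-12)

    def test_empty_phrase_rejected(self):
        with pytest.raises(ValueError):
            score_concepts(tiny_model(4), [])


class TestTopK:
    def test_uniform_tie_broken_by_id(self):
        dist = ScoreDistribution(ids=["b", "a", "c"], probs=np.full(3, 1 / 3))
        assert top_k(dist, 1)[0][0] == "a"

    def test_k_larger_than_n_returns_all(self):
        dist = ScoreDistribution(ids=["b", "a"], probs=np.array([0.4, 0.6]))
        assert [c for c, _ in top_k(dist, 10)] == ["a", "b"]

    def test_descending_order(self):
        dist = ScoreDistribution(ids=["a", "b", "c"], probs=np.array([0.7, 0.2, 0.1]))
        assert [c for c, _ in top_k(dist, 2)] == ["a", "b"]

    def test_none_row_excluded(self):
        dist = ScoreDistribution(
            ids=["a", "b"], probs=np.array([0.1, 0.2, 0.7]), has_none=True
        )
        assert [c for c, _ in top_k(dist, 5)] == ["b", "a"]


class TestEnsemble:
    def test_mean_of_one_is_itself(self):
        d = ScoreDistribution(ids=["a", "b"], probs=np.array([0.3, 0.7]))
        assert np.array_equal(ensemble_scores([d]).probs, d.probs)

    def test_symmetric_average(self):
        d1 = ScoreDistribution(ids=["a", "b"], probs=np.array([1.0, 0.0]))
        d2 = ScoreDistribution(ids=["a", "b"], probs=np.array([0.0, 1.0]))
        assert np.allclose(ensemble_scores([d1, d2]).probs, [0.5, 0.5], atol=1e-12)

    def test_matches_direct_averaging_oracle(self):
        rng = np.random.default_rng(0)
        mats = rng.dirichlet(np.ones(4), size=10)
        dists = [ScoreDistribution(ids=list("abcd"), probs=row) for row in mats]
        out = ensemble_scores(dists)
        assert np.allclose(out.probs, mats.mean(axis=0), atol=1e-12)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_sets_rejected(self):
        d1 = ScoreDistribution(ids=["a"], probs=np.array([1.0]))
        d2 = ScoreDistribution(ids=["b"], probs=np.array([1.0]))
        with pytest.raises(ValueError):
            ensemble_scores([d1, d2])


class TestGradients:
    def test_flat_model_embedding_gradient_matches_finite_differences(self):
        """With the hierarchy off the model is an ordinary linear-softmax
        classifier on e; check dL/dH̄ by central finite differences."""
        m = tiny_model(0, n_concepts=5, use_hierarchy=False, use_negatives=False)
        phrases = [["w0", "w1"], ["w2"], ["w3", "w4", "w5"], ["w6"]]
        labels = np.array([0, 2, 4, 1])
        from neurodict.model import pad_token_batch

        X, mask = pad_token_batch(m.word_table, phrases)
        _, grads = _forward_backward(m, X, mask, labels)
        dHraw = grads[3]

        def loss_at(Hraw):
            total = 0.0
            for ph, y in zip(phrases, labels):
                _, e = straight_line_encode(m.params, m.word_table.encode_tokens(ph))
                logits = Hraw @ e + m.bias
                p = np.exp(logits - logits.max())
                p /= p.sum()
                total += -np.log(p[y])
            return total / len(phrases)

        eps = 1e-6
        rng = np.random.default_rng(1)
        idx = [(int(i), int(j)) for i, j in
               zip(rng.integers(0, 5, 30), rng.integers(0, m.config.concept_dim, 30))]
        for i, j in idx:
            Hp, Hm = m.raw_embeddings.copy(), m.raw_embeddings.copy()
            Hp[i, j] += eps
            Hm[i, j] -= eps
            numeric = (loss_at(Hp) - loss_at(Hm)) / (2 * eps)
            assert numeric == pytest.approx(dHraw[i, j], abs=1e-4)


class TestCheckpoint:
    def test_round_trip_bitwise(self, tmp_path, chain_ontology):
        am = build_ancestry_matrix(chain_ontology)
        m = tiny_model(0, n_concepts=3, use_hierarchy=True, use_negatives=True,
                       ancestry=am, ids=am.ids)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        assert m2.concept_ids == m.concept_ids
        assert np.array_equal(m2.params.W, m.params.W)
        assert np.array_equal(m2.params.b, m.params.b)
        assert np.array_equal(m2.params.U, m.params.U)
        assert np.array_equal(m2.raw_embeddings, m.raw_embeddings)
        assert np.array_equal(m2.bias, m.bias)
        assert m2.config == m.config
        assert np.array_equal(m2.ancestry.A.toarray(), m.ancestry.A.toarray())
        for tok in m.word_table.vectors:
            assert np.array_equal(m2.word_table.lookup(tok), m.word_table.lookup(tok))
        # scoring through the reloaded model is identical
        ph = ["w0", "w1"]
        assert np.array_equal(score_concepts(m, ph).probs, score_concepts(m2, ph).probs)
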