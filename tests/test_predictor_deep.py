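"""Two-branch deep regressor: wiring, transforms, freezing, similarity."""

import numpy as np
import pandas as pd
import pytest

from promdesign.features_numeric import kmer_count_features
from promdesign.predictor_deep import (
    DeepModelConfig,
    StrengthTransform,
    build_inputs,
    fit_embedding_for,
    incremental_train,
    predict_deep,
    similarity_subset,
    train_deep,
)
from promdesign.synthetic_data import SyntheticSpec, generate_corpus

TINY = DeepModelConfig(embedding_dim=12, conv1d_filters=8, bilstm_hidden=4,
                       conv2d_filters=4, dense_width=32, epochs=3, batch_size=16,
                       seed=2)


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(SyntheticSpec(n=40, seed=2))


@pytest.fixture(scope="module")
def embedding(corpus):
    return fit_embedding_for(corpus, TINY, epochs=1)


@pytest.fixture(scope="module")
def model(corpus, embedding):
    return train_deep(corpus, TINY, embedding=embedding)


def test_build_inputs_shapes(corpus, embedding):
    xk, xp, y = build_inputs(corpus, embedding, TINY)
    assert xk.shape == (40, 48, 12)
    assert xp.shape == (40, 20, 20, 1)
    assert y.shape == (40,) and (y > 0).all()


def test_build_inputs_requires_strength(embedding, corpus):
    from promdesign.sequence_io import PromoterRecord
    bare = [PromoterRecord(r.id, r.sequence) for r in corpus]
    with pytest.raises(ValueError, match="without strength"):
        build_inputs(bare, embedding, TINY)


def test_strength_transform_round_trip(rng):
    y = np.exp(rng.normal(2, 1, size=50))
    t = StrengthTransform.fit(y)
    z = t.forward(y)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(t.inverse(z), y, rtol=1e-9)


def test_history_covers_epochs_and_is_finite(model):
    assert len(model.history) == TINY.epochs
    assert np.isfinite(model.history[["train_mse", "val_mse"]]).all().all()


def test_empty_auxiliary_equals_no_auxiliary(corpus, embedding):
    a = train_deep(corpus, TINY, embedding=embedding, auxiliary_corpus=[])
    b = train_deep(corpus, TINY, embedding=embedding, auxiliary_corpus=None)
    for ta, tb in zip(a.net.params, b.net.params):
        np.testing.assert_array_equal(ta.data, tb.data)


def test_auxiliary_records_counted(corpus, embedding):
    aux = generate_corpus(SyntheticSpec(n=25, seed=9))
    emb = fit_embedding_for(corpus, TINY, extra_records=aux, epochs=1)
    m = train_deep(corpus, TINY, embedding=emb, auxiliary_corpus=aux)
    assert m.provenance["n_auxiliary"] == 25


def test_prediction_deterministic_and_batch_invariant(model, corpus):
    preds = predict_deep(model, corpus)
    assert list(preds.index) == [r.id for r in corpus]
    again = predict_deep(model, corpus)
    pd.testing.assert_frame_equal(preds, again)
    singles = pd.concat([predict_deep(model, [r]) for r in corpus[:5]])
    np.testing.assert_allclose(preds.iloc[:5].to_numpy(), singles.to_numpy(),
                               atol=1e-10)


def test_validation_fraction_bounds():
    with pytest.raises(ValueError):
        DeepModelConfig(validation_fraction=0.0)
    with pytest.raises(ValueError):
        DeepModelConfig(validation_fraction=1.0)


class TestIncremental:
    def test_full_lock_is_bit_identical(self, model, corpus):
        before = model.parameter_checksums()
        updated = incremental_train(model, corpus[:20], lock_fraction=1.0,
                                    seed=5, epochs=2)
        assert updated.parameter_checksums() == before
        pd.testing.assert_frame_equal(predict_deep(updated, corpus[:5]),
                                      predict_deep(model, corpus[:5]))

    def test_half_lock_freezes_exact_count(self, model, corpus):
        before = model.parameter_checksums()
        updated = incremental_train(model, corpus[:20], lock_fraction=0.5,
                                    seed=5, epochs=2)
        T = len(model.net.params)
        locked = updated.provenance["locked_tensors"]
        assert len(locked) == round(0.5 * T)
        after = updated.parameter_checksums()
        for name in locked:
            assert after[name] == before[name]
        assert any(after[n] != before[n] for n in before if n not in locked)

    def test_original_model_untouched(self, model, corpus):
        before = model.parameter_checksums()
        incremental_train(model, corpus[:20], lock_fraction=0.0, seed=1, epochs=1)
        assert model.parameter_checksums() == before

    def test_lock_fraction_bounds(self, model, corpus):
        with pytest.raises(ValueError):
            incremental_train(model, corpus[:5], lock_fraction=1.5)
        with pytest.raises(ValueError):
            incremental_train(model, [], lock_fraction=0.5)


class TestSimilaritySubset:
    def test_identical_query_ranks_first(self, corpus):
        subset, sims = similarity_subset(corpus, [corpus[3].sequence], top_n=1)
        assert subset[0].id == corpus[3].id
        assert sims.loc[corpus[3].id] == pytest.approx(1.0)

    def test_top_n_covers_corpus(self, corpus):
        subset, _ = similarity_subset(corpus, [corpus[0].sequence], top_n=1000)
        assert len(subset) == len(corpus)

    def test_matches_all_pairs_oracle(self, corpus, random_sequence):
        queries = [random_sequence(50) for _ in range(3)]
        subset, _ = similarity_subset(corpus, queries, top_n=4)
        chosen = {r.id for r in subset}
        expected = set()
        for q in queries:
            qv = kmer_count_features(q, (3,)).to_numpy()
            sims = []
            for r in corpus:
                tv = kmer_count_features(r.sequence, (3,)).to_numpy()
                sims.append(qv @ tv / (np.linalg.norm(qv) * np.linalg.norm(tv)))
            order = sorted(range(len(corpus)), key=lambda i: (-sims[i], i))
            expected.update(corpus[i].id for i in order[:4])
        assert chosen == expected

    def test_top_n_validation(self, corpus):
        with pytest.raises(ValueError):
            similarity_subset(corpus, ["A" * 50], top_n=0)
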