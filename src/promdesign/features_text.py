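"""String-based featurizers and the trainable k-mer embedding.

Sequences are treated as text in two ways:

* **k-mer embeddings** — overlapping k-mers are "words"; a skip-gram
  model with negative sampling learns a D-dimensional vector per k-mer
  from its context window, and a sequence becomes the (n_kmers, D)
  matrix of its k-mer vectors (for 50-mers at k=3: (48, 100)).  The same
  machinery, with subword units, backs the FastText-style featurizer,
  and with document units the Doc2Vec-style featurizer.
* **classic text vectorizers** — character counts, character n-gram
  counts, tf-idf, feature hashing, and the LDA/LSA/PCA/t-SNE reductions
  of the count matrix, all via scikit-learn.

Every stochastic featurizer takes an explicit seed.  The ``glove`` and
``bert`` ids are declared stubs (they would require pretrained weights)
and raise :class:`FeaturizerNotImplementedError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, LatentDirichletAllocation, TruncatedSVD
from sklearn.feature_extraction.text import (
    CountVectorizer,
    HashingVectorizer,
    TfidfVectorizer,
)
from sklearn.manifold import TSNE

from .features_numeric import extract_kmers
from .sequence_io import BASES

__all__ = [
    "SUPPORTED_FEATURIZERS",
    "STUB_FEATURIZERS",
    "FeaturizerNotImplementedError",
    "KmerEmbeddingModel",
    "train_kmer_embedding",
    "embed_sequence",
    "StringFeatureBlock",
    "fit_string_block",
    "assemble_feature_matrix",
]

STUB_FEATURIZERS = ("glove", "bert")
SUPPORTED_FEATURIZERS = (
    "count",
    "count_ngrams",
    "tfidf",
    "hashing",
    "lda",
    "lsa",
    "pca",
    "tsne",
    "word2vec_pooled",
    "fasttext_pooled",
    "doc2vec",
) + STUB_FEATURIZERS


class FeaturizerNotImplementedError(NotImplementedError):
    """Raised for featurizer ids that depend on unavailable pretrained weights."""


class OutOfVocabularyError(KeyError):
    """A k-mer was not seen when the embedding model was trained."""


# ---------------------------------------------------------------------------
# skip-gram with negative sampling (shared trainer)
# ---------------------------------------------------------------------------


def _sgns_train(
    unit_sets: np.ndarray,
    contexts: np.ndarray,
    n_units: int,
    n_vocab_out: int,
    dim: int,
    epochs: int,
    negative: int,
    lr: float,
    rng: np.random.Generator,
    w_out: np.ndarray | None = None,
    freeze_out: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mini-batched skip-gram/negative-sampling SGD.

    ``unit_sets`` is (P, S): per training pair, the S input-unit indices
    whose mean vector predicts the output word ``contexts[p]``.  S = 1
    recovers plain word2vec; S > 1 gives subword (FastText-style) input;
    document-id units give PV-DBOW (Doc2Vec-style).
    """
    w_in = (rng.random((n_units, dim)) - 0.5) / dim
    if w_out is None:
        w_out = np.zeros((n_vocab_out, dim))
    counts = np.bincount(contexts, minlength=n_vocab_out).astype(np.float64)
    probs = counts**0.75
    probs /= probs.sum()
    P, S = unit_sets.shape
    batch = 1024
    n_batches = max(1, -(-P // batch)) * epochs
    step = 0
    for _ in range(epochs):
        order = rng.permutation(P)
        for s0 in range(0, P, batch):
            sel = order[s0 : s0 + batch]
            # mean-normalized batch gradient: with a small vocabulary each
            # index receives many contributions per batch, and summed
            # updates would diverge
            eta = lr * max(0.1, 1.0 - step / n_batches) / len(sel)
            step += 1
            U = unit_sets[sel]
            h = w_in[U].mean(axis=1)
            neg = rng.choice(n_vocab_out, size=(len(sel), negative), p=probs)
            out_idx = np.concatenate([contexts[sel][:, None], neg], axis=1)
            vo = w_out[out_idx]
            score = np.clip(np.einsum("bd,bkd->bk", h, vo), -30.0, 30.0)
            sig = 1.0 / (1.0 + np.exp(-score))
            sig[:, 0] -= 1.0  # gradient of -log sigma for the positive column
            gh = np.einsum("bk,bkd->bd", sig, vo)
            if not freeze_out:
                gvo = sig[:, :, None] * h[:, None, :]
                np.add.at(w_out, out_idx, -eta * gvo)
            gin = np.repeat(gh[:, None, :] / S, S, axis=1)
            np.add.at(w_in, U, -eta * gin)
    return w_in, w_out


def _skipgram_pairs(
    sentences: Sequence[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for toks in sentences:
        n = len(toks)
        for d in range(1, window + 1):
            if d >= n:
                break
            centers.append(toks[:-d])
            contexts.append(toks[d:])
            centers.append(toks[d:])
            contexts.append(toks[:-d])
    return (
        np.concatenate(centers).astype(np.int32),
        np.concatenate(contexts).astype(np.int32),
    )


@dataclass
class KmerEmbeddingModel:
    """Skip-gram k-mer embedding: vocabulary plus one D-vector per k-mer."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (V, D)
    dim: int
    k: int
    seed: int

    def vector(self, kmer: str) -> np.ndarray:
        if kmer not in self.vocab:
            raise OutOfVocabularyError(
                f"k-mer {kmer!r} was not in the embedding training corpus"
            )
        return self.vectors[self.vocab[kmer]]


def train_kmer_embedding(
    corpus: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    epochs: int = 3,
    negative: int = 5,
    lr: float = 5.0,
    seed: int = 0,
) -> KmerEmbeddingModel:
    """Train a skip-gram embedding on k-mer "sentences".

    Every k-mer occurring in the corpus enters the vocabulary (min count
    1), so sequences drawn from the corpus can always be embedded.
    Deterministic for fixed (corpus, seed, hyperparameters).
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("embedding corpus is empty")
    k = len(corpus[0][0])
    vocab_list = sorted({km for sent in corpus for km in sent})
    vocab = {km: i for i, km in enumerate(vocab_list)}
    sentences = [np.array([vocab[km] for km in sent], dtype=np.int32) for sent in corpus]
    centers, contexts = _skipgram_pairs(sentences, window)
    rng = np.random.default_rng(seed)
    w_in, _ = _sgns_train(
        centers[:, None], contexts, len(vocab), len(vocab), dim, epochs, negative, lr, rng
    )
    return KmerEmbeddingModel(vocab=vocab, vectors=w_in, dim=dim, k=k, seed=seed)


def embed_sequence(model: KmerEmbeddingModel, kmers: Sequence[str]) -> np.ndarray:
    """Stack the embedding vectors of a k-mer list into an (n, D) matrix."""
    return np.stack([model.vector(km) for km in kmers])


# ---------------------------------------------------------------------------
# FastText- and Doc2Vec-style models (share the SGNS trainer)
# ---------------------------------------------------------------------------


def _subword_units(kmer: str) -> list[str]:
    """The k-mer itself, its character bigrams, and its characters."""
    grams = [kmer] + [kmer[i : i + 2] for i in range(len(kmer) - 1)] + list(kmer)
    return grams


@dataclass
class _SubwordEmbedding:
    unit_vocab: dict[str, int]
    unit_vectors: np.ndarray
    dim: int
    k: int

    def kmer_vector(self, kmer: str) -> np.ndarray:
        idx = [self.unit_vocab[u] for u in _subword_units(kmer) if u in self.unit_vocab]
        if not idx:
            raise OutOfVocabularyError(f"no known subword units for {kmer!r}")
        return self.unit_vectors[idx].mean(axis=0)


def _train_subword_embedding(
    corpus: Sequence[Sequence[str]], dim: int, window: int, epochs: int,
    negative: int, lr: float, seed: int,
) -> _SubwordEmbedding:
    k = len(corpus[0][0])
    kmer_list = sorted({km for sent in corpus for km in sent})
    units = sorted({u for km in kmer_list for u in _subword_units(km)})
    unit_vocab = {u: i for i, u in enumerate(units)}
    out_vocab = {km: i for i, km in enumerate(kmer_list)}
    S = 2 * k  # kmer + (k-1) bigrams + k chars
    unit_matrix = np.array(
        [[unit_vocab[u] for u in _subword_units(km)] for km in kmer_list], dtype=np.int32
    )
    sentences = [np.array([out_vocab[km] for km in s], dtype=np.int32) for s in corpus]
    centers, contexts = _skipgram_pairs(sentences, window)
    rng = np.random.default_rng(seed)
    w_in, _ = _sgns_train(
        unit_matrix[centers], contexts, len(units), len(out_vocab),
        dim, epochs, negative, lr, rng,
    )
    assert unit_matrix.shape[1] == S
    return _SubwordEmbedding(unit_vocab=unit_vocab, unit_vectors=w_in, dim=dim, k=k)


@dataclass
class _DocEmbedding:
    """PV-DBOW: one trained vector per fitting document; inference for new docs."""

    doc_vectors: np.ndarray
    word_vocab: dict[str, int]
    w_out: np.ndarray
    dim: int
    k: int
    seed: int
    epochs: int
    lr: float
    negative: int

    def infer(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        toks = [
            np.array([self.word_vocab[km] for km in s if km in self.word_vocab], np.int32)
            for s in sentences
        ]
        doc_ids = np.concatenate(
            [np.full(len(t), i, dtype=np.int32) for i, t in enumerate(toks)]
        )
        contexts = np.concatenate(toks).astype(np.int32)
        rng = np.random.default_rng(self.seed + 1)
        vecs, _ = _sgns_train(
            doc_ids[:, None], contexts, len(toks), self.w_out.shape[0],
            self.dim, self.epochs, self.negative, self.lr, rng,
            w_out=self.w_out, freeze_out=True,
        )
        return vecs


def _train_doc_embedding(
    corpus: Sequence[Sequence[str]], dim: int, epochs: int, negative: int,
    lr: float, seed: int,
) -> _DocEmbedding:
    k = len(corpus[0][0])
    vocab = {km: i for i, km in enumerate(sorted({km for s in corpus for km in s}))}
    toks = [np.array([vocab[km] for km in s], dtype=np.int32) for s in corpus]
    doc_ids = np.concatenate([np.full(len(t), i, dtype=np.int32) for i, t in enumerate(toks)])
    contexts = np.concatenate(toks).astype(np.int32)
    rng = np.random.default_rng(seed)
    doc_vecs, w_out = _sgns_train(
        doc_ids[:, None], contexts, len(corpus), len(vocab), dim, epochs, negative, lr, rng
    )
    return _DocEmbedding(
        doc_vectors=doc_vecs, word_vocab=vocab, w_out=w_out, dim=dim, k=k,
        seed=seed, epochs=epochs, lr=lr, negative=negative,
    )


# ---------------------------------------------------------------------------
# string feature blocks
# ---------------------------------------------------------------------------


@dataclass
class StringFeatureBlock:
    """A fitted featurizer plus its feature matrix on the fitting corpus."""

    featurizer_id: str
    matrix: pd.DataFrame  # rows = sequence ids, columns prefixed with the id
    _transform: Callable[[Sequence[str], Sequence[str]], pd.DataFrame] = field(repr=False)

    def transform(self, sequences: Sequence[str], ids: Sequence[str] | None = None) -> pd.DataFrame:
        ids = list(ids) if ids is not None else [f"s{i}" for i in range(len(sequences))]
        return self._transform(list(sequences), ids)


def _frame(values: np.ndarray, ids: Sequence[str], names: list[str], fid: str) -> pd.DataFrame:
    return pd.DataFrame(
        np.asarray(values, dtype=np.float64),
        index=pd.Index(ids, name="id"),
        columns=[f"{fid}:{n}" for n in names],
    )


def fit_string_block(
    featurizer_id: str,
    sequences: Sequence[str],
    params: dict | None = None,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> StringFeatureBlock:
    """Fit one string featurizer on a corpus and return the fitted block.

    ``params`` override featurizer-specific defaults (n-gram range,
    reduced dimension, hashing width, embedding hyperparameters).  The
    block's ``transform`` re-applies the fitted state to new sequences;
    t-SNE has no out-of-sample transform and only reproduces its fitting
    corpus.
    """
    params = dict(params or {})
    sequences = [s.upper() for s in sequences]
    ids = list(ids) if ids is not None else [f"s{i}" for i in range(len(sequences))]
    if len(ids) != len(sequences):
        raise ValueError("ids and sequences length mismatch")
    fid = featurizer_id

    if fid in STUB_FEATURIZERS:
        raise FeaturizerNotImplementedError(
            f"featurizer {fid!r} requires pretrained weights and is not implemented"
        )
    if fid not in SUPPORTED_FEATURIZERS:
        raise ValueError(f"unknown featurizer id {fid!r}")

    if fid in ("count", "tfidf"):
        vocab = {b: i for i, b in enumerate(BASES)}
        cls = CountVectorizer if fid == "count" else TfidfVectorizer
        vec = cls(analyzer="char", lowercase=False, vocabulary=vocab)
        mat = vec.fit_transform(sequences).toarray()
        names = list(BASES)

        def tf(seqs, sids, vec=vec, names=names):
            return _frame(vec.transform(seqs).toarray(), sids, names, fid)

    elif fid == "count_ngrams":
        nrange = tuple(params.get("ngram_range", (2, 3)))
        vec = CountVectorizer(analyzer="char", lowercase=False, ngram_range=nrange)
        mat = vec.fit_transform(sequences).toarray()
        names = list(vec.get_feature_names_out())

        def tf(seqs, sids, vec=vec, names=names):
            return _frame(vec.transform(seqs).toarray(), sids, names, fid)

    elif fid == "hashing":
        width = int(params.get("n_features", 64))
        vec = HashingVectorizer(
            analyzer="char", lowercase=False, ngram_range=(1, 3),
            n_features=width, alternate_sign=False, norm="l2",
        )
        mat = vec.transform(sequences).toarray()
        names = [f"h{i}" for i in range(width)]

        def tf(seqs, sids, vec=vec, names=names):
            return _frame(vec.transform(seqs).toarray(), sids, names, fid)

    elif fid in ("lda", "lsa", "pca", "tsne"):
        nrange = tuple(params.get("ngram_range", (1, 3)))
        counts_vec = CountVectorizer(analyzer="char", lowercase=False, ngram_range=nrange)
        counts = counts_vec.fit_transform(sequences)
        if len(sequences) < 2 and fid in ("pca", "tsne"):
            raise ValueError(f"{fid} requires at least 2 sequences")
        if fid == "tsne":
            dim = int(params.get("dim", 2))
            perplexity = min(float(params.get("perplexity", 30.0)), len(sequences) - 1)
            reducer = TSNE(n_components=dim, random_state=seed, perplexity=perplexity,
                           init="pca")
            mat = reducer.fit_transform(counts.toarray())
            names = [f"dim{i}" for i in range(dim)]
            fitted = _frame(mat, ids, names, fid)

            def tf(seqs, sids, fitted=fitted, ref=list(sequences)):
                if list(seqs) != ref:
                    raise NotImplementedError(
                        "t-SNE has no out-of-sample transform; only the fitting "
                        "corpus can be reproduced"
                    )
                out = fitted.copy()
                out.index = pd.Index(sids, name="id")
                return out

        else:
            max_dim = min(counts.shape[1], len(sequences))
            dim = min(int(params.get("dim", 10)), max_dim if fid == "lda" else max_dim - 1)
            if dim < 1:
                raise ValueError(f"{fid}: reduced dimension must be >= 1")
            if fid == "lda":
                reducer = LatentDirichletAllocation(n_components=dim, random_state=seed)
                mat = reducer.fit_transform(counts)
            elif fid == "lsa":
                reducer = TruncatedSVD(n_components=dim, random_state=seed)
                mat = reducer.fit_transform(counts)
            else:  # pca
                reducer = PCA(n_components=dim, random_state=seed)
                mat = reducer.fit_transform(counts.toarray())
            names = [f"dim{i}" for i in range(dim)]

            def tf(seqs, sids, vec=counts_vec, reducer=reducer, names=names, fid=fid):
                c = vec.transform(seqs)
                out = reducer.transform(c.toarray() if fid == "pca" else c)
                return _frame(out, sids, names, fid)

    elif fid in ("word2vec_pooled", "fasttext_pooled", "doc2vec"):
        k = int(params.get("k", 3))
        dim = int(params.get("dim", params.get("d", 32)))
        epochs = int(params.get("epochs", 3))
        window = int(params.get("window", 5))
        corpus = [extract_kmers(s, k) for s in sequences]
        names = [f"dim{i}" for i in range(dim)]
        if fid == "word2vec_pooled":
            model = train_kmer_embedding(corpus, dim=dim, window=window,
                                         epochs=epochs, seed=seed)

            def tf(seqs, sids, model=model, k=k, names=names):
                pooled = [embed_sequence(model, extract_kmers(s, k)).mean(axis=0) for s in seqs]
                return _frame(np.stack(pooled), sids, names, fid)

            mat = None
        elif fid == "fasttext_pooled":
            model = _train_subword_embedding(corpus, dim, window, epochs, 5, 5.0, seed)

            def tf(seqs, sids, model=model, k=k, names=names):
                pooled = [
                    np.stack([model.kmer_vector(km) for km in extract_kmers(s, k)]).mean(axis=0)
                    for s in seqs
                ]
                return _frame(np.stack(pooled), sids, names, fid)

            mat = None
        else:  # doc2vec
            model = _train_doc_embedding(corpus, dim, epochs, 5, 5.0, seed)
            fitted = _frame(model.doc_vectors, ids, names, fid)

            def tf(seqs, sids, model=model, k=k, names=names, fitted=fitted,
                   ref=list(sequences)):
                if list(seqs) == ref:
                    out = fitted.copy()
                    out.index = pd.Index(sids, name="id")
                    return out
                corpus = [extract_kmers(s, k) for s in seqs]
                return _frame(model.infer(corpus), sids, names, fid)

            mat = None
        if mat is None:
            block_matrix = tf(sequences, ids)
            return StringFeatureBlock(fid, block_matrix, tf)

    else:  # pragma: no cover - guarded above
        raise ValueError(f"unknown featurizer id {fid!r}")

    return StringFeatureBlock(fid, _frame(mat, ids, names, fid), tf)


def assemble_feature_matrix(
    blocks: Sequence[StringFeatureBlock | pd.DataFrame],
    numeric_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concatenate feature blocks column-wise into one named matrix.

    All blocks must cover the same sequence ids in the same order; column
    names must be globally unique (block columns carry featurizer-id
    prefixes).  Deterministic: same inputs give a bitwise-identical frame.
    """
    frames = [b.matrix if isinstance(b, StringFeatureBlock) else b for b in blocks]
    if numeric_features is not None:
        frames.append(numeric_features)
    if not frames:
        raise ValueError("no feature blocks given")
    index = frames[0].index
    for f in frames[1:]:
        if len(f.index) != len(index) or not (f.index == index).all():
            raise ValueError("feature blocks cover different sequences or orders")
    out = pd.concat(frames, axis=1)
    dup = out.columns[out.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature column names: {list(dup[:5])}")
    return out
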