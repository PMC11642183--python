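"""Two-branch deep regressor for promoter strength (model 1).

The k-mer branch embeds each 50 bp sequence as a (48, 100) matrix of
skip-gram k-mer vectors, applies a 1-D convolution + max-pooling and a
bidirectional LSTM; the structural branch feeds the (20, 20, 1) CGR
occupancy grid through a 2-D convolution + max-pooling.  The two branch
outputs are concatenated into a dense ReLU head of width 512 ending in a
single linear output.  The target is log-standardized strength; the loss
is MSE under Adam, with the learning rate halved when validation loss
plateaus.

Training can pool an auxiliary corpus (a second species' promoters) into
the training split to stabilize fitting when the primary corpus is
small, and a fitted model can be *incrementally trained* on new records
with a seeded random subset of its parameter tensors locked (frozen
bit-for-bit), retaining prior knowledge while adapting to the new data.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity

from . import nn
from .features_numeric import cgr_trajectory, extract_kmers, kmer_count_features, pssm_from_cgr
from .features_text import KmerEmbeddingModel, embed_sequence, train_kmer_embedding
from .sequence_io import PromoterRecord

__all__ = ["DeepModelConfig", "StrengthTransform", "TrainedDeepModel", "build_inputs",
           "train_deep", "predict_deep", "incremental_train", "similarity_subset",
           "fit_embedding_for"]


@dataclass(frozen=True)
class DeepModelConfig:
    k: int = 3
    embedding_dim: int = 100
    conv1d_filters: int = 64
    conv1d_kernel: int = 3
    pool_width: int = 2
    bilstm_hidden: int = 32
    conv2d_filters: int = 32
    conv2d_kernel: int = 3
    grid_size: int = 20
    dense_width: int = 512
    lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    epochs: int = 30
    batch_size: int = 64
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class StrengthTransform:
    """Log-standardization of strength: z = (log(y + eps) - mean) / sd."""

    mean: float
    sd: float
    eps: float = 0.0

    @classmethod
    def fit(cls, y: np.ndarray, eps: float = 0.0) -> "StrengthTransform":
        ly = np.log(np.asarray(y, dtype=np.float64) + eps)
        sd = float(ly.std())
        return cls(mean=float(ly.mean()), sd=sd if sd > 0 else 1.0, eps=eps)

    def forward(self, y) -> np.ndarray:
        return (np.log(np.asarray(y, dtype=np.float64) + self.eps) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.exp(np.asarray(z, dtype=np.float64) * self.sd + self.mean) - self.eps


class _DeepNet:
    """The two-branch network; owns an ordered list of parameter tensors."""

    def __init__(self, cfg: DeepModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.conv1 = nn.Conv1D(cfg.embedding_dim, cfg.conv1d_filters, cfg.conv1d_kernel,
                               rng, name="kmer.conv")
        self.bilstm = nn.BiLSTM(cfg.conv1d_filters, cfg.bilstm_hidden, rng, name="kmer.bilstm")
        self.conv2 = nn.Conv2D(1, cfg.conv2d_filters, cfg.conv2d_kernel, rng, name="pssm.conv")
        g_out = (cfg.grid_size - cfg.conv2d_kernel + 1) // cfg.pool_width
        concat_width = 2 * cfg.bilstm_hidden + cfg.conv2d_filters * g_out * g_out
        self.dense = nn.Dense(concat_width, cfg.dense_width, rng, name="head.dense")
        self.out = nn.Dense(cfg.dense_width, 1, rng, name="head.out")
        self.out.W.data *= 0.1  # small initial output keeps early MSE near target variance
        self.layers = [self.conv1, self.bilstm, self.conv2, self.dense, self.out]

    @property
    def param_names(self) -> list[str]:
        return [t.name for layer in self.layers for t in layer.params.values()]

    @property
    def params(self) -> list[nn.Tensor]:
        return [t for layer in self.layers for t in layer.params.values()]

    def forward(self, x_kmer: np.ndarray, x_pssm: np.ndarray) -> nn.Tensor:
        h1 = self.conv1(nn.Tensor(x_kmer)).relu()
        h1 = nn.maxpool1d(h1, self.cfg.pool_width)
        h1 = self.bilstm(h1)
        h2 = self.conv2(nn.Tensor(x_pssm)).relu()
        h2 = nn.maxpool2d(h2, self.cfg.pool_width)
        h2 = h2.reshape(h2.shape[0], -1)
        h = nn.concat([h1, h2], axis=1)
        return self.out(self.dense(h).relu())


@dataclass
class TrainedDeepModel:
    net: _DeepNet = field(repr=False)
    config: DeepModelConfig
    embedding: KmerEmbeddingModel = field(repr=False)
    transform: StrengthTransform
    kmer_scaler: tuple[np.ndarray, np.ndarray] = field(repr=False)  # (mean, sd) over dims
    pssm_scaler: tuple[np.ndarray, np.ndarray] = field(repr=False)  # (mean, sd) per cell
    history: pd.DataFrame = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def parameter_checksums(self) -> dict[str, str]:
        return {t.name: hashlib.sha256(np.ascontiguousarray(t.data).tobytes()).hexdigest()
                for t in self.net.params}


def fit_embedding_for(
    records: list[PromoterRecord], config: DeepModelConfig,
    extra_records: list[PromoterRecord] | None = None, epochs: int = 2,
) -> KmerEmbeddingModel:
    """Train the k-mer embedding on the union of the given corpora."""
    corpus = [extract_kmers(r.sequence, config.k) for r in records]
    for r in extra_records or []:
        corpus.append(extract_kmers(r.sequence, config.k))
    return train_kmer_embedding(corpus, dim=config.embedding_dim, epochs=epochs,
                                seed=config.seed)


def build_inputs(
    records: list[PromoterRecord],
    embedding: KmerEmbeddingModel,
    config: DeepModelConfig | None = None,
    require_strength: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Records -> (k-mer tensor (N, L-k+1, D), grid tensor (N, G, G, 1), raw y).

    For 50 bp records at k=3 and D=100 the k-mer tensor is (N, 48, 100)
    and the grid tensor is (N, 20, 20, 1).
    """
    cfg = config or DeepModelConfig()
    if not records:
        raise ValueError("no records")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed lengths {sorted(lengths)}")
    xk = np.stack([embed_sequence(embedding, extract_kmers(r.sequence, cfg.k))
                   for r in records])
    xp = np.stack([pssm_from_cgr(cgr_trajectory(r.sequence), cfg.grid_size)
                   for r in records])[..., None]
    y = None
    if require_strength:
        missing = [r.id for r in records if r.strength is None]
        if missing:
            raise ValueError(f"records without strength: {missing[:5]}")
        y = np.array([r.strength for r in records], dtype=np.float64)
    return xk, xp, y


def _standardize(x: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, sd = scaler
    return (x - mean) / sd


def _fit_scaler(x: np.ndarray, axes: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=axes, keepdims=True)
    sd = x.std(axis=axes, keepdims=True)
    sd[sd == 0] = 1.0
    return mean, sd


def _data_hash(records: list[PromoterRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(f"{r.id}\t{r.sequence}\t{r.strength}\n".encode())
    return h.hexdigest()


def train_deep(
    records: list[PromoterRecord],
    config: DeepModelConfig | None = None,
    embedding: KmerEmbeddingModel | None = None,
    auxiliary_corpus: list[PromoterRecord] | None = None,
    net: _DeepNet | None = None,
    frozen_indices: set[int] | None = None,
) -> TrainedDeepModel:
    """Fit the two-branch network; aux records are pooled into training only.

    The strength transform and the input scalers are fit on the training
    split (primary + auxiliary) only; validation rows never contribute.
    ``net``/``frozen_indices`` are used internally by incremental training.
    """
    cfg = config or DeepModelConfig()
    aux = list(auxiliary_corpus or [])
    if net is None and len(records) < 20:
        raise ValueError("need at least 20 training records")
    if embedding is None:
        embedding = fit_embedding_for(records, cfg, extra_records=aux)
    rng = np.random.default_rng(cfg.seed + 1)

    order = rng.permutation(len(records))
    n_val = max(1, int(round(cfg.validation_fraction * len(records))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    train_recs = [records[i] for i in tr_idx] + aux
    source = np.array(["primary"] * len(tr_idx) + ["auxiliary"] * len(aux))
    val_recs = [records[i] for i in val_idx]

    xk_tr, xp_tr, y_tr = build_inputs(train_recs, embedding, cfg)
    xk_va, xp_va, y_va = build_inputs(val_recs, embedding, cfg)
    transform = StrengthTransform.fit(y_tr)
    z_tr, z_va = transform.forward(y_tr)[:, None], transform.forward(y_va)[:, None]
    kmer_scaler = _fit_scaler(xk_tr, (0, 1))
    pssm_scaler = _fit_scaler(xp_tr, (0,))
    xk_tr, xp_tr = _standardize(xk_tr, kmer_scaler), _standardize(xp_tr, pssm_scaler)
    xk_va, xp_va = _standardize(xk_va, kmer_scaler), _standardize(xp_va, pssm_scaler)

    if net is None:
        net = _DeepNet(cfg, np.random.default_rng(cfg.seed))
    opt = nn.Adam(net.params, lr=cfg.lr)
    if frozen_indices:
        opt.freeze(frozen_indices)

    n, B = len(train_recs), cfg.batch_size
    best_val, since_best, lr = np.inf, 0, cfg.lr
    rows = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, B):
            sel = perm[s : s + B]
            pred = net.forward(xk_tr[sel], xp_tr[sel])
            loss = nn.mse_loss(pred, z_tr[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_mse = float(np.mean(losses))
        val_pred = _predict_batched(net, xk_va, xp_va)
        val_mse = float(np.mean((val_pred - z_va) ** 2))
        if not np.isfinite(train_mse):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        rows.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse, "lr": lr})
        if val_mse < best_val - 1e-5:
            best_val, since_best = val_mse, 0
        else:
            since_best += 1
            if since_best >= cfg.plateau_patience:
                lr = max(lr * cfg.plateau_factor, 1e-5)
                opt.lr = lr
                since_best = 0
    history = pd.DataFrame(rows)
    provenance = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg.__dict__, sort_keys=True).encode()).hexdigest(),
        "data_hash": _data_hash(records + aux),
        "seed": cfg.seed,
        "n_primary": len(tr_idx),
        "n_auxiliary": int((source == "auxiliary").sum()),
        "n_validation": len(val_recs),
        "validation_ids": [r.id for r in val_recs],
    }
    return TrainedDeepModel(net=net, config=cfg, embedding=embedding, transform=transform,
                            kmer_scaler=kmer_scaler, pssm_scaler=pssm_scaler,
                            history=history, provenance=provenance)


def _predict_batched(net: _DeepNet, xk: np.ndarray, xp: np.ndarray,
                     batch: int = 256) -> np.ndarray:
    preds = [net.forward(xk[s : s + batch], xp[s : s + batch]).data
             for s in range(0, len(xk), batch)]
    return np.concatenate(preds, axis=0)


def predict_deep(model: TrainedDeepModel, records: list[PromoterRecord]) -> pd.DataFrame:
    """Predictions on the transformed and raw scales, indexed by record id."""
    xk, xp, _ = build_inputs(records, model.embedding, model.config, require_strength=False)
    xk = _standardize(xk, model.kmer_scaler)
    xp = _standardize(xp, model.pssm_scaler)
    z = _predict_batched(model.net, xk, xp)[:, 0]
    return pd.DataFrame(
        {"pred_transformed": z, "pred_raw": model.transform.inverse(z)},
        index=pd.Index([r.id for r in records], name="id"),
    )


def incremental_train(
    model: TrainedDeepModel,
    new_records: list[PromoterRecord],
    lock_fraction: float,
    seed: int = 0,
    epochs: int = 10,
) -> TrainedDeepModel:
    """Continue training on new records with a random subset of tensors frozen.

    round(lock_fraction * T) of the T parameter tensors (chosen by the
    seeded RNG) stay bit-identical; the rest are updated.  The original
    model is left untouched.  lock_fraction 1.0 freezes everything.
    """
    if not 0.0 <= lock_fraction <= 1.0:
        raise ValueError("lock_fraction must be in [0, 1]")
    if not new_records:
        raise ValueError("no new records for incremental training")
    new_net = copy.deepcopy(model.net)
    T = len(new_net.params)
    n_lock = int(round(lock_fraction * T))
    rng = np.random.default_rng(seed)
    frozen = set(rng.choice(T, size=n_lock, replace=False).tolist())
    cfg = DeepModelConfig(**{**model.config.__dict__, "epochs": epochs, "seed": seed})
    updated = train_deep(
        new_records, cfg, embedding=model.embedding, net=new_net,
        frozen_indices=frozen,
    )
    updated.provenance["locked_tensors"] = sorted(
        new_net.param_names[i] for i in frozen)
    updated.provenance["lock_fraction"] = lock_fraction
    # keep the original target/input scaling so predictions stay comparable
    updated.transform = model.transform
    updated.kmer_scaler = model.kmer_scaler
    updated.pssm_scaler = model.pssm_scaler
    return updated


def similarity_subset(
    train_corpus: list[PromoterRecord],
    query_sequences: list[str],
    top_n: int,
    k: int = 3,
) -> tuple[list[PromoterRecord], pd.Series]:
    """Training records most similar to any query, by cosine of k-mer counts.

    For each query the ``top_n`` nearest training records are taken
    (ties broken by record order); the union is returned together with
    each record's maximum similarity over the queries.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not train_corpus or not query_sequences:
        raise ValueError("corpora must be nonempty")
    tmat = np.stack([kmer_count_features(r.sequence, (k,)).to_numpy()
                     for r in train_corpus])
    qmat = np.stack([kmer_count_features(s, (k,)).to_numpy() for s in query_sequences])
    sims = cosine_similarity(qmat, tmat)  # (n_query, n_train)
    top_n = min(top_n, len(train_corpus))
    chosen: set[int] = set()
    for row in sims:
        # stable ties: sort by (-similarity, record index)
        order = np.lexsort((np.arange(len(row)), -row))
        chosen.update(order[:top_n].tolist())
    idx = sorted(chosen)
    max_sim = sims.max(axis=0)
    subset = [train_corpus[i] for i in idx]
    return subset, pd.Series(max_sim[idx], index=[train_corpus[i].id for i in idx],
                             name="max_similarity")
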