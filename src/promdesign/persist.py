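"""Model persistence for the command-line workflow.

The deep model is stored as a directory: ``config.json`` (architecture,
strength transform, provenance), ``vocab.json`` (k-mer vocabulary) and
``arrays.npz`` (parameter tensors by name, embedding matrix, input
scalers).  The random-forest model is a joblib pickle next to its
manifest.  Loading rebuilds the network and overwrites its parameters,
so a round trip reproduces predictions exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .features_text import KmerEmbeddingModel
from .predictor_deep import (DeepModelConfig, StrengthTransform, TrainedDeepModel,
                             _DeepNet)
from .predictor_rf import TrainedRFModel

__all__ = ["save_deep_model", "load_deep_model", "save_rf_model", "load_rf_model"]


def save_deep_model(model: TrainedDeepModel, dirpath: str | Path) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.config.__dict__,
        "transform": model.transform.__dict__,
        "embedding": {"dim": model.embedding.dim, "k": model.embedding.k,
                      "seed": model.embedding.seed},
        "provenance": model.provenance,
    }
    (d / "config.json").write_text(json.dumps(meta, indent=2, default=str))
    (d / "vocab.json").write_text(json.dumps(model.embedding.vocab))
    arrays = {f"param:{t.name}": t.data for t in model.net.params}
    arrays["embedding_vectors"] = model.embedding.vectors
    arrays["kmer_mean"], arrays["kmer_sd"] = model.kmer_scaler
    arrays["pssm_mean"], arrays["pssm_sd"] = model.pssm_scaler
    np.savez(d / "arrays.npz", **arrays)
    model.history.to_csv(d / "history.tsv", sep="\t", index=False)


def load_deep_model(dirpath: str | Path) -> TrainedDeepModel:
    d = Path(dirpath)
    meta = json.loads((d / "config.json").read_text())
    cfg = DeepModelConfig(**meta["config"])
    vocab = json.loads((d / "vocab.json").read_text())
    with np.load(d / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    embedding = KmerEmbeddingModel(vocab=vocab, vectors=arrays["embedding_vectors"],
                                   **meta["embedding"])
    net = _DeepNet(cfg, np.random.default_rng(cfg.seed))
    for t in net.params:
        t.data = np.asarray(arrays[f"param:{t.name}"], dtype=np.float64)
    history = pd.read_csv(d / "history.tsv", sep="\t")
    return TrainedDeepModel(
        net=net, config=cfg, embedding=embedding,
        transform=StrengthTransform(**meta["transform"]),
        kmer_scaler=(arrays["kmer_mean"], arrays["kmer_sd"]),
        pssm_scaler=(arrays["pssm_mean"], arrays["pssm_sd"]),
        history=history, provenance=meta["provenance"],
    )


def save_rf_model(model: TrainedRFModel, dirpath: str | Path) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, d / "rf_model.joblib")


def load_rf_model(dirpath: str | Path) -> TrainedRFModel:
    return joblib.load(Path(dirpath) / "rf_model.joblib")
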