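"""Random-forest strength regressor over engineered features (model 2).

The feature matrix fuses string-based blocks (character counts, n-grams,
tf-idf, hashing, reductions, pooled embeddings) with non-string
descriptors (GC content, dinucleotide Moran's I, CKSNAP, EIIP-weighted
k-mer frequencies, and plain k-mer frequencies for k = 2..6).  The fit
pipeline is: z-score scaling, log-standardization of the target,
univariate top-fraction (default 20% by squared correlation, the
F-statistic ordering) or model-based feature selection, exhaustive grid
search over forest hyperparameters with k-fold cross-validation, and a
refit on all rows.  Scaling and selection live inside the
cross-validated pipeline, so fold statistics never leak from validation
rows.

Prediction aligns columns by name, never by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectFromModel, SelectPercentile, f_regression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features_numeric import (ZeroVarianceError, cksnap, dinucleotide_moran,
                               eiip_features, gc_content, kmer_count_features)
from .features_text import assemble_feature_matrix, fit_string_block
from .predictor_deep import StrengthTransform
from .sequence_io import PromoterRecord

__all__ = ["RFConfig", "TrainedRFModel", "build_rf_features", "train_rf", "predict_rf",
           "DEFAULT_GRID"]

DEFAULT_GRID: dict[str, list] = {
    "rf__n_estimators": [100, 300],
    "rf__max_depth": [8, 16, None],
    "rf__max_features": ["sqrt", 0.3],
}


@dataclass(frozen=True)
class RFConfig:
    grid: Mapping[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    folds: int = 5
    selection_mode: str = "univariate"  # or "model_based"
    selection_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.selection_mode not in ("univariate", "model_based"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")


def build_rf_features(
    records: Sequence[PromoterRecord],
    string_featurizers: Sequence[str] = (),
    string_params: Mapping[str, dict] | None = None,
    kmer_k_set: tuple[int, ...] = (2, 3, 4, 5, 6),
    cksnap_K_max: int = 5,
    eiip_k_values: tuple[int, ...] = (3,),
    seed: int = 0,
) -> pd.DataFrame:
    """Fuse the configured string blocks with the non-string descriptors.

    Returns a frame indexed by record id whose non-string columns are
    GC content, Moran's I, the CKSNAP blocks, the EIIP block and the
    per-k k-mer frequency blocks.  Featurizer failures propagate with
    the offending featurizer or record named.
    """
    if not records:
        raise ValueError("no records")
    ids = [r.id for r in records]
    seqs = [r.sequence for r in records]

    numeric_rows = []
    for rec in records:
        try:
            parts = [
                pd.Series({"gc_content": gc_content(rec.sequence)}),
                pd.Series({"moran_i": dinucleotide_moran(rec.sequence).I}),
                cksnap(rec.sequence, cksnap_K_max),
                eiip_features(rec.sequence, eiip_k_values),
                kmer_count_features(rec.sequence, kmer_k_set),
            ]
        except ZeroVarianceError as exc:
            raise ZeroVarianceError(f"record {rec.id!r}: {exc}") from exc
        numeric_rows.append(pd.concat(parts))
    numeric = pd.DataFrame(numeric_rows, index=pd.Index(ids, name="id"))

    blocks = []
    params = dict(string_params or {})
    for fid in string_featurizers:
        try:
            blocks.append(fit_string_block(fid, seqs, params.get(fid), seed=seed, ids=ids))
        except Exception as exc:
            raise type(exc)(f"featurizer {fid!r}: {exc}") from exc
    return assemble_feature_matrix(blocks, numeric)


@dataclass
class TrainedRFModel:
    pipeline: Pipeline = field(repr=False)
    feature_columns: list[str]
    selected_columns: list[str]
    transform: StrengthTransform
    best_params: dict
    cv_results: pd.DataFrame = field(repr=False)
    config: RFConfig


def _make_pipeline(config: RFConfig) -> Pipeline:
    if config.selection_mode == "univariate":
        selector = SelectPercentile(f_regression,
                                    percentile=100.0 * config.selection_fraction)
    else:
        selector = SelectFromModel(
            RandomForestRegressor(n_estimators=100, random_state=config.seed))
    return Pipeline([
        ("scale", StandardScaler()),
        ("select", selector),
        ("rf", RandomForestRegressor(random_state=config.seed)),
    ])


def train_rf(
    matrix: pd.DataFrame, strengths: pd.Series, config: RFConfig | None = None
) -> TrainedRFModel:
    """Cross-validated grid search + refit of the forest pipeline.

    ``strengths`` must align with the matrix rows by id.  Zero-variance
    columns are dropped (with a warning) before fitting; the best grid
    point minimizes mean cross-validated MSE on the log-standardized
    target; the full per-point score table is retained.
    """
    config = config or RFConfig()
    if len(matrix) < 2 * config.folds:
        raise ValueError(f"need at least {2 * config.folds} rows for {config.folds}-fold CV")
    strengths = strengths.loc[matrix.index]
    if matrix.isna().any().any():
        raise ValueError("feature matrix contains missing values")

    variances = matrix.var(axis=0, ddof=0)
    degenerate = list(matrix.columns[variances == 0.0])
    if degenerate:
        warnings.warn(f"dropping {len(degenerate)} zero-variance columns "
                      f"(e.g. {degenerate[:3]})", stacklevel=2)
        matrix = matrix.drop(columns=degenerate)
    dupes = matrix.T.duplicated()
    if dupes.any():
        dropped = list(matrix.columns[dupes.to_numpy()])
        warnings.warn(f"dropping {len(dropped)} duplicate columns (e.g. {dropped[:3]})",
                      stacklevel=2)
        matrix = matrix.loc[:, ~dupes.to_numpy()]

    transform = StrengthTransform.fit(strengths.to_numpy())
    z = transform.forward(strengths.to_numpy())
    cv = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        _make_pipeline(config), dict(config.grid),
        scoring="neg_mean_squared_error", cv=cv, refit=True, n_jobs=None,
    )
    search.fit(matrix.to_numpy(), z)
    support = search.best_estimator_.named_steps["select"].get_support()
    selected = list(np.asarray(matrix.columns)[support])
    return TrainedRFModel(
        pipeline=search.best_estimator_,
        feature_columns=list(matrix.columns),
        selected_columns=selected,
        transform=transform,
        best_params={k.removeprefix("rf__"): v for k, v in search.best_params_.items()},
        cv_results=pd.DataFrame(search.cv_results_),
        config=config,
    )


def predict_rf(model: TrainedRFModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Predict on the transformed and raw scales; columns matched by name."""
    missing = [c for c in model.feature_columns if c not in matrix.columns]
    if missing:
        raise KeyError(f"feature matrix lacks trained columns, e.g. {missing[:5]}")
    x = matrix[model.feature_columns].to_numpy()
    z = model.pipeline.predict(x)
    return pd.DataFrame(
        {"pred_transformed": z, "pred_raw": model.transform.inverse(z)},
        index=matrix.index,
    )
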