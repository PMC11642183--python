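"""Random-forest regressor: feature fusion, selection, alignment, reference fit."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from promdesign.features_numeric import ZeroVarianceError
from promdesign.predictor_rf import (
    RFConfig,
    _make_pipeline,
    build_rf_features,
    predict_rf,
    train_rf,
)
from promdesign.sequence_io import PromoterRecord
from promdesign.synthetic_data import PlantedMotif, SyntheticSpec, generate_corpus

SMALL_GRID = {"rf__n_estimators": [50], "rf__max_depth": [None],
              "rf__max_features": ["sqrt"]}


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(SyntheticSpec(n=60, seed=13))


@pytest.fixture(scope="module")
def matrix(corpus):
    return build_rf_features(corpus, kmer_k_set=(2, 3))


@pytest.fixture(scope="module")
def strengths(corpus):
    return pd.Series({r.id: r.strength for r in corpus})


@pytest.fixture(scope="module")
def fitted(matrix, strengths):
    cfg = RFConfig(grid=SMALL_GRID, folds=3, seed=1)
    with pytest.warns(UserWarning):  # sparse k-mer columns are degenerate at n=60
        return train_rf(matrix, strengths, cfg)


def test_feature_width_additivity(corpus):
    mat = build_rf_features(corpus[:10], kmer_k_set=(2, 3), cksnap_K_max=5,
                            eiip_k_values=(3,))
    expected = 1 + 1 + 16 * 5 + 4**3 + (4**2 + 4**3)
    assert mat.shape == (10, expected)


def test_string_blocks_add_columns(corpus):
    base = build_rf_features(corpus[:10], kmer_k_set=(2,))
    plus = build_rf_features(corpus[:10], string_featurizers=("count",),
                             kmer_k_set=(2,))
    assert plus.shape[1] == base.shape[1] + 4
    assert {"count:A", "count:T"} <= set(plus.columns)


def test_constant_sequence_surfaces_record_id():
    recs = [PromoterRecord("const01", "A" * 50, 1.0)]
    with pytest.raises(ZeroVarianceError, match="const01"):
        build_rf_features(recs, kmer_k_set=(2,))


def test_matrix_stable_across_runs(corpus):
    a = build_rf_features(corpus[:15], kmer_k_set=(2,))
    b = build_rf_features(corpus[:15], kmer_k_set=(2,))
    pd.testing.assert_frame_equal(a, b)


def test_single_point_grid_is_best(fitted):
    assert fitted.best_params == {"n_estimators": 50, "max_depth": None,
                                  "max_features": "sqrt"}
    assert len(fitted.cv_results) == 1


def test_selection_fraction_one_keeps_all(matrix, strengths):
    cfg = RFConfig(grid=SMALL_GRID, folds=3, selection_fraction=1.0, seed=1)
    with pytest.warns(UserWarning):
        model = train_rf(matrix, strengths, cfg)
    assert set(model.selected_columns) == set(model.feature_columns)


def test_empty_grid_rejected():
    with pytest.raises(ValueError):
        RFConfig(grid={})


def test_predictions_align_by_name_not_position(fitted, matrix):
    preds = predict_rf(fitted, matrix)
    shuffled = matrix[list(reversed(matrix.columns))]
    pd.testing.assert_frame_equal(predict_rf(fitted, shuffled), preds)


def test_missing_column_named(fitted, matrix):
    incomplete = matrix.drop(columns=[fitted.feature_columns[0]])
    with pytest.raises(KeyError, match=fitted.feature_columns[0].split(":")[0][:5]):
        predict_rf(fitted, incomplete)


def test_prediction_deterministic(fitted, matrix):
    a = predict_rf(fitted, matrix)
    b = predict_rf(fitted, matrix)
    pd.testing.assert_frame_equal(a, b)
    assert np.isfinite(a.to_numpy()).all()


def test_planted_signal_selected():
    """With strength driven only by a planted motif, most selected columns
    name the motif's k-mer content."""
    spec = SyntheticSpec(
        n=300, seed=21, gc_coeff=0.0, noise_sd=0.1,
        motifs=(PlantedMotif("TATAAT", (10, 40), 1.0, 0.5),),
    )
    recs = generate_corpus(spec)
    matrix = build_rf_features(recs, kmer_k_set=(3,))
    strengths = pd.Series({r.id: r.strength for r in recs})
    cfg = RFConfig(grid=SMALL_GRID, folds=3, selection_fraction=0.05, seed=2)
    model = train_rf(matrix, strengths, cfg)
    motif_parts = {"TAT", "ATA", "TAA", "AAT", "TA", "AT", "AA"}
    related = [c for c in model.selected_columns
               if any(p in c.split("_")[-1] for p in motif_parts)]
    assert len(related) / len(model.selected_columns) >= 0.6


def test_matches_reference_pipeline_fit(matrix, strengths, fitted):
    """The cross-validated search must equal an independently assembled
    scikit-learn pipeline run with the same folds and seed."""
    cfg = RFConfig(grid=SMALL_GRID, folds=3, seed=1)
    variances = matrix.var(axis=0, ddof=0)
    kept = matrix.loc[:, variances > 0]
    kept = kept.loc[:, ~kept.T.duplicated().to_numpy()]
    z = fitted.transform.forward(strengths.loc[kept.index].to_numpy())
    ref = GridSearchCV(_make_pipeline(cfg), SMALL_GRID,
                       scoring="neg_mean_squared_error",
                       cv=KFold(3, shuffle=True, random_state=1))
    ref.fit(kept.to_numpy(), z)
    np.testing.assert_allclose(
        ref.best_estimator_.predict(kept[fitted.feature_columns].to_numpy()),
        predict_rf(fitted, matrix)["pred_transformed"].to_numpy(),
    )


def test_heldout_signal_positive():
    """Train/test split on synthetic data: rank correlation above zero."""
    from scipy import stats
    spec = SyntheticSpec(n=240, seed=31, noise_sd=0.3)
    recs = generate_corpus(spec)
    train, test = recs[:180], recs[180:]
    mtr = build_rf_features(train, kmer_k_set=(2, 3))
    mte = build_rf_features(test, kmer_k_set=(2, 3))
    cfg = RFConfig(grid=SMALL_GRID, folds=3, seed=3)
    with pytest.warns(UserWarning):
        model = train_rf(mtr, pd.Series({r.id: r.strength for r in train}), cfg)
    preds = predict_rf(model, mte)
    rho, p = stats.spearmanr(preds["pred_raw"],
                             [r.strength for r in test])
    assert rho > 0 and p < 0.01
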