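"""Train the two-branch deep strength regressor on a small benchmark.

Each 50 bp sequence enters as (a) a (48, D) matrix of skip-gram 3-mer
embeddings and (b) its (20, 20, 1) chaos-game occupancy grid; a 1-D
convolution + BiLSTM and a 2-D convolution meet in a dense head that
regresses log-standardized strength.  (Scaled down here for speed —
the package default uses D=100 and n=2000.)
"""

import numpy as np
from scipy import stats

from promdesign.predictor_deep import (
    DeepModelConfig,
    fit_embedding_for,
    predict_deep,
    train_deep,
)
from promdesign.synthetic_data import SyntheticSpec, generate_benchmark

train, test, truth = generate_benchmark(SyntheticSpec(n=400, seed=2))
cfg = DeepModelConfig(embedding_dim=24, conv1d_filters=16, bilstm_hidden=8,
                      conv2d_filters=8, dense_width=64, epochs=15, seed=2)
embedding = fit_embedding_for(train, cfg)
model = train_deep(train, cfg, embedding=embedding)
print(model.history.tail(3).to_string(index=False))

preds = predict_deep(model, test)
y = np.array([truth[i] for i in preds.index])
rho, p = stats.spearmanr(preds["pred_raw"], y)
print(f"\nheld-out Spearman: {rho:.4f} (p = {p:.2g}, n = {len(y)})")
print("top-3 predicted promoters (raw scale):")
print(preds.nlargest(3, "pred_raw").to_string())
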