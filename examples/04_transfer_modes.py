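"""The three transfer modes against their baselines on one small task.

Generates two related synthetic families (overlap 0.8), pre-trains the FNN-2
source model, adapts it to 12 target compounds with each Stage-II mode, and
prints test MCC on 500 held-out target compounds. Runs in seconds by using a
reduced input dimension.
"""

import numpy as np

from dtitransfer import FNNConfig, compute_metrics, make_benchmark_data
from dtitransfer.split import balanced_indices
from dtitransfer.transfer import (
    mode1_full_finetune,
    mode2_feature_transformer,
    mode3_shallow,
    pretrain_source,
    train_scratch_base,
    train_scratch_reference,
    zero_shot,
)

DIM = 50
cfg = FNNConfig(input_dim=DIM, hidden_sizes=(120, 40), epochs=60,
                batch_size=64, learning_rate=1e-3, seed=0)
source, target_train, target_test = make_benchmark_data(
    seed=5, overlap=0.8, n_source=2000, n_target_train=500, n_target_test=500,
    dimension=DIM)

source_params = pretrain_source((source.X, source.y), cfg)

idx = balanced_indices(target_train.y, 12, np.random.default_rng(3))
subset = (target_train.X[idx], target_train.y[idx])

models = {
    "mode 1 (full fine-tune) ": mode1_full_finetune(source_params, subset, cfg),
    "mode 2 (feature transf.)": mode2_feature_transformer(source_params, subset, cfg),
    "mode 3 (frozen + SVM)   ": mode3_shallow(source_params, subset),
    "zero-shot source model  ": zero_shot(source_params),
    "scratch FNN reference   ": train_scratch_reference(subset, cfg),
    "scratch SVM base model  ": train_scratch_base(subset),
}

print("test MCC after training on 12 balanced target compounds:")
for name, model in models.items():
    labels, scores = model.predict(target_test.X)
    m = compute_metrics(target_test.y, labels, scores)
    print(f"  {name} MCC {m.mcc:+.3f}  AUROC {m.auroc:.3f}")
# With related families, the pre-trained weights (modes 1-2, zero-shot) lift
# performance far above the scratch FNN, which sees only the 12 compounds.
# A single draw is noisy - especially for the SVM-head modes at this size;
# the benchmark grid (next example) averages paired repeats instead.
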