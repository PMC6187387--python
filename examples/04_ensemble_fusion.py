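"""Combine two stacked auto-encoders by sum-rule and product-rule fusion.

Trains the two-member ensemble (hidden sizes 46 and 15) and compares each
member's accuracy with the fused decisions under both rules.
"""

import numpy as np

from gaitstack import (
    TrainConfig,
    default_gait_specs,
    evaluate,
    featurize_dataset,
    fuse_product,
    fuse_sum,
    generate_dataset,
    scale_features,
    split_5050,
)
from gaitstack.ensemble import classify, train_ensemble
from gaitstack.stacked import predict_proba
from gaitstack.wavelet import compress_recording, get_filters

recordings = generate_dataset(default_gait_specs(), n_frames_per_gait=4800, seed=2)
features = featurize_dataset(
    [compress_recording(r, get_filters("db2"), 2) for r in recordings], 20
)
train, test = split_5050(features, seed=2)
train_s, test_s, _ = scale_features(train, test)

config = TrainConfig(max_epochs=500, learning_rate=0.5, seed=2)
ensemble = train_ensemble(
    train_s.values, train_s.labels, ((46,), (15,)), config, fusion="sum"
)

member_probas = [predict_proba(m, test_s.values) for m in ensemble.members]
names = ensemble.class_names
for m, rep_sizes in zip(ensemble.members, ensemble.member_hidden_sizes):
    rep = evaluate(test_s.labels, classify(m, test_s.values), names)
    print(f"member hidden={rep_sizes}: accuracy {rep.accuracy_overall:.3f}")

for rule, fused in (("sum", fuse_sum(member_probas)),
                    ("product", fuse_product(member_probas))):
    pred = np.array([names[i] for i in fused.argmax(axis=1)], dtype=object)
    rep = evaluate(test_s.labels, pred, names)
    print(f"ensemble ({rule}): accuracy {rep.accuracy_overall:.3f}")

print("\nThe sum rule averages the members' class probabilities; the product")
print("rule multiplies and renormalizes them. Both keep or improve on the")
print("weaker member by letting confident members outvote uncertain ones.")
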