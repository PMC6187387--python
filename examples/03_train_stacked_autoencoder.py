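"""Train one stacked auto-encoder classifier on synthetic gait features.

Greedy layerwise pretraining (each auto-encoder reconstructs the previous
layer's codes) followed by supervised softmax fine-tuning, at reduced scale
so the script runs in seconds.
"""

from gaitstack import (
    TrainConfig,
    default_gait_specs,
    evaluate,
    featurize_dataset,
    generate_dataset,
    scale_features,
    split_5050,
)
from gaitstack.ensemble import classify
from gaitstack.stacked import build_sae
from gaitstack.wavelet import compress_recording, get_filters

recordings = generate_dataset(default_gait_specs(), n_frames_per_gait=4800, seed=1)
filters = get_filters("db2")
features = featurize_dataset(
    [compress_recording(r, filters, 2) for r in recordings], window_size=20
)
train, test = split_5050(features, seed=1)
train_s, test_s, _ = scale_features(train, test)

config = TrainConfig(max_epochs=500, learning_rate=0.5, seed=1)
model = build_sae(train_s.values, train_s.labels, hidden_sizes=(10, 15), config=config)

report = evaluate(test_s.labels, classify(model, test_s.values),
                  model.head.class_names)
print(f"hidden sizes: {model.hidden_sizes}")
print(f"test accuracy: {report.accuracy_overall:.3f} on {report.n_test} windows")
print("confusion matrix (rows = truth):")
for name, row in zip(report.class_names, report.confusion):
    print(f"  {name:<14}{row}")

print("\nAccuracy is the trace of the confusion matrix over the test size;")
print("off-diagonal entries are windows assigned to the wrong gait.")
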