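"""Wavelet-packet compression and windowed statistical features.

Compresses a 49,000-frame channel to its level-2 approximation (12,250
coefficients — a 4x reduction that keeps the low-frequency stride content),
then builds the 40-column feature table from four 12,000-frame recordings.
"""

from gaitstack import default_gait_specs, featurize_dataset, generate_dataset, \
    generate_recording
from gaitstack.wavelet import compress_recording, decompose, get_filters, select_node

filters = get_filters("db2")

rec = generate_recording(default_gait_specs()["walk"], 49_000, seed=0)
tree = decompose(rec.values[:, 0], filters, levels=2)
a2 = select_node(tree, 2, 0)
print(f"one channel: {rec.n_frames} frames -> {len(a2)} level-2 coefficients")

recordings = generate_dataset(default_gait_specs(), n_frames_per_gait=12_000, seed=0)
compressed = [compress_recording(r, filters, level=2) for r in recordings]
features = featurize_dataset(compressed, window_size=20)
rows, cols = features.values.shape
print(f"feature table: {rows} windows x {cols} features "
      f"({rows // 4} windows per gait)")
print("columns:", ", ".join(features.column_names[:5]), "...")

print("\nEach window of 20 compressed samples contributes 5 statistics")
print("(mean, max, min, variance, std) per channel: 8 channels x 5 = 40.")
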