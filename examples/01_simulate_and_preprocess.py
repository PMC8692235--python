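"""Simulate raw fiber-optic AF spectra and run the calibration chain.

Generates two tissue classes on the 3648-channel instrument grid, then
applies background subtraction, 10-nm smoothing, the 435-900 nm window,
and peak normalization.  The printed peak positions show where each
class's dominant fluorophore emits.
"""

import numpy as np

from myospec import default_config, preprocess_dataset, simulate_dataset

dataset = simulate_dataset(default_config(n_per_class=5, seed=0), "AF")
print(f"raw dataset: {dataset.matrix.shape[0]} measurements x "
      f"{dataset.matrix.shape[1]} wavelengths "
      f"({dataset.grid.values[0]:.0f}-{dataset.grid.values[-1]:.0f} nm)")

processed = preprocess_dataset(dataset)
lo, hi = processed.grid.span()
print(f"preprocessed: {processed.matrix.shape[1]} channels kept in [{lo:.1f}, {hi:.1f}] nm")
print(f"every normalized spectrum peaks at 1: max = {processed.matrix.max(axis=1).min():.6f}")

for group in ("Quad", "Heart"):
    rows = processed.matrix[processed.classes() == group]
    peak_nm = processed.grid.values[np.argmax(rows.mean(axis=0))]
    print(f"{group:>6}: mean spectrum peaks at {peak_nm:.0f} nm")
# Quadriceps peaks near the 475 nm collagen band; heart, richer in flavin
# and porphyrin, peaks further to the red.
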