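"""Estimate band-averaged coherence features and verify a planted effect.

Simulates two groups whose theta coherence between ROI 0 and ROI 1 differs
(0.2 vs 0.6 magnitude-squared coherence), runs the Welch MSC estimator over
all ROI pairs and bands, and compares the group means for the planted pair.
"""

import numpy as np

from remitpredict import coherence_features
from remitpredict.synthetic_cohort import CoherenceEffect, simulate_roi_signals

labels = {f"S{i:03d}": ("remitted" if i % 2 else "continued") for i in range(40)}
signals = simulate_roi_signals(
    labels,
    [CoherenceEffect(0, 1, "theta", 0.2, 0.6)],
    n_rois=6, fs=256.0, duration=120.0, seed=3,
)

block = coherence_features(signals)
print(f"{block.features.shape[1]} features per subject "
      f"({len(block.band_names)} bands x C({signals.n_rois},2) ROI pairs)")

name = f"{signals.roi_names[0]}-{signals.roi_names[1]}@theta"
vals = block.features[name]
rem = np.mean([vals[s] for s, l in labels.items() if l == "remitted"])
con = np.mean([vals[s] for s, l in labels.items() if l == "continued"])
print(f"planted pair {name}:")
print(f"  remitted mean {rem:.3f} (target 0.6), continued mean {con:.3f} (target 0.2)")

null_name = f"{signals.roi_names[2]}-{signals.roi_names[3]}@theta"
print(f"unplanted pair {null_name}: mean {block.features[null_name].mean():.3f} "
      "(estimator bias floor only — no real coupling)")
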