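"""Extract features from a simulated dataset and score separability.

Each (possibly augmented) column contributes three features — absolute
standard deviation, RMS, and mean power frequency — min-max normalized
to [0, 1] over the dataset.  SFV = D/c summarizes how separable the
gesture classes are: D is the mean Euclidean distance between class-mean
feature vectors, c the grand mean of within-class standard deviations.
"""

import numpy as np

from emgvdi import (
    LabeledFeatureSet,
    SimConfig,
    apply_normalizer,
    augment,
    default_activation_profile,
    extract,
    fit_normalizer,
    sfv_score,
    simulate_dataset,
)

profile = default_activation_profile()
cfg = SimConfig(seed=7, n_windows_per_gesture=40)
dataset = simulate_dataset(profile, cfg)
print(f"simulated {len(dataset)} windows "
      f"({cfg.n_windows_per_gesture} per gesture)")

for label, do_augment in (("plain", False), ("augmented", True)):
    vectors = []
    labels = []
    for window, gesture in dataset:
        source = augment(window, "all") if do_augment else window
        vectors.append(extract(source).values)
        labels.append(gesture.id)
    matrix = np.vstack(vectors)
    params = fit_normalizer(matrix)
    fs = LabeledFeatureSet(apply_normalizer(matrix, params),
                           np.array(labels))
    comp = sfv_score(fs)
    print(f"\n{label}: {matrix.shape[1]} features")
    print(f"  D   = {comp.D:.4f}   (between-class dispersion)")
    print(f"  c   = {comp.c:.4f}   (within-class dispersion)")
    print(f"  SFV = {comp.sfv:.3f}")
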