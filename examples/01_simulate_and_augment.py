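"""Simulate one gesture window and add virtual channels.

A window is a 200 x n matrix of raw samples at 1 kHz (rows = time,
columns = muscles).  Augmentation appends, for every unordered channel
pair (i, j), the virtual channel |s_i^2 - s_j^2|, raising an n-channel
montage to n + n(n-1)/2 columns at the data level — before any feature
is computed.
"""

import numpy as np

from emgvdi import (
    GESTURES,
    SimConfig,
    augment,
    default_activation_profile,
    simulate_window,
)

profile = default_activation_profile()
cfg = SimConfig(fs=1000.0, window_len=200)

fist = GESTURES[3]
window = simulate_window(fist, profile, cfg, seed=42)
print(f"gesture: {fist.name} (id {fist.id})")
print(f"raw window: {window.data.shape[0]} samples x "
      f"{window.n_channels} channels")
print("channels:", ", ".join(window.channel_names))

aug = augment(window, "all")
print(f"\naugmented: {aug.n_channels} columns "
      f"({aug.n_physical} physical + {len(aug.virtual_pairs)} virtual)")
print("virtual columns:", ", ".join(aug.column_names[aug.n_physical:]))

# The physical columns pass through untouched; virtual columns are
# nonnegative by construction.
assert np.array_equal(aug.data[:, : aug.n_physical], window.data)
assert (aug.data[:, aug.n_physical :] >= 0).all()
print("\nper-column RMS of the augmented window:")
for name, col in zip(aug.column_names, aug.data.T):
    print(f"  {name:35s} {np.sqrt(np.mean(col ** 2)):.4f}")
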