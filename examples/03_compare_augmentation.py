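"""Paired comparison: does virtual-channel augmentation help?

For each seed, one dataset is simulated and both arms — plain features
and features of the augmented matrix — are split, normalized, scored
with SFV, and classified with the MLP, so differences are paired.  This
example runs a reduced version (5 seeds, 60 windows/gesture) to stay
fast; scripts/acceptance.py runs the full 20-seed, 150-window study.
"""

from emgvdi import ExperimentConfig, channels_for, compare_vdi

for n_channels in (2, 3, 4):
    cfg = ExperimentConfig(
        channels=channels_for(n_channels),
        n_per_gesture=60,
        n_seeds=5,
        seed=1,
    )
    report = compare_vdi(cfg)
    print(f"\n{n_channels} physical channels "
          f"({report.records[0]['n_features_plain']} plain features -> "
          f"{report.records[0]['n_features_vdi']} augmented)")
    print(f"  accuracy: {report.mean('plain'):.3f} -> "
          f"{report.mean('vdi'):.3f} "
          f"(mean gain {report.deltas('accuracy').mean():+.3f})")
    print(f"  SFV:      {report.mean('plain', 'sfv'):.2f} -> "
          f"{report.mean('vdi', 'sfv'):.2f} "
          f"(mean gain {report.deltas('sfv').mean():+.2f})")
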