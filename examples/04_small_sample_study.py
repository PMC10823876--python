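"""Small-sample behaviour of accuracy and SFV.

For each per-gesture subsample size and montage, a random subsample of
the simulated dataset is split 2:1, classified, and scored with SFV.
The point of interest is stability: how much each metric moves across
seeds when training data are scarce, and whether the SFV ordering by
channel count survives subsampling.  Reduced scale here (5 seeds);
scripts/acceptance.py runs 20.
"""

from emgvdi import ExperimentConfig, subsample_study

cfg = ExperimentConfig(n_per_gesture=150, n_seeds=5, seed=1)
table = subsample_study(cfg, [60, 90, 120, 150])

print("mean over seeds (accuracy / SFV):\n")
print(f"{'size':>6} | " + " | ".join(f"{n} channels" for n in (2, 3, 4)))
for size in (60, 90, 120, 150):
    cells = []
    for nch in (2, 3, 4):
        rows = table[(table["size"] == size) & (table["n_channels"] == nch)]
        cells.append(f"{rows['accuracy'].mean():.3f} / "
                     f"{rows['sfv'].mean():.2f}")
    print(f"{size:>6} | " + " | ".join(cells))

smallest = table[table["size"] == 60]
for col in ("accuracy", "sfv"):
    cv = smallest.groupby("n_channels")[col].agg(
        lambda x: x.std(ddof=1) / x.mean()
    )
    print(f"\nacross-seed CV of {col} at size 60, by montage:")
    print(cv.to_string())
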