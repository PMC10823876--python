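# emgvdi — virtual-channel augmentation for sEMG gesture recognition

`emgvdi` implements a data-level fusion method for multichannel surface
electromyography (sEMG) gesture recognition.  Given an n-channel window
of raw EMG — a matrix `S` with 200 time samples (200 ms at 1 kHz) per
column — the method appends, for every unordered pair of physical
channels (i, j), a *virtual channel*

```
v_ij[t] = | s_i[t]² − s_j[t]² |
```

raising the montage from n to n + n(n−1)/2 columns before any feature
is computed.  The virtual channel carries cross-channel structure
(inter-muscle co-activation) that per-channel features cannot see, so a
sparse electrode montage behaves more like a denser one — a *virtual
dimension increase* of the measurement.

The package also implements the **SFV** statistic ("separability of
feature vectors") used to quantify how much a feature set separates the
gesture classes:

```
SFV = D / c
```

where `D` is the mean Euclidean distance between class-mean feature
vectors (between-class dispersion) and `c` is the grand mean of the
within-class per-feature standard deviations.  Higher SFV means more
separable classes, independent of any particular classifier.

Because the original human recordings are not distributed, the package
ships a seeded synthetic sEMG generator: band-limited (20–450 Hz)
Gaussian carriers scaled by a gesture × muscle activation matrix for
four forearm muscles, with per-gesture common-drive correlation between
channels, multiplicative trial-to-trial jitter, and additive baseline
noise.  Five gestures are modeled: thumbs up, "V" sign, "OK" sign,
fist, open hand.

## What is in the box

| module | contents |
| --- | --- |
| `emgvdi.simulate` | activation profiles, seeded window/dataset generator |
| `emgvdi.windows` | `SampleMatrix`, delimited-text I/O, segmentation |
| `emgvdi.vdi` | virtual channels and `augment` |
| `emgvdi.features` | abs-std, RMS, mean power frequency; min-max normalization |
| `emgvdi.sfv` | `sfv_score` and its components D, c |
| `emgvdi.classify` | stratified 2:1 split, MLP classifier, evaluation |
| `emgvdi.pipeline` | paired with/without-augmentation study, subsample study |
| `emgvdi.cli` | thin `emgvdi` command wrapping the above |

## Worked example

```python
from emgvdi import (GESTURES, SimConfig, augment,
                    default_activation_profile, simulate_window)

profile = default_activation_profile()
window = simulate_window(GESTURES[3], profile, SimConfig(), seed=42)
aug = augment(window, "all")     # 4 physical -> 10 columns
```

Running the paired experiment (`examples/03_compare_augmentation.py`,
5 seeds, 60 windows/gesture) prints:

```
2 physical channels (6 plain features -> 9 augmented)
  accuracy: 0.768 -> 0.852 (mean gain +0.084)
  SFV:      5.60 -> 6.14 (mean gain +0.54)
3 physical channels (9 plain features -> 18 augmented)
  accuracy: 0.822 -> 0.864 (mean gain +0.042)
  SFV:      6.51 -> 7.26 (mean gain +0.76)
4 physical channels (12 plain features -> 30 augmented)
  accuracy: 0.854 -> 0.886 (mean gain +0.032)
  SFV:      7.09 -> 8.32 (mean gain +1.23)
```

The gain from augmentation is largest for the sparsest montage — the
central claim of the method.  The `examples/` directory walks through
simulation and augmentation (`01`), feature extraction and SFV (`02`),
the paired comparison (`03`), and the small-sample study (`04`).

## Command line

```sh
emgvdi simulate --channels 4 --per-gesture 150 --seed 1 --out data/
emgvdi augment  --in data/window_g1_0000.csv --pairs all --out aug.csv
emgvdi features --in data/ --augment all --out features.csv
emgvdi sfv      --features features.csv --out sfv.json
emgvdi train-eval --features features.csv --split 2:1 --seed 3 --report report.json
emgvdi compare  --channels 2 --n-seeds 20 --seed 1 --out results/cmp
emgvdi subsample --sizes 60,90,120,150 --n-seeds 20 --seed 1 --out results/sub
```

`compare` and `subsample` accept a YAML `--config` file; flags override
file values.  Both write a `provenance.json` recording the full
configuration and seeds.

## Documentation

- `docs/methods.md` — signal model, estimator choices, experiment
  design, and limitations.
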