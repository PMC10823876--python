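# Methods

This note records the signal model, estimator definitions, experiment
design, and the reasoning behind the main numerical choices.

## 1. Virtual dimension increase (VDI)

A raw window is a sample matrix `S ∈ R^{m×n}` (m = 200 time samples at
fs = 1 kHz, n physical channels).  For every unordered channel pair
(i, j), augmentation appends the virtual channel

```
v_ij[t] = | s_i[t]² − s_j[t]² |        t = 1..m
```

yielding `S_new ∈ R^{m×(n + n(n−1)/2)}`.  Properties relied on by the
tests: symmetry in (i, j), nonnegativity, zero for identical channels,
sign-invariance of the inputs, and bit-identical pass-through of the
physical columns.  Virtual columns are ordered lexicographically by
(i, j) with i < j and named `v_<i+1>_<j+1>` (1-based display).

The squaring makes the virtual channel sensitive to instantaneous
*power* differences between muscles; its temporal statistics therefore
encode cross-channel co-activation structure that per-channel features
marginalize away.

## 2. Features and normalization

Each (physical or virtual) column contributes three features, in fixed
order:

1. **abs-std** — population standard deviation of the rectified signal
   `|s[t]|`.  "Absolute standard deviation" has no universal formula;
   mean absolute value (MAV) is available via
   `extract(..., amplitude_stat="mav")`.  Both are standard sEMG
   amplitude features; the choice is isolated behind one switch.
2. **RMS** — root mean square.
3. **MPF** — mean power frequency: the power-weighted mean frequency of
   a single-taper periodogram (constant detrend, no zero padding, bin
   width fs/m, DC bin excluded).  This is the simplest defensible
   estimator; fancier spectral estimators change the variance, not the
   directional results.

Feature vectors are min–max normalized per feature (fit on the training
split only, applied to both splits, clipped to [0, 1]; degenerate
features map to 0).  Normalization matters because SFV mixes Euclidean
distances across features of different units.

## 3. SFV — separability of feature vectors

For a labeled set with K classes and I features:

- class means `x̄_i^k` and population standard deviations `s_i^k` per
  class k and feature i;
- between-class dispersion
  `D = (2 / K(K−1)) Σ_{p<q} ‖x̄^p − x̄^q‖₂` — the average Euclidean
  distance between class-mean vectors over all unordered class pairs;
- within-class dispersion `c = (1 / IK) Σ_i Σ_k s_i^k` — the grand mean
  of all class-feature standard deviations;
- `SFV = D / c`.

Edge cases: `c = 0` with `D > 0` is reported as +inf with a flag;
`D = c = 0` raises (SFV undefined).  SFV is invariant to common scaling
and translation of the features, and to permutations of labels or
feature order — each invariance is tested to 1e-12.  An independent
brute-force double-loop implementation in the test suite serves as the
oracle.

## 4. Synthetic sEMG generator

Real recordings are not distributed, so experiments run on a seeded
generator with the statistical structure the method assumes.  Per
channel c and gesture g:

```
x_c[t] = a(g, c) · j_c · e_c[t]  +  b_c[t]
```

- `e_c` — unit-variance carrier: white Gaussian noise band-limited to
  20–450 Hz by a zero-phase 4th-order Butterworth filter
  (`sosfiltfilt`), then standardized to unit sample std.  Surface EMG
  is well approximated by band-limited Gaussian noise whose variance
  tracks muscle activation.
- `a(g, c)` — gesture × muscle activation matrix (4 forearm muscles:
  extensor carpi ulnaris, extensor pollicis longus, flexor digitorum
  superficialis, extensor digiti minimi).  The default matrix encodes
  muscle involvement per gesture: e.g. the thumb extensor is strongly
  active for thumbs-up, fist and open hand; the little-finger extensor
  for OK, fist and open hand.
- `j_c` — multiplicative log-normal trial jitter (σ = 0.25),
  representing electrode/effort variability between repetitions.
- `b_c` — additive white baseline noise (sd = 0.2).

**Common drive.**  Before filtering, each channel's carrier noise is
mixed with a shared per-gesture source:
`noise_c = √(1−ρ_g²)·own_c + ρ_g·common_g`.  This leaves every
channel's marginal distribution unchanged but correlates channels
pairwise by ρ_g², modeling the central co-contraction drive that
synchronizes synergist muscles.  This is the mechanism that gives
virtual channels information content: with fully independent carriers,
every virtual-channel feature is (statistically) a function of the
per-channel features, and data-level fusion cannot help.  With common
drive, the cross-channel correlation is visible only to pairwise
quantities such as `|s_i² − s_j²|`.  Default ρ per gesture ranges from
0.20 to 0.85 (highest for fist, where many muscles co-contract).

**Determinism.**  Every channel draws from its own stream seeded by
(window seed, CRC-32 of the channel name), so a montage subset is
bit-identical to the corresponding columns of the full simulation —
tested, and exploited by the pipeline to simulate once per seed and
slice montages.  Per-window seeds derive from
`SeedSequence([master, gesture_id, index])`; all derived seeds are
< 2³¹.

**What the generator does not emulate:** motor-unit action-potential
shapes and firing statistics, fatigue and electrode-shift
nonstationarity, movement artifacts, inter-subject variability, and
heavy-tailed amplitude distributions.  Consequently absolute SFV
magnitudes are higher than on real recordings (Gaussian clouds have no
outliers); only directional comparisons are claimed.

## 5. Classifier and experiment design

- **Split:** stratified per class, round(J_k · 2/3) training samples,
  seeded permutation (2:1 train/test).
- **Classifier:** single-hidden-layer MLP, width 2I+1 for I input
  features, logistic activation, trained with L-BFGS to a loss plateau
  (max 200 epochs).  L-BFGS rather than SGD with early stopping:
  deterministic given the seed, and ~50× faster at these problem
  sizes; both are config-exposed.  Ties in the output layer break to
  the lowest class id.
- **Paired comparison (`compare_vdi`):** per seed, one dataset is
  simulated and both arms share it; plain features are the leading 3n
  columns of the augmented feature table (valid because physical
  columns pass through augmentation bit-identically and features are
  per-column — equivalence to an independent run is asserted in tests).
  Each arm fits its own normalizer on its own training split.
- **Subsample study:** for per-gesture sizes 60–150, a seeded random
  subsample is drawn per gesture, then split, normalized, scored and
  classified per montage (2, 3, 4 channels).

Defaults: 150 windows per gesture, 20 seeds, montages
{EPL+EDM, EPL+FDS+EDM, all four}.

## 6. Generator calibration (design decision)

The default activation matrix, jitter, baseline noise and common-drive
levels were chosen — and frozen — at design time so that the study
operates in the regime where the method is interesting: plain-feature
accuracy well below ceiling (~0.78–0.86 across montages), class pairs
that per-channel amplitudes confuse, and genuine cross-channel synergy
for augmentation to exploit.  These parameters are ordinary config
(`ActivationProfile`), so users can run any regime they like.

## 7. Limitations

- Synthetic data: directional results (augmentation helps; SFV grows
  with channel count; gains largest for sparse montages) are claims
  about this generator, not about any human cohort.
- The across-seed dispersion comparison between accuracy and SFV at the
  smallest subsample size is marginal under this generator: both
  statistics are computed from the same normalized features, so SFV
  inherits comparable sampling noise at 60 samples/gesture.  The
  acceptance script reports both coefficients of variation so the
  actual margin is visible.
- SFV uses population (ddof = 0) standard deviations by default; a
  `ddof` switch is provided.
- The MLP is a deliberately simple reference classifier; the package
  makes no claim of classifier optimality.
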