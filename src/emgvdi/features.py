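"""Per-channel EMG features and min-max normalization.

Three features per column, the classic small sEMG feature set:

* absolute standard deviation — population standard deviation of the
  rectified signal |s_t| (time-domain amplitude spread),
* RMS — root mean square (time-domain amplitude),
* MPF — mean power frequency, the power-weighted mean of the periodogram
  over positive-frequency bins (frequency-domain).

Feature vectors are laid out per column as (abs_std, rms, mpf), so a
window with ``n_cols`` columns yields ``3 * n_cols`` values.  Before
classification the features are linearly rescaled to [0, 1] with min-max
normalization fitted on training data only; test values outside the
training range are clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .vdi import AugmentedMatrix
from .windows import SampleMatrix

__all__ = [
    "FeatureVector",
    "NormalizationParams",
    "LabeledFeatureSet",
    "abs_std",
    "mean_absolute_value",
    "rms",
    "mean_power_frequency",
    "extract",
    "fit_normalizer",
    "apply_normalizer",
]

#: Feature layout per source column, in order.
FEATURE_ORDER = ("absstd", "rms", "mpf")


def abs_std(column: np.ndarray) -> float:
    """Population standard deviation of the rectified signal |s_t|."""
    column = np.asarray(column, dtype=float)
    if column.size < 2:
        raise ValueError("abs_std needs at least 2 samples")
    return float(np.std(np.abs(column)))


def mean_absolute_value(column: np.ndarray) -> float:
    """Mean absolute value, the config alternative amplitude feature."""
    column = np.asarray(column, dtype=float)
    if column.size < 1:
        raise ValueError("mean_absolute_value needs at least 1 sample")
    return float(np.mean(np.abs(column)))


def rms(column: np.ndarray) -> float:
    """Root mean square sqrt(mean(s_t^2))."""
    column = np.asarray(column, dtype=float)
    if column.size < 1:
        raise ValueError("rms needs at least 1 sample")
    return float(np.sqrt(np.mean(column**2)))


def mean_power_frequency(column: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency of the mean-removed periodogram.

    Single-taper periodogram, no zero padding, DC bin excluded; the
    result lies in (0, fs/2].  A zero-power (constant) column raises.
    """
    column = np.asarray(column, dtype=float)
    if column.size < 4:
        raise ValueError("mean_power_frequency needs at least 4 samples")
    f, p = periodogram(column, fs=fs, detrend="constant")
    f, p = f[1:], p[1:]  # drop DC
    total = p.sum()
    if not total > 0:
        raise ValueError("undefined MPF for zero-power signal")
    return float((f * p).sum() / total)


@dataclass(frozen=True)
class FeatureVector:
    """Features of one window: per column (abs_std, rms, mpf)."""

    values: np.ndarray
    source_cols: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size != 3 * len(self.source_cols):
            raise ValueError(
                f"{values.size} values for {len(self.source_cols)} columns; "
                "expected 3 per column"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(
            f"{col}_{feat}" for col in self.source_cols for feat in FEATURE_ORDER
        )


def extract(
    window: SampleMatrix | AugmentedMatrix, amplitude_stat: str = "abs_std"
) -> FeatureVector:
    """Extract the three features from every column of a window.

    ``amplitude_stat`` selects the first feature slot: ``"abs_std"``
    (default) or ``"mav"`` (mean absolute value).  The layout is
    deterministic: column order, then (amplitude, rms, mpf).
    """
    if amplitude_stat not in ("abs_std", "mav"):
        raise ValueError(f"unknown amplitude_stat {amplitude_stat!r}")
    amp = abs_std if amplitude_stat == "abs_std" else mean_absolute_value
    data = window.data
    fs = window.fs
    # one periodogram call across all columns
    f, p = periodogram(data, fs=fs, detrend="constant", axis=0)
    f, p = f[1:], p[1:, :]
    totals = p.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise ValueError(
            f"undefined MPF for zero-power signal in column "
            f"{window.channel_names[bad]!r}"
        )
    mpfs = (f[:, None] * p).sum(axis=0) / totals
    values = np.empty(3 * data.shape[1])
    for c in range(data.shape[1]):
        values[3 * c] = amp(data[:, c])
        values[3 * c + 1] = rms(data[:, c])
        values[3 * c + 2] = mpfs[c]
    return FeatureVector(values=values, source_cols=tuple(window.channel_names))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training-set extrema for min-max rescaling."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        x_min = np.asarray(self.x_min, dtype=float)
        x_max = np.asarray(self.x_max, dtype=float)
        if x_min.shape != x_max.shape or x_min.ndim != 1:
            raise ValueError("x_min and x_max must be 1-D and equal length")
        if np.any(x_min > x_max):
            raise ValueError("x_min must not exceed x_max")
        object.__setattr__(self, "x_min", x_min)
        object.__setattr__(self, "x_max", x_max)

    @property
    def n_features(self) -> int:
        return self.x_min.size


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(np.asarray(vectors, dtype=float))
    return np.vstack([np.asarray(v.values, dtype=float) for v in vectors])


def fit_normalizer(training_vectors) -> NormalizationParams:
    """Per-feature min and max over the training set.

    Accepts a 2-D array (rows = vectors) or a sequence of
    :class:`FeatureVector`; at least 2 training vectors are required.
    """
    x = _as_matrix(training_vectors)
    if x.shape[0] < 2:
        raise ValueError("fit_normalizer needs at least 2 training vectors")
    return NormalizationParams(x_min=x.min(axis=0), x_max=x.max(axis=0))


def apply_normalizer(vector, params: NormalizationParams) -> np.ndarray:
    """Min-max rescale to [0, 1], clipping values outside the training range.

    Degenerate features (x_min == x_max) map to 0.  Accepts a single
    vector or a 2-D matrix; returns the same shape.
    """
    x = np.asarray(
        vector.values if isinstance(vector, FeatureVector) else vector, dtype=float
    )
    if x.shape[-1] != params.n_features:
        raise ValueError(
            f"vector length {x.shape[-1]} does not match normalizer "
            f"({params.n_features} features)"
        )
    span = params.x_max - params.x_min
    with np.errstate(divide="ignore", invalid="ignore"):
        y = (x - params.x_min) / span
    y = np.where(span > 0, y, 0.0)
    return np.clip(y, 0.0, 1.0)


@dataclass(frozen=True)
class LabeledFeatureSet:
    """Feature matrix (rows = windows) with a gesture id per row.

    Intended to hold normalized features in [0, 1]; finiteness and
    nonempty classes are enforced, the [0, 1] range is checked downstream
    (the separability statistic warns on unnormalized input).
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        labels = np.asarray(self.labels, dtype=int)
        if matrix.shape[0] != labels.size:
            raise ValueError(
                f"{matrix.shape[0]} rows but {labels.size} labels"
            )
        if matrix.shape[0] < 1:
            raise ValueError("feature set must contain at least one row")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("feature matrix must be finite")
        if self.feature_names and len(self.feature_names) != matrix.shape[1]:
            raise ValueError("one feature name per column is required")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_rows(self, label: int) -> np.ndarray:
        rows = self.matrix[self.labels == label]
        if rows.shape[0] == 0:
            raise ValueError(f"class {label} has no samples")
        return rows

    def subset(self, row_indices: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            self.matrix[row_indices], self.labels[row_indices], self.feature_names
        )

    def warn_if_unnormalized(self, tol: float = 1e-9) -> None:
        lo, hi = self.matrix.min(), self.matrix.max()
        if lo < -tol or hi > 1 + tol:
            warnings.warn(
                f"feature values outside [0, 1] (range [{lo:.3g}, {hi:.3g}]); "
                "the separability statistic is defined on normalized features",
                stacklevel=3,
            )
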