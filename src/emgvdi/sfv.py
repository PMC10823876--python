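"""SFV — separability of feature vectors.

A scalar summary of how separable a labeled, normalized feature set is,
defined as the ratio of interclass to intraclass dispersion:

    SFV = D / c

where

* D is the mean Euclidean distance between class mean feature vectors
  over all unordered class pairs,
      D = 2/(K(K-1)) * sum_{p<q} ||mean_p - mean_q||,
* c is the grand mean of the per-class, per-feature population standard
  deviations,
      c = 1/(I*K) * sum_i sum_k s_i^k.

Large D means gesture clusters sit far apart; small c means each cluster
is tight.  SFV is computed from the feature set alone — no classifier is
trained — which makes it a fast predictor of recognition quality that is
less sensitive to sample size than a measured accuracy.

SFV is invariant to relabeling, feature permutation, global translation
and global positive scaling of the feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .features import LabeledFeatureSet

__all__ = [
    "SFVComponents",
    "class_means",
    "class_stds",
    "between_dispersion",
    "within_dispersion",
    "sfv_score",
]


@dataclass(frozen=True)
class SFVComponents:
    """Class statistics plus the dispersion ratio.

    ``class_means`` and ``class_stds`` are K x I (classes in ``classes``
    order); ``sfv = D / c``, reported as ``inf`` with ``infinite=True``
    when every cluster collapses to a point (c = 0) but the points
    differ (D > 0).
    """

    classes: np.ndarray
    class_sizes: np.ndarray
    class_means: np.ndarray
    class_stds: np.ndarray
    D: float
    c: float
    sfv: float
    infinite: bool = False


def class_means(fs: LabeledFeatureSet) -> np.ndarray:
    """K x I matrix of per-class feature means (classes in sorted order)."""
    return np.vstack([fs.class_rows(k).mean(axis=0) for k in fs.classes])


def class_stds(fs: LabeledFeatureSet, ddof: int = 0) -> np.ndarray:
    """K x I matrix of per-class feature standard deviations.

    Population form (``ddof=0``, divisor J) by default; ``ddof=1`` gives
    the sample form for sensitivity analysis.  A single-sample class has
    std 0 under the population form.
    """
    out = []
    for k in fs.classes:
        rows = fs.class_rows(k)
        if ddof > 0 and rows.shape[0] <= ddof:
            raise ValueError(
                f"class {k} has {rows.shape[0]} sample(s); ddof={ddof} "
                "requires more"
            )
        out.append(rows.std(axis=0, ddof=ddof))
    return np.vstack(out)


def between_dispersion(means: np.ndarray) -> float:
    """Mean pairwise Euclidean distance between the K class means.

    Equals 2/(K(K-1)) times the sum over unordered pairs; requires
    K >= 2.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape[0] < 2:
        raise ValueError("between_dispersion requires at least 2 classes")
    return float(pdist(means).mean())


def within_dispersion(stds: np.ndarray) -> float:
    """Grand mean of all class-feature standard deviations."""
    stds = np.atleast_2d(np.asarray(stds, dtype=float))
    if stds.size == 0:
        raise ValueError("within_dispersion requires a nonempty std matrix")
    return float(stds.mean())


def sfv_score(
    fs: LabeledFeatureSet, ddof: int = 0, check_range: bool = True
) -> SFVComponents:
    """Compute D, c and SFV = D/c for a labeled feature set.

    Requires at least 2 classes, each nonempty.  If c = 0 while D > 0
    (perfectly separable point clusters) SFV is +inf with the
    ``infinite`` flag set; if both are 0 the statistic is undefined and a
    ``ValueError`` is raised.  Warns (does not fail) when features fall
    outside [0, 1], since the statistic is defined on normalized
    features.
    """
    classes = fs.classes
    if classes.size < 2:
        raise ValueError("SFV requires at least 2 classes")
    if check_range:
        fs.warn_if_unnormalized()
    means = class_means(fs)
    stds = class_stds(fs, ddof=ddof)
    d = between_dispersion(means)
    c = within_dispersion(stds)
    infinite = False
    if c > 0:
        value = d / c
    elif d > 0:
        value = float("inf")
        infinite = True
    else:
        raise ValueError(
            "SFV undefined: all samples identical (D = c = 0)"
        )
    sizes = np.array([int((fs.labels == k).sum()) for k in classes])
    return SFVComponents(
        classes=classes,
        class_sizes=sizes,
        class_means=means,
        class_stds=stds,
        D=d,
        c=c,
        sfv=value,
        infinite=infinite,
    )
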