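"""Virtual-dimension increase: pairwise data-level channel fusion.

The core idea: from a window ``S`` with physical channels ``s_1..s_n``,
derive for each unordered channel pair (i, j) a *virtual channel*

    v_ij[t] = | s_i[t]^2 - s_j[t]^2 |

The squared signal tracks instantaneous muscle-activity intensity, so the
absolute difference of squares encodes the intensity contrast between two
muscles during a gesture — information about inter-muscle synergy that no
single physical channel carries.  Appending the virtual channels to the
window increases its dimensionality without extra electrodes.

Virtual channels have units of amplitude squared; no rescaling is applied
here because downstream min-max feature normalization absorbs scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .windows import SampleMatrix

__all__ = ["AugmentedMatrix", "square_sample", "virtual_channel", "augment"]


@dataclass(frozen=True)
class AugmentedMatrix:
    """A window with its physical channels followed by virtual channels.

    ``data`` is ``m x (n + P)``: the first ``n_physical`` columns are the
    source window bit-identical, the remaining ``P`` columns are one
    virtual channel per (i, j) pair in ``virtual_pairs`` (0-based physical
    column indices, i < j).  Virtual columns are named ``v_<i+1>_<j+1>``
    after the field's 1-based channel numbering.
    """

    data: np.ndarray
    n_physical: int
    virtual_pairs: tuple[tuple[int, int], ...]
    fs: float
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = self.n_physical + len(self.virtual_pairs)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"data has {self.data.shape[1]} columns, expected {expected}"
            )
        if len(self.column_names) != expected:
            raise ValueError("one column name per column is required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        """Total column count, physical plus virtual."""
        return self.data.shape[1]

    @property
    def channel_names(self) -> tuple[str, ...]:
        # alias so feature extraction treats physical and augmented
        # windows uniformly
        return self.column_names


def square_sample(window: SampleMatrix) -> np.ndarray:
    """Elementwise square of the window — instantaneous intensity."""
    return window.data**2


def virtual_channel(window: SampleMatrix, i: int, j: int) -> np.ndarray:
    """The |s_i^2 - s_j^2| virtual channel for physical columns i, j (0-based).

    Symmetric in (i, j); elementwise nonnegative.  ``i == j`` is rejected
    (it would always be the zero channel).
    """
    n = window.n_channels
    for idx in (i, j):
        if not 0 <= idx < n:
            raise IndexError(f"channel index {idx} out of range for n={n}")
    if i == j:
        raise ValueError(
            f"virtual channel requires two distinct channels, got i=j={i}"
        )
    return np.abs(window.data[:, i] ** 2 - window.data[:, j] ** 2)


def _canonical_pairs(n: int) -> list[tuple[int, int]]:
    return list(combinations(range(n), 2))


def augment(
    window: SampleMatrix,
    pairs: str | list[tuple[int, int]] = "all",
) -> AugmentedMatrix:
    """Append virtual channels for the requested channel pairs.

    ``pairs="all"`` (default) uses every unordered physical-channel pair
    in lexicographic order, yielding ``n(n-1)/2`` virtual columns; an
    explicit, duplicate-free pair list restricts the fusion for
    ablations.  Physical columns pass through bit-identically.
    """
    n = window.n_channels
    if pairs == "all":
        if n < 2:
            raise ValueError(
                "virtual-dimension increase requires >= 2 physical channels"
            )
        pair_list = _canonical_pairs(n)
    else:
        pair_list = [(int(i), int(j)) for i, j in pairs]
        seen = set()
        for i, j in pair_list:
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate channel pair {key}")
            seen.add(key)
    virtual_cols = [virtual_channel(window, i, j) for i, j in pair_list]
    data = (
        np.column_stack([window.data] + virtual_cols)
        if virtual_cols
        else window.data.copy()
    )
    names = tuple(window.channel_names) + tuple(
        f"v_{i + 1}_{j + 1}" for i, j in pair_list
    )
    return AugmentedMatrix(
        data=data,
        n_physical=n,
        virtual_pairs=tuple(pair_list),
        fs=window.fs,
        column_names=names,
    )
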