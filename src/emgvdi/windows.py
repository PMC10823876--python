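"""Raw sEMG analysis windows: the sample matrix, delimited-text I/O, segmentation.

A *sample matrix* is one analysis window of multichannel surface EMG:
``m`` rows of time samples by ``n`` columns of physical channels, recorded
at a known sampling frequency.  The canonical window in this package is
200 ms at 1 kHz, i.e. a 200-row matrix, treated as one classification
instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampleMatrix", "read_window", "write_window", "segment"]


@dataclass(frozen=True)
class SampleMatrix:
    """One multichannel EMG window.

    Parameters
    ----------
    data
        ``m x n`` array, rows = time samples, columns = physical channels,
        amplitude in arbitrary units.  ``m >= 2``, ``n >= 1``, all finite.
    fs
        Sampling frequency in Hz.
    channel_names
        One unique name per column.  Auto-named ``ch1..chn`` if omitted.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"sample matrix must be 2-D, got shape {data.shape}")
        m, n = data.shape
        if m < 2:
            raise ValueError(f"a window needs at least 2 time samples, got m={m}")
        if n < 1:
            raise ValueError("a window needs at least 1 channel")
        if not np.all(np.isfinite(data)):
            r, c = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at row {r}, column {c} of the sample matrix"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        names = self.channel_names or tuple(f"ch{i + 1}" for i in range(n))
        if len(names) != n:
            raise ValueError(
                f"{len(names)} channel names for {n} channels"
            )
        if len(set(names)) != n:
            raise ValueError(f"channel names must be unique, got {names}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(names))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select_channels(self, names: tuple[str, ...] | list[str]) -> "SampleMatrix":
        """Return a window containing only ``names``, in the given order."""
        idx = [self.channel_names.index(nm) for nm in names]
        return SampleMatrix(self.data[:, idx], self.fs, tuple(names))


def _detect_delimiter(first_line: str) -> str:
    # comma or tab, per the text dialect this package writes and reads
    return "\t" if first_line.count("\t") > first_line.count(",") else ","


def read_window(path, fs: float) -> SampleMatrix:
    """Read a delimited-text (CSV/TSV) window into a :class:`SampleMatrix`.

    The delimiter (comma or tab) is auto-detected.  An optional single
    header row supplies channel names; otherwise channels are auto-named
    ``ch1..chn``.  Ragged rows, non-numeric cells and NaNs raise a
    ``ValueError`` naming the offending row and column.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n\r") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0])
    first = [c.strip() for c in lines[0].split(delim)]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header: tuple[str, ...] = ()
    body_start = 0
    if not all(_is_number(tok) for tok in first):
        header = tuple(first)
        body_start = 1

    rows: list[list[float]] = []
    ncol = None
    for r, line in enumerate(lines[body_start:]):
        cells = [c.strip() for c in line.split(delim)]
        if ncol is None:
            ncol = len(cells)
        elif len(cells) != ncol:
            raise ValueError(
                f"{path}: ragged row {r} has {len(cells)} cells, expected {ncol}"
            )
        parsed = []
        for c, tok in enumerate(cells):
            try:
                val = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {tok!r}"
                ) from None
            if not np.isfinite(val):
                raise ValueError(
                    f"{path}: non-finite value at row {r}, column {c}"
                )
            parsed.append(val)
        rows.append(parsed)
    return SampleMatrix(np.array(rows, dtype=float), fs, header)


def write_window(window: SampleMatrix, path, delimiter: str = ",") -> None:
    """Write a window as delimited text with a channel-name header row."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(window.channel_names) + "\n")
        np.savetxt(fh, window.data, delimiter=delimiter, fmt="%.10g")


def segment(
    recording: SampleMatrix, window_len: int, step: int | None = None
) -> list[SampleMatrix]:
    """Cut a longer recording into fixed-length analysis windows.

    Windows start at 0-based indices ``0, step, 2*step, ...`` and span the
    half-open range ``[start, start + window_len)``; a trailing partial
    window is discarded.  ``step`` defaults to ``window_len`` (disjoint
    windows).  Returns ``floor((m - window_len)/step) + 1`` windows.
    """
    if step is None:
        step = window_len
    m = recording.n_samples
    if window_len > m:
        raise ValueError(
            f"window_len {window_len} exceeds recording length {m}"
        )
    if window_len < 2:
        raise ValueError("window_len must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    starts = range(0, m - window_len + 1, step)
    return [
        SampleMatrix(
            recording.data[s : s + window_len].copy(),
            recording.fs,
            recording.channel_names,
        )
        for s in starts
    ]
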