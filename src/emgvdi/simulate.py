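"""Synthetic gesture-conditioned surface-EMG generator.

Real interference-pattern sEMG is well approximated, for amplitude-based
pattern recognition, by bandlimited Gaussian noise whose standard
deviation tracks the contraction intensity of the underlying muscle.
This module generates multichannel windows on that model: each channel is

    activation(gesture, muscle) * jitter * carrier + baseline noise

where the carrier is zero-mean Gaussian noise bandpassed to the 20-450 Hz
sEMG band (zero-phase 4th-order Butterworth) and standardised to unit
sample standard deviation, the multiplicative log-normal jitter creates
realistic window-to-window amplitude spread within a gesture class, and
the baseline term is the electrode/amplifier noise floor.

Carriers are not independent across muscles: each gesture has a
*common-drive* coefficient rho that mixes a window-wide shared source
into every channel's carrier (pairwise carrier correlation ~ rho^2),
emulating gesture-specific co-contraction synergy.  Per-channel marginal
statistics are unchanged by rho — only joint, cross-channel structure
carries it, which is exactly the information a pairwise intensity-
contrast channel can expose and per-channel features cannot.

The default activation profile encodes which of four forearm muscles
(extensor carpi ulnaris, extensor pollicis longus, flexor digitorum
superficialis, extensor digiti minimi) participate in each of the five
gestures, with amplitudes chosen so that recognition from few channels is
realistically imperfect: some gesture pairs are nearly indistinguishable
on a two-channel montage and only resolve as channels are added.

Reproducibility: every random draw for a channel is seeded from the
window seed and a stable per-muscle identifier, so a simulated channel is
bit-identical whether it is generated alone, as part of a subset, or as
part of the full four-channel montage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .gestures import GESTURES, GestureLabel
from .windows import SampleMatrix

__all__ = [
    "MUSCLES",
    "ActivationProfile",
    "SimConfig",
    "default_activation_profile",
    "simulate_window",
    "simulate_dataset",
    "write_dataset",
    "dataset_to_frame",
]

#: Canonical forearm muscle order (strongest / most movements first).
MUSCLES: tuple[str, ...] = (
    "extensor_carpi_ulnaris",
    "extensor_pollicis_longus",
    "flexor_digitorum_superficialis",
    "extensor_digiti_minimi",
)


@dataclass(frozen=True)
class ActivationProfile:
    """Gesture x muscle activation amplitudes driving the simulator.

    ``matrix[g, c]`` is the nonnegative contraction amplitude (arbitrary
    units) of muscle ``channels[c]`` during gesture ``g+1``.  Rows must be
    pairwise distinct, otherwise two gestures would be indistinguishable
    by construction.  ``baseline_sd`` is the additive noise floor and
    ``band`` the carrier passband in Hz.  ``jitter_sigma`` is the sigma of
    the per-window, per-channel multiplicative log-normal amplitude
    jitter (0 disables it).  ``common_drive`` holds one coefficient rho
    in [0, 1) per gesture: the fraction of every channel's carrier drawn
    from a window-wide shared source (co-contraction synergy); 0 gives
    independent carriers.
    """

    channels: tuple[str, ...]
    matrix: np.ndarray
    baseline_sd: float = 0.2
    band: tuple[float, float] = (20.0, 450.0)
    jitter_sigma: float = 0.25
    common_drive: tuple[float, ...] = (0.0,) * 5

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != len(GESTURES):
            raise ValueError(
                f"activation matrix must be {len(GESTURES)} x n_channels, "
                f"got shape {matrix.shape}"
            )
        if matrix.shape[1] != len(self.channels):
            raise ValueError("one activation column per channel is required")
        if np.any(matrix < 0):
            raise ValueError("activations must be nonnegative")
        for a in range(matrix.shape[0]):
            for b in range(a + 1, matrix.shape[0]):
                if np.array_equal(matrix[a], matrix[b]):
                    raise ValueError(
                        f"gestures {a + 1} and {b + 1} have identical "
                        "activation rows; they would be indistinguishable"
                    )
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be nonnegative")
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"invalid passband {self.band}")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be nonnegative")
        if len(self.common_drive) != matrix.shape[0]:
            raise ValueError("one common_drive coefficient per gesture")
        if any(not 0 <= r < 1 for r in self.common_drive):
            raise ValueError("common_drive coefficients must lie in [0, 1)")
        object.__setattr__(self, "common_drive", tuple(self.common_drive))
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "channels", tuple(self.channels))

    def activation(self, gesture: GestureLabel, channel: str) -> float:
        return float(self.matrix[gesture.id - 1, self.channels.index(channel)])

    def subset(self, channels: tuple[str, ...] | list[str]) -> "ActivationProfile":
        """Profile restricted to ``channels``, in the given order."""
        idx = [self.channels.index(c) for c in channels]
        return replace(self, channels=tuple(channels), matrix=self.matrix[:, idx])


# Rows: thumbs_up, v_sign, ok_sign, fist, open_hand; columns follow MUSCLES.
# Amplitudes encode qualitative muscle involvement: the thumb extensor
# (extensor pollicis longus) drives thumbs_up/fist/open_hand; the finger
# flexor-extensors (flexor digitorum superficialis, extensor carpi ulnaris)
# drive everything except thumbs_up; the little-finger extensor (extensor
# digiti minimi) drives ok_sign/fist/open_hand.  Inactive muscles keep a
# small tonic level.  The magnitudes are chosen so that recognition
# difficulty tracks the montage: fist/open_hand nearly coincide on the
# thumb/little-finger pair (resolved mainly by the finger flexor added at
# three channels), and v_sign/ok_sign stay close until the wrist extensor
# added at four channels.
_DEFAULT_MATRIX = np.array(
    [
        # ECU   EPL   FDS   EDM
        [0.10, 0.80, 0.10, 0.10],  # thumbs_up
        [0.60, 0.10, 0.55, 0.15],  # v_sign
        [0.45, 0.14, 0.50, 0.32],  # ok_sign
        [0.75, 0.60, 0.85, 0.50],  # fist
        [0.55, 0.56, 0.62, 0.55],  # open_hand
    ]
)

# Per-gesture common-drive (co-contraction synergy): strong for the power
# grip, weak for the isolated thumb extension.
_DEFAULT_COMMON_DRIVE = (0.20, 0.40, 0.50, 0.85, 0.45)


def default_activation_profile() -> ActivationProfile:
    """The package's fixed 5-gesture x 4-muscle activation profile.

    Deterministic; amplitudes are package constants in [0, 1], not claims
    about physiology.
    """
    return ActivationProfile(
        channels=MUSCLES,
        matrix=_DEFAULT_MATRIX.copy(),
        common_drive=_DEFAULT_COMMON_DRIVE,
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters: 1 kHz sampling, 200-sample (200 ms) windows,
    150 windows per gesture by default."""

    fs: float = 1000.0
    window_len: int = 200
    n_windows_per_gesture: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.window_len < 2:
            raise ValueError("window_len must be at least 2")
        if self.n_windows_per_gesture < 1:
            raise ValueError("n_windows_per_gesture must be at least 1")


@lru_cache(maxsize=8)
def _carrier_sos(band: tuple[float, float], fs: float):
    low, high = band
    if not high < fs / 2:
        raise ValueError(
            f"passband {band} must lie strictly below the Nyquist "
            f"frequency {fs / 2}"
        )
    return butter(4, band, btype="bandpass", fs=fs, output="sos")


def _min_window_len(sos: np.ndarray) -> int:
    # sosfiltfilt requires x.shape[axis] > padlen (its default edge padding)
    n_sections = sos.shape[0]
    ntaps = 2 * n_sections + 1
    ntaps -= min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())
    return 3 * ntaps + 1


#: Reserved stream name for the shared common-drive source.
_COMMON_DRIVE_TAG = "__common_drive__"


def _channel_rng(seed: int, channel: str) -> np.random.Generator:
    # stable per-muscle stream: the same channel is bit-identical whether
    # simulated alone or within any montage
    return np.random.default_rng([int(seed), zlib.crc32(channel.encode())])


def simulate_window(
    gesture: GestureLabel,
    profile: ActivationProfile,
    cfg: SimConfig,
    seed: int,
) -> SampleMatrix:
    """Simulate one multichannel window for ``gesture``.

    Identical ``(gesture, profile, cfg, seed)`` give a bit-identical
    matrix.  Raises if the window is too short for the zero-phase
    bandpass filter, naming the minimum length.
    """
    if not isinstance(gesture, GestureLabel):
        raise TypeError(f"expected a GestureLabel, got {type(gesture).__name__}")
    sos = _carrier_sos(profile.band, cfg.fs)
    min_len = _min_window_len(sos)
    if cfg.window_len < min_len:
        raise ValueError(
            f"window_len {cfg.window_len} is too short for the zero-phase "
            f"bandpass filter; minimum is {min_len} samples"
        )
    m = cfg.window_len
    n = len(profile.channels)
    noise = np.empty((m, n))
    jitters = np.empty(n)
    baseline = np.zeros((m, n))
    for c, name in enumerate(profile.channels):
        rng = _channel_rng(seed, name)
        noise[:, c] = rng.standard_normal(m)
        jitters[c] = (
            rng.lognormal(0.0, profile.jitter_sigma)
            if profile.jitter_sigma > 0
            else 1.0
        )
        if profile.baseline_sd > 0:
            baseline[:, c] = profile.baseline_sd * rng.standard_normal(m)
    rho = profile.common_drive[gesture.id - 1]
    if rho > 0:
        # shared source stream is independent of the montage, so any
        # channel subset stays bit-identical to the full simulation
        common = _channel_rng(seed, _COMMON_DRIVE_TAG).standard_normal(m)
        noise = np.sqrt(1.0 - rho**2) * noise + rho * common[:, None]
    carriers = sosfiltfilt(sos, noise, axis=0)
    sd = carriers.std(axis=0)
    carriers = np.where(sd > 0, carriers / np.where(sd > 0, sd, 1.0), carriers)
    amps = profile.matrix[gesture.id - 1] * jitters
    return SampleMatrix(amps * carriers + baseline, cfg.fs, profile.channels)


def window_seed(master_seed: int, gesture_id: int, index: int) -> int:
    """Deterministic per-window seed from (master seed, gesture, index).

    Order-independent: the seed of window ``index`` of a gesture does not
    depend on how many other windows are generated.
    """
    ss = np.random.SeedSequence([int(master_seed), int(gesture_id), int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_dataset(
    profile: ActivationProfile, cfg: SimConfig
) -> list[tuple[SampleMatrix, GestureLabel]]:
    """Simulate ``n_windows_per_gesture`` labeled windows per gesture.

    Returns exactly ``5 * n_windows_per_gesture`` pairs, grouped by
    gesture in label order; bit-identical for equal inputs.
    """
    out: list[tuple[SampleMatrix, GestureLabel]] = []
    for gesture in GESTURES:
        for w in range(cfg.n_windows_per_gesture):
            s = window_seed(cfg.seed, gesture.id, w)
            out.append((simulate_window(gesture, profile, cfg, s), gesture))
    return out


def write_dataset(
    dataset: list[tuple[SampleMatrix, GestureLabel]], outdir, master_seed: int | None = None
) -> pd.DataFrame:
    """Write one CSV per window plus a ``manifest.csv`` table.

    The manifest records filename, gesture id and name, and the window's
    seed column when ``master_seed`` is given.  Returns the manifest.
    """
    import os

    from .windows import write_window

    os.makedirs(outdir, exist_ok=True)
    records = []
    per_gesture_count: dict[int, int] = {}
    for window, gesture in dataset:
        idx = per_gesture_count.get(gesture.id, 0)
        per_gesture_count[gesture.id] = idx + 1
        fname = f"window_g{gesture.id}_{idx:04d}.csv"
        write_window(window, os.path.join(outdir, fname))
        rec = {
            "filename": fname,
            "gesture_id": gesture.id,
            "gesture_name": gesture.name,
            "window_index": idx,
        }
        if master_seed is not None:
            rec["seed"] = window_seed(master_seed, gesture.id, idx)
        records.append(rec)
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest


def dataset_to_frame(
    dataset: list[tuple[SampleMatrix, GestureLabel]]
) -> pd.DataFrame:
    """Single long-format table: window index, gesture, time sample, channels."""
    frames = []
    for w, (window, gesture) in enumerate(dataset):
        df = pd.DataFrame(window.data, columns=list(window.channel_names))
        df.insert(0, "t", np.arange(window.n_samples))
        df.insert(0, "gesture_id", gesture.id)
        df.insert(0, "window", w)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
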