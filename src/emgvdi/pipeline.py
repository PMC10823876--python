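"""End-to-end experiments: simulate, augment, extract, score, classify.

The experiments mirror the study design the method was proposed under:
per "subject" (one master seed), simulate 150 windows per gesture on a
2-, 3- or 4-channel montage, optionally append virtual channels, extract
and normalize features, compute the SFV separability statistic, train
the gesture classifier on a stratified 2:1 split and measure test
accuracy.  :func:`compare_vdi` runs the with/without-augmentation arms
on byte-identical raw windows per seed (a paired design), and
:func:`subsample_study` measures how accuracy and SFV behave as the
per-gesture sample count shrinks.

Montages follow the study's channel ranking: the 2-channel montage is
{extensor pollicis longus, extensor digiti minimi}, the 3-channel adds
flexor digitorum superficialis, the 4-channel adds extensor carpi
ulnaris.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .classify import MLPConfig, SplitSpec, evaluate, split, train
from .features import LabeledFeatureSet, apply_normalizer, extract, fit_normalizer
from .gestures import GestureLabel
from .sfv import SFVComponents, sfv_score
from .simulate import ActivationProfile, SimConfig, default_activation_profile, simulate_dataset
from .vdi import augment
from .windows import SampleMatrix

__all__ = [
    "CHANNEL_SUBSETS",
    "ExperimentConfig",
    "ArmResult",
    "ComparisonReport",
    "run_arm",
    "compare_vdi",
    "subsample_study",
    "channels_for",
]

#: Montages by physical channel count, mirroring the study's ranking.
CHANNEL_SUBSETS: dict[int, tuple[str, ...]] = {
    2: ("extensor_pollicis_longus", "extensor_digiti_minimi"),
    3: (
        "extensor_pollicis_longus",
        "flexor_digitorum_superficialis",
        "extensor_digiti_minimi",
    ),
    4: (
        "extensor_carpi_ulnaris",
        "extensor_pollicis_longus",
        "flexor_digitorum_superficialis",
        "extensor_digiti_minimi",
    ),
}


def channels_for(count: int) -> tuple[str, ...]:
    """The default montage with ``count`` physical channels (2, 3 or 4)."""
    if count not in CHANNEL_SUBSETS:
        raise ValueError(f"no default montage with {count} channels; use 2, 3 or 4")
    return CHANNEL_SUBSETS[count]


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: montage, sample count, split, number of seeds."""

    channels: tuple[str, ...] = CHANNEL_SUBSETS[4]
    augment: bool = False
    n_per_gesture: int = 150
    train_fraction: float = 2.0 / 3.0
    n_seeds: int = 20
    seed: int = 0
    fs: float = 1000.0
    window_len: int = 200
    amplitude_stat: str = "abs_std"
    sfv_scope: str = "all"
    profile: ActivationProfile = field(default_factory=default_activation_profile)
    mlp: MLPConfig = field(default_factory=MLPConfig)

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("channel subset must be nonempty")
        unknown = set(self.channels) - set(self.profile.channels)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.sfv_scope not in ("all", "train", "test"):
            raise ValueError(f"unknown sfv_scope {self.sfv_scope!r}")


@dataclass(frozen=True)
class ArmResult:
    """One arm of one seed: accuracy plus the separability components."""

    accuracy: float
    sfv: SFVComponents
    report: object
    n_features: int


def _stage_seed(seed: int, tag: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return int(ss.generate_state(1)[0] % 2**31)


def _arm_seed(master_seed: int, seed_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), 1000 + int(seed_index)])
    return int(ss.generate_state(1)[0] % 2**31)


def _feature_table(
    dataset: list[tuple[SampleMatrix, GestureLabel]],
    do_augment: bool,
    amplitude_stat: str,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    rows, labels = [], []
    names: tuple[str, ...] = ()
    for window, gesture in dataset:
        w = augment(window, "all") if do_augment else window
        fv = extract(w, amplitude_stat=amplitude_stat)
        rows.append(fv.values)
        labels.append(gesture.id)
        names = fv.feature_names
    return np.vstack(rows), np.asarray(labels), names


def _evaluate_features(
    raw: np.ndarray,
    labels: np.ndarray,
    names: tuple[str, ...],
    cfg: ExperimentConfig,
    split_seed: int,
    train_seed: int,
) -> ArmResult:
    raw_set = LabeledFeatureSet(raw, labels, names)
    spec = SplitSpec(train_fraction=cfg.train_fraction, seed=split_seed)
    train_raw, test_raw = split(raw_set, spec)
    params = fit_normalizer(train_raw.matrix)
    train_set = LabeledFeatureSet(
        apply_normalizer(train_raw.matrix, params), train_raw.labels, names
    )
    test_set = LabeledFeatureSet(
        apply_normalizer(test_raw.matrix, params), test_raw.labels, names
    )
    if cfg.sfv_scope == "train":
        sfv_set = train_set
    elif cfg.sfv_scope == "test":
        sfv_set = test_set
    else:
        all_norm = apply_normalizer(raw_set.matrix, params)
        sfv_set = LabeledFeatureSet(all_norm, raw_set.labels, names)
    components = sfv_score(sfv_set)
    clf = train(train_set, replace(cfg.mlp, seed=train_seed))
    report = evaluate(clf, test_set)
    return ArmResult(
        accuracy=report.overall_accuracy,
        sfv=components,
        report=report,
        n_features=raw.shape[1],
    )


def run_arm(cfg: ExperimentConfig, do_augment: bool, seed: int) -> ArmResult:
    """Run one full pipeline pass for one arm under one seed.

    simulate -> (augment?) -> extract -> fit/apply normalizer ->
    SFV -> split -> train -> evaluate, with the simulation, split and
    training seeds all derived from ``seed``.  The simulated windows do
    not depend on ``do_augment``, so the two arms of a paired comparison
    consume byte-identical raw data.
    """
    sim_cfg = SimConfig(
        fs=cfg.fs,
        window_len=cfg.window_len,
        n_windows_per_gesture=cfg.n_per_gesture,
        seed=_stage_seed(seed, 0),
    )
    dataset = simulate_dataset(cfg.profile.subset(cfg.channels), sim_cfg)
    raw, labels, names = _feature_table(dataset, do_augment, cfg.amplitude_stat)
    return _evaluate_features(
        raw, labels, names, cfg, _stage_seed(seed, 1), _stage_seed(seed, 2)
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Paired with/without-augmentation results across seeds."""

    config: ExperimentConfig
    records: tuple[dict, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    def _column(self, arm: str, what: str) -> np.ndarray:
        return np.array([r[f"{what}_{arm}"] for r in self.records])

    def mean(self, arm: str, what: str = "accuracy") -> float:
        return float(self._column(arm, what).mean())

    def std(self, arm: str, what: str = "accuracy") -> float:
        return float(self._column(arm, what).std(ddof=1))

    def deltas(self, what: str = "accuracy") -> np.ndarray:
        return self._column("vdi", what) - self._column("plain", what)

    def summary(self) -> dict:
        out = {"n_seeds": len(self.records), "n_channels": len(self.config.channels)}
        for what in ("accuracy", "sfv"):
            out[f"mean_{what}_plain"] = self.mean("plain", what)
            out[f"mean_{what}_vdi"] = self.mean("vdi", what)
            out[f"mean_delta_{what}"] = float(self.deltas(what).mean())
        return out


def compare_vdi(cfg: ExperimentConfig) -> ComparisonReport:
    """Run both arms on paired seeds and report per-seed deltas.

    For each of ``cfg.n_seeds`` derived arm seeds, the plain and
    augmented arms are executed on the identical simulated dataset; the
    report carries accuracy, SFV, D and c per seed and arm.
    """
    records = []
    for s in range(cfg.n_seeds):
        seed = _arm_seed(cfg.seed, s)
        rec: dict = {"seed_index": s, "arm_seed": seed}
        # Simulate once and extract the augmented feature table once:
        # physical columns pass through augmentation bit-identically and
        # features are per-column, so the plain arm's table is exactly
        # the leading 3n columns of the augmented one.
        sim_cfg = SimConfig(
            fs=cfg.fs,
            window_len=cfg.window_len,
            n_windows_per_gesture=cfg.n_per_gesture,
            seed=_stage_seed(seed, 0),
        )
        dataset = simulate_dataset(cfg.profile.subset(cfg.channels), sim_cfg)
        raw_aug, labels, names_aug = _feature_table(
            dataset, True, cfg.amplitude_stat
        )
        n_phys_feat = 3 * len(cfg.channels)
        arms = {
            "plain": (raw_aug[:, :n_phys_feat], names_aug[:n_phys_feat]),
            "vdi": (raw_aug, names_aug),
        }
        for arm_name, (raw, names) in arms.items():
            res = _evaluate_features(
                raw, labels, names, cfg, _stage_seed(seed, 1), _stage_seed(seed, 2)
            )
            rec[f"accuracy_{arm_name}"] = res.accuracy
            rec[f"sfv_{arm_name}"] = res.sfv.sfv
            rec[f"D_{arm_name}"] = res.sfv.D
            rec[f"c_{arm_name}"] = res.sfv.c
            rec[f"n_features_{arm_name}"] = res.n_features
        rec["delta_accuracy"] = rec["accuracy_vdi"] - rec["accuracy_plain"]
        rec["delta_sfv"] = rec["sfv_vdi"] - rec["sfv_plain"]
        records.append(rec)
    return ComparisonReport(config=cfg, records=tuple(records))


def _subsample_rows(
    labels: np.ndarray, per_class: int, rng: np.random.Generator
) -> np.ndarray:
    keep = []
    for k in np.unique(labels):
        rows = np.flatnonzero(labels == k)
        if per_class > rows.size:
            raise ValueError(
                f"requested {per_class} windows per gesture but class {k} "
                f"has only {rows.size}"
            )
        if per_class == rows.size:
            keep.append(rows)
        else:
            keep.append(rng.choice(rows, size=per_class, replace=False))
    return np.sort(np.concatenate(keep))


def subsample_study(
    cfg: ExperimentConfig,
    sizes: list[int],
    channel_counts: tuple[int, ...] = (2, 3, 4),
) -> pd.DataFrame:
    """Accuracy and SFV across per-gesture subsample sizes and montages.

    For each seed, one full 4-channel dataset is simulated; each montage
    reuses the relevant channels (bit-identical to simulating the
    montage directly, by the simulator's stable per-muscle seeding).
    For each size a random per-gesture subsample is drawn, split 2:1,
    and both quality measures are computed.  A size equal to the full
    dataset reproduces a standard :func:`run_arm` at that montage and
    seed.  Returns a long-format table with one row per (seed, size,
    montage).
    """
    for size in sizes:
        if size > cfg.n_per_gesture:
            raise ValueError(
                f"subsample size {size} exceeds n_per_gesture={cfg.n_per_gesture}"
            )
        if size < 3:
            raise ValueError("subsample size must be >= 3 for a 2:1 split")
    rows = []
    for s in range(cfg.n_seeds):
        seed = _arm_seed(cfg.seed, s)
        sim_cfg = SimConfig(
            fs=cfg.fs,
            window_len=cfg.window_len,
            n_windows_per_gesture=cfg.n_per_gesture,
            seed=_stage_seed(seed, 0),
        )
        full = simulate_dataset(cfg.profile.subset(channels_for(max(channel_counts))), sim_cfg)
        for count in channel_counts:
            montage = channels_for(count)
            dataset = [(w.select_channels(montage), g) for w, g in full]
            raw, labels, names = _feature_table(
                dataset, cfg.augment, cfg.amplitude_stat
            )
            for size in sizes:
                if size == cfg.n_per_gesture:
                    keep = np.arange(labels.size)
                else:
                    sel_rng = np.random.default_rng(
                        [_stage_seed(seed, 3), int(size)]
                    )
                    keep = _subsample_rows(labels, size, sel_rng)
                res = _evaluate_features(
                    raw[keep],
                    labels[keep],
                    names,
                    cfg,
                    _stage_seed(seed, 1),
                    _stage_seed(seed, 2),
                )
                rows.append(
                    {
                        "seed_index": s,
                        "arm_seed": seed,
                        "size": size,
                        "n_channels": count,
                        "accuracy": res.accuracy,
                        "sfv": res.sfv.sfv,
                        "D": res.sfv.D,
                        "c": res.sfv.c,
                    }
                )
    return pd.DataFrame.from_records(rows)


def write_provenance(path, cfg: ExperimentConfig, extra: dict | None = None) -> None:
    """Write a JSON provenance record (config, package version) beside outputs."""
    record = {
        "package_version": _pkg_version,
        "config": _config_dict(cfg),
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["profile"]["matrix"] = cfg.profile.matrix.tolist()
    return d
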