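"""Session containers, file I/O, configuration, and seed management.

Activity tables are CSV with a ``time_s`` column plus one column per subject;
behavior tables are CSV with ``time_s`` plus one ``<subject>_behavior`` label
column per subject. Times are absolute seconds from session start, first bin
at t = 0, on a uniform grid (default step 2.5 s, the sampling period of the
band-averaged LFP-power signals this package models).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_BEHAVIORS",
    "DEFAULT_MODULATION_LEVELS",
    "BehaviorVocabulary",
    "ActivityTimeSeries",
    "BehaviorSequence",
    "RunConfig",
    "read_session",
    "write_session",
    "parse_config",
    "stage_rng",
]

#: The 11-behavior ethogram vocabulary.
DEFAULT_BEHAVIORS = (
    "resting",
    "active non-social",
    "self-grooming",
    "social grooming",
    "probing",
    "fighting",
    "mating",
    "wing covering",
    "reaching",
    "blocking",
    "other interactions",
)

#: Per-behavior neural-modulation levels (dimensionless, on the normalized
#: LFP-power scale), estimated as the average power observed during each
#: behavior.
DEFAULT_MODULATION_LEVELS: Mapping[str, float] = {
    "resting": 0.158,
    "active non-social": 0.269,
    "self-grooming": 0.264,
    "social grooming": 0.223,
    "probing": 0.284,
    "fighting": 0.355,
    "mating": 0.367,
    "wing covering": 0.364,
    "reaching": 0.321,
    "blocking": 0.339,
    "other interactions": 0.291,
}

_GRID_TOL = 1e-9


def _check_uniform_grid(times: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return the step."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("time grid must be 1-D with at least 2 points")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    dt = steps[0]
    if np.any(np.abs(steps - dt) > _GRID_TOL):
        raise ValueError(
            f"non-uniform time grid: step varies by more than {_GRID_TOL} s"
        )
    return float(dt)


@dataclass(frozen=True)
class BehaviorVocabulary:
    """Ordered collection of behavior labels."""

    names: tuple[str, ...] = DEFAULT_BEHAVIORS

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("vocabulary must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("vocabulary names must be unique")
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ActivityTimeSeries:
    """Per-subject neural activity sampled on a uniform time grid.

    ``values`` has one row per subject and one column per time bin.
    """

    times: np.ndarray
    values: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.subject_ids = tuple(self.subject_ids)
        _check_uniform_grid(self.times)
        if self.values.shape != (len(self.subject_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {self.times.size} bins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values contain non-finite entries")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_bins(self) -> int:
        return self.times.size


@dataclass
class BehaviorSequence:
    """Per-subject behavior label per time bin, on the activity grid."""

    times: np.ndarray
    labels: np.ndarray  # (n_subjects, n_bins) array of str
    subject_ids: tuple[str, ...]
    vocabulary: BehaviorVocabulary = field(default_factory=BehaviorVocabulary)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=object))
        self.subject_ids = tuple(self.subject_ids)
        _check_uniform_grid(self.times)
        if self.labels.shape != (len(self.subject_ids), self.times.size):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"{len(self.subject_ids)} subjects x {self.times.size} bins"
            )
        for i in range(self.labels.shape[0]):
            for j in range(self.labels.shape[1]):
                lab = self.labels[i, j]
                if lab not in self.vocabulary:
                    raise ValueError(
                        f"unknown behavior label {lab!r} for subject "
                        f"{self.subject_ids[i]!r} at row {j}"
                    )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_bins(self) -> int:
        return self.times.size


# Keys accepted by parse_config, with their defaults (one-chamber model).
_CONFIG_DEFAULTS = {
    "chamber": "one_chamber",
    "cs": 1.0,
    "ci": None,  # chamber-dependent: 0.4 one-chamber, 0.0 two-chambers
    "tau": 15.0,
    "sigma_n": 0.15,
    "bconstant": None,  # chamber-dependent: -0.08 one-chamber, 0.0 two-chambers
    "duration_min": 100.0,
    "dt": 2.5,
    "seed": 0,
    "modulation": None,
    "out_dir": None,
}


@dataclass
class RunConfig:
    """Full parameter set for a simulated two-subject session.

    Defaults are the one-chamber model parameters: self-coupling CS = 1,
    across-brain coupling CI = 0.4, time constant tau = 15 s, modulation
    noise sigma_n = 0.15, offset bconstant = -0.08, 100-minute sessions at
    2.5 s bins. The two-chambers variant sets CI = 0 and bconstant = 0.
    """

    chamber: str = "one_chamber"
    cs: float = 1.0
    ci: float = 0.4
    tau: float = 15.0
    sigma_n: float = 0.15
    bconstant: float = -0.08
    duration_min: float = 100.0
    dt: float = 2.5
    seed: int = 0
    modulation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODULATION_LEVELS)
    )
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.chamber not in ("one_chamber", "two_chambers"):
            raise ValueError(
                "chamber must be 'one_chamber' or 'two_chambers', "
                f"got {self.chamber!r}"
            )
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        if self.cs <= 0:
            raise ValueError("CS > 0 required")
        if not 0 <= self.ci < self.cs:
            raise ValueError(
                f"stability constraint violated: CI < CS required "
                f"(0 <= CI < CS; got CI={self.ci}, CS={self.cs})"
            )
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_min * 60.0 / self.dt))

    def two_chambers_variant(self) -> "RunConfig":
        """The matched no-coupling configuration (CI = 0, bconstant = 0)."""
        return replace(self, chamber="two_chambers", ci=0.0, bconstant=0.0)


def parse_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) config; unspecified keys take the defaults.

    Unknown keys fail loudly; out-of-range values are rejected by RunConfig
    validation with the violated constraint named.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(
            f"unknown config key(s): {sorted(unknown)}; "
            f"allowed: {sorted(_CONFIG_DEFAULTS)}"
        )
    merged = {**_CONFIG_DEFAULTS, **raw}
    chamber = merged["chamber"]
    if merged["ci"] is None:
        merged["ci"] = 0.4 if chamber == "one_chamber" else 0.0
    if merged["bconstant"] is None:
        merged["bconstant"] = -0.08 if chamber == "one_chamber" else 0.0
    modulation = dict(DEFAULT_MODULATION_LEVELS)
    if merged["modulation"] is not None:
        if not isinstance(merged["modulation"], dict):
            raise ValueError("'modulation' must be a mapping behavior -> level")
        bad = set(merged["modulation"]) - set(DEFAULT_BEHAVIORS)
        if bad:
            raise ValueError(f"unknown behavior(s) in modulation: {sorted(bad)}")
        modulation.update(merged["modulation"])
    return RunConfig(
        chamber=chamber,
        cs=float(merged["cs"]),
        ci=float(merged["ci"]),
        tau=float(merged["tau"]),
        sigma_n=float(merged["sigma_n"]),
        bconstant=float(merged["bconstant"]),
        duration_min=float(merged["duration_min"]),
        dt=float(merged["dt"]),
        seed=int(merged["seed"]),
        modulation=modulation,
        out_dir=merged["out_dir"],
    )


def read_session(
    activity_path: str | Path,
    behavior_path: str | Path | None = None,
    vocabulary: BehaviorVocabulary | None = None,
) -> tuple[ActivityTimeSeries, BehaviorSequence | None]:
    """Read an activity table (and optional behavior table) from CSV."""
    activity_path = Path(activity_path)
    if not activity_path.exists():
        raise FileNotFoundError(str(activity_path))
    adf = pd.read_csv(activity_path)
    if "time_s" not in adf.columns:
        raise ValueError(f"{activity_path}: missing 'time_s' column")
    subj_cols = [c for c in adf.columns if c != "time_s"]
    if not subj_cols:
        raise ValueError(f"{activity_path}: no subject columns")
    if adf.isna().any().any():
        raise ValueError(f"{activity_path}: missing values in table")
    activity = ActivityTimeSeries(
        times=adf["time_s"].to_numpy(float),
        values=adf[subj_cols].to_numpy(float).T,
        subject_ids=tuple(subj_cols),
    )
    behavior = None
    if behavior_path is not None:
        behavior_path = Path(behavior_path)
        if not behavior_path.exists():
            raise FileNotFoundError(str(behavior_path))
        bdf = pd.read_csv(behavior_path)
        if "time_s" not in bdf.columns:
            raise ValueError(f"{behavior_path}: missing 'time_s' column")
        bcols = [c for c in bdf.columns if c != "time_s"]
        if bdf.isna().any().any():
            raise ValueError(f"{behavior_path}: missing values in table")
        vocab = vocabulary or BehaviorVocabulary()
        btimes = bdf["time_s"].to_numpy(float)
        if btimes.size != activity.n_bins or np.any(
            np.abs(btimes - activity.times) > _GRID_TOL
        ):
            raise ValueError(
                "behavior table grid does not match the activity table grid"
            )
        labels = bdf[bcols].to_numpy(dtype=object).T
        for i, col in enumerate(bcols):
            for j, lab in enumerate(labels[i]):
                if lab not in vocab:
                    raise ValueError(
                        f"{behavior_path}: unknown behavior label {lab!r} "
                        f"in column {col!r}, row {j}"
                    )
        ids = tuple(c.removesuffix("_behavior") for c in bcols)
        behavior = BehaviorSequence(
            times=btimes, labels=labels, subject_ids=ids, vocabulary=vocab
        )
    return activity, behavior


def write_session(
    activity: ActivityTimeSeries,
    behavior: BehaviorSequence | None,
    path: str | Path,
) -> dict[str, Path]:
    """Write a session to ``activity.csv`` (and ``behavior.csv``) under path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    adf = pd.DataFrame({"time_s": activity.times})
    for i, sid in enumerate(activity.subject_ids):
        adf[sid] = activity.values[i]
    apath = path / "activity.csv"
    adf.to_csv(apath, index=False, float_format="%.17g")
    out["activity"] = apath
    if behavior is not None:
        bdf = pd.DataFrame({"time_s": behavior.times})
        for i, sid in enumerate(behavior.subject_ids):
            bdf[f"{sid}_behavior"] = behavior.labels[i]
        bpath = path / "behavior.csv"
        bdf.to_csv(bpath, index=False, float_format="%.17g")
        out["behavior"] = bpath
    return out


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed.

    The stage label is hashed (CRC-32) and combined with the master seed in a
    SeedSequence, so each named stage of a run draws from an independent
    stream yet is individually reproducible.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def sequences_match(a: Sequence[float], b: Sequence[float], tol: float = 1e-12) -> bool:
    """Convenience: elementwise agreement within tol."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return a.shape == b.shape and bool(np.all(np.abs(a - b) <= tol))
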