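"""Overlapped windowing and feature extraction.

Decisions are made on 200 ms windows advanced every 25 ms (175 ms overlap)
inside the active segments of each trial.  Four feature-set variants are
produced:

* ``EMG_TD`` (32-D): the classic Hudgins time-domain descriptors — mean
  absolute value, zero-crossing count, slope-sign-change count and waveform
  length — for each of the 8 EMG channels, channel-major order;
* ``LOADCELL`` (6-D): per-window mean of the six raw load-cell channels;
* ``TORQUE`` (4-D): per-window mean of the four computed joint torques;
* ``EMG_LC`` (38-D): the EMG_TD and LOADCELL vectors concatenated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .core import TaskClass
from .preprocessing import ActiveSegment, JointTorqueSeries
from .synthetic import TrialRecording


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry in milliseconds."""

    window_ms: float = 200.0
    increment_ms: float = 25.0

    def __post_init__(self):
        if self.window_ms <= 0 or self.increment_ms <= 0:
            raise ValueError("window and increment must be positive")
        if self.increment_ms > self.window_ms:
            raise ValueError("increment must not exceed window")

    @property
    def overlap_ms(self) -> float:
        return self.window_ms - self.increment_ms

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms / 1000.0 * fs))

    def increment_samples(self, fs: float) -> int:
        return int(round(self.increment_ms / 1000.0 * fs))


class FeatureSet(enum.Enum):
    EMG_TD = "emg_td"
    LOADCELL = "loadcell"
    TORQUE = "torque"
    EMG_LC = "emg_lc"


FEATURE_DIMS = {FeatureSet.EMG_TD: 32, FeatureSet.LOADCELL: 6,
                FeatureSet.TORQUE: 4, FeatureSet.EMG_LC: 38}

_TD_NAMES = ("mav", "zc", "ssc", "wl")
_LC_NAMES = ("fx", "fy", "fz", "mx", "my", "mz")
_TQ_NAMES = ("ab_ad", "hab_had", "er_ir", "ef_ee")


def feature_names(feature_set: FeatureSet) -> list[str]:
    if feature_set is FeatureSet.EMG_TD:
        return [f"emg{ch + 1}_{f}" for ch in range(8) for f in _TD_NAMES]
    if feature_set is FeatureSet.LOADCELL:
        return [f"lc_{c}" for c in _LC_NAMES]
    if feature_set is FeatureSet.TORQUE:
        return [f"tq_{c}" for c in _TQ_NAMES]
    return feature_names(FeatureSet.EMG_TD) + feature_names(FeatureSet.LOADCELL)


@dataclass
class FeatureMatrix:
    """Windows x features table with class labels and trial provenance."""

    values: np.ndarray          # (n_windows, D)
    labels: list                # TaskClass per window
    trial_ids: list             # opaque per-window trial identifier
    feature_set: FeatureSet
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, FEATURE_DIMS[self.feature_set])
        if self.values.shape[1] != FEATURE_DIMS[self.feature_set]:
            raise ValueError(
                f"{self.feature_set.name} features must have "
                f"{FEATURE_DIMS[self.feature_set]} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        if len(self.labels) != self.values.shape[0] or \
                len(self.trial_ids) != self.values.shape[0]:
            raise ValueError("labels/trial_ids length mismatch")
        if not self.feature_names:
            self.feature_names = feature_names(self.feature_set)

    def __len__(self) -> int:
        return self.values.shape[0]

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        fs = parts[0].feature_set
        if any(p.feature_set is not fs for p in parts):
            raise ValueError("mixed feature sets")
        return FeatureMatrix(
            values=np.vstack([p.values for p in parts]),
            labels=[l for p in parts for l in p.labels],
            trial_ids=[t for p in parts for t in p.trial_ids],
            feature_set=fs)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def window_starts(segment_length: int, window: int, increment: int) -> list[int]:
    """Start indices 0, increment, 2*increment, ... of full windows fitting
    in a segment; empty when the segment is shorter than one window."""
    if window <= 0 or increment <= 0:
        raise ValueError("window and increment must be positive")
    if segment_length < window:
        return []
    return list(range(0, segment_length - window + 1, increment))


# ---------------------------------------------------------------------------
# Hudgins time-domain features
# ---------------------------------------------------------------------------

def mav(x: np.ndarray) -> float:
    """Mean absolute value."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def _sign(x: np.ndarray) -> np.ndarray:
    # sign(0) treated as positive: zeros never create crossings on their own
    return np.where(np.asarray(x) >= 0, 1, -1)


def zero_crossings(x: np.ndarray, deadband: float = 0.0) -> int:
    """Count of sign changes between consecutive samples whose amplitude step
    is at least ``deadband`` (suppresses noise-floor chatter)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    s = _sign(x)
    flips = s[:-1] != s[1:]
    big = np.abs(np.diff(x)) >= deadband
    return int(np.count_nonzero(flips & big))


def slope_sign_changes(x: np.ndarray, deadband: float = 0.0) -> int:
    """Count of interior samples where the slope changes sign and at least
    one of the two adjacent differences has magnitude >= ``deadband``."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("window must have at least 3 samples")
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    d = np.diff(x)
    s = _sign(d)
    flips = s[:-1] != s[1:]
    big = (np.abs(d[:-1]) >= deadband) | (np.abs(d[1:]) >= deadband)
    return int(np.count_nonzero(flips & big))


def waveform_length(x: np.ndarray) -> float:
    """Cumulative absolute first difference (path length of the waveform)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def hudgins_features(window: np.ndarray, deadband: float = 0.0) -> np.ndarray:
    """[MAV, ZC, SSC, WL] for each channel of a (window, channels) block,
    channel-major order (ch1 features, ch2 features, ...)."""
    w = np.atleast_2d(np.asarray(window, dtype=float))
    if w.shape[0] < 3:
        raise ValueError("window too short for Hudgins features")
    out = np.empty(4 * w.shape[1])
    for ch in range(w.shape[1]):
        x = w[:, ch]
        out[4 * ch:4 * ch + 4] = (mav(x), zero_crossings(x, deadband),
                                  slope_sign_changes(x, deadband),
                                  waveform_length(x))
    return out


# ---------------------------------------------------------------------------
# per-trial extraction
# ---------------------------------------------------------------------------

def extract_features(trial: TrialRecording, segment: ActiveSegment,
                     torques: JointTorqueSeries, spec: WindowSpec,
                     feature_set: FeatureSet, *, emg: np.ndarray | None = None,
                     deadband: float = 0.0,
                     trial_id=None) -> FeatureMatrix:
    """Feature rows for every analysis window of one trial.

    Windows are formed independently inside each contiguous active run (they
    never span a gap); partial trailing windows are dropped.  ``emg``
    overrides the trial's raw EMG with a filtered version — the pipeline
    passes notch-filtered EMG here.  An empty segment yields a valid 0-row
    matrix.
    """
    emg_data = trial.emg if emg is None else np.asarray(emg, dtype=float)
    if emg_data.shape != trial.emg.shape:
        raise ValueError("filtered EMG shape must match the trial")
    win = spec.window_samples(trial.fs)
    inc = spec.increment_samples(trial.fs)
    tid = trial_id if trial_id is not None else \
        f"{trial.participant_id}/{trial.task.code}/{trial.acquisition_index}"

    rows = []
    for start, end in segment.ranges:
        for s in window_starts(end - start, win, inc):
            a, b = start + s, start + s + win
            if feature_set is FeatureSet.EMG_TD:
                rows.append(hudgins_features(emg_data[a:b], deadband))
            elif feature_set is FeatureSet.LOADCELL:
                rows.append(trial.loadcell[a:b].mean(axis=0))
            elif feature_set is FeatureSet.TORQUE:
                rows.append(torques.torque[a:b].mean(axis=0))
            else:  # EMG_LC
                rows.append(np.concatenate([
                    hudgins_features(emg_data[a:b], deadband),
                    trial.loadcell[a:b].mean(axis=0)]))
    values = np.array(rows) if rows else \
        np.empty((0, FEATURE_DIMS[feature_set]))
    n = len(rows)
    return FeatureMatrix(values=values, labels=[trial.task] * n,
                         trial_ids=[tid] * n, feature_set=feature_set)
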