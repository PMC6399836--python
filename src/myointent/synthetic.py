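"""Synthetic generator for isometric shoulder/elbow torque trials.

Produces labeled 5 s trials (1 kHz) of 8-channel surface EMG and 6-channel
load-cell data with the statistical structure the downstream analysis
assumes, so the whole pipeline runs without access to laboratory recordings:

* a ramp-hold-release torque envelope scaled by a class-specific 4-DOF
  torque-direction vector (N*m at plateau), with per-trial amplitude and
  strategy jitter;
* load-cell channels obtained by inverting the rigid-body transform used in
  preprocessing, so :func:`~myointent.preprocessing.compute_joint_torques`
  recovers the latent torques up to the injected noise;
* EMG channels as amplitude-modulated band-limited (20-450 Hz) Gaussian
  noise — the standard surrogate for interference-pattern surface EMG — with
  class-specific per-muscle activation gains, plus additive 60 Hz power-line
  interference;
* a ``synergy_coupling`` knob in [0, 1] that mixes the AB<->ER and AD<->IR
  class profiles (both torque directions and muscle activations), emulating
  the abnormal flexion/extension synergy coupling seen after stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import CLASS_ORDER, MUSCLE_NAMES, TaskClass
from .preprocessing import RigidBodyGeometry, default_geometry

# Class-mean plateau torques, N*m, rows in CLASS_ORDER (EF, AB, ER, HAB, EE,
# AD, IR, HAD), columns (AB/AD, HAB/HAD, ER/IR, EF/EE).  Magnitudes are
# typical moderate-impairment maximal isometric values; small secondary
# torques echo the synergy grouping.  Each row is diagonally dominant in its
# primary axis.
DEFAULT_TORQUE_DIRECTIONS = np.array([
    #  AB/AD  HAB/HAD  ER/IR   EF/EE
    [3.0,    1.0,     1.0,    30.0],   # EF
    [25.0,   3.0,     2.0,     4.0],   # AB
    [2.0,    1.0,    12.0,     2.0],   # ER
    [3.0,   20.0,     2.0,     2.0],   # HAB
    [-2.0,  -1.0,    -1.0,   -25.0],   # EE
    [-30.0, -3.0,    -2.0,    -4.0],   # AD
    [-2.0,  -1.0,   -15.0,    -3.0],   # IR
    [-3.0, -22.0,    -2.0,    -2.0],   # HAD
])

# Muscle activation gains (dimensionless, scale EMG standard deviation in mV
# at full envelope), rows in CLASS_ORDER, columns in MUSCLE_NAMES order
# (AntDelt, MidDelt, PostDelt, PecMajor, Biceps, TriLong, TriLat, Brachiorad).
# Rotation classes activate the recorded superficial muscles only weakly and
# share them with ab/adduction, reflecting that rotator-cuff muscles were not
# instrumented.
DEFAULT_ACTIVATIONS = np.array([
    # AntD  MidD  PostD  Pec   Bic   TriLo TriLa BR
    [0.08, 0.04, 0.02, 0.03, 0.35, 0.02, 0.02, 0.30],   # EF
    [0.20, 0.35, 0.10, 0.03, 0.10, 0.03, 0.02, 0.04],   # AB
    [0.10, 0.12, 0.22, 0.04, 0.06, 0.03, 0.02, 0.03],   # ER
    [0.08, 0.20, 0.32, 0.02, 0.04, 0.06, 0.04, 0.02],   # HAB
    [0.03, 0.03, 0.06, 0.04, 0.02, 0.30, 0.28, 0.04],   # EE
    [0.06, 0.03, 0.03, 0.30, 0.04, 0.12, 0.08, 0.03],   # AD
    [0.14, 0.04, 0.03, 0.26, 0.06, 0.04, 0.04, 0.04],   # IR
    [0.25, 0.06, 0.02, 0.32, 0.08, 0.03, 0.03, 0.03],   # HAD
])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the recorded protocol: 5 s trials at 1 kHz, eight
    directions, 3-6 trials per direction, maximal-effort ramp-hold-release
    torque profiles, and per-trial variability so that the three-trial
    retention rule and trial-wise cross-validation are non-degenerate.
    """

    n_participants: int = 10
    trials_per_class: int = 4
    fs: float = 1000.0
    trial_duration: float = 5.0
    torque_direction_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TORQUE_DIRECTIONS.copy())
    activation_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_ACTIVATIONS.copy())
    emg_noise_floor: float = 0.01          # mV, resting-baseline EMG sd
    powerline_amplitude: float = 0.02      # mV, 60 Hz interference amplitude
    powerline_freq: float = 60.0
    synergy_coupling: float = 0.5          # 0 = independent, 1 = fully merged
    envelope_ramp: float = 1.0             # s
    envelope_hold: float = 2.5             # s
    torque_noise_sd: float = 0.8           # N*m, broadband sample noise
    amplitude_jitter: float = 0.05         # +/- fraction, per-trial plateau
    direction_jitter_rel: float = 0.15     # per-trial relative strategy noise
    direction_jitter_abs: float = 1.2      # N*m, per-trial additive strategy noise
    activation_jitter: float = 0.15        # per-trial lognormal sd of EMG gains
    geometry: RigidBodyGeometry = field(default_factory=default_geometry)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "torque_direction_matrix",
                           np.asarray(self.torque_direction_matrix, dtype=float))
        object.__setattr__(self, "activation_matrix",
                           np.asarray(self.activation_matrix, dtype=float))
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 3 <= self.trials_per_class <= 6:
            raise ValueError("trials_per_class must be in [3, 6]")
        if self.fs <= 0 or self.trial_duration <= 0:
            raise ValueError("fs and trial_duration must be positive")
        if self.torque_direction_matrix.shape != (8, 4):
            raise ValueError("torque_direction_matrix must be 8x4")
        if self.activation_matrix.shape != (8, 8):
            raise ValueError("activation_matrix must be 8x8")
        if np.any(self.activation_matrix < 0):
            raise ValueError("activation gains must be >= 0")
        if not 0.0 <= self.synergy_coupling <= 1.0:
            raise ValueError("synergy_coupling must be in [0, 1]")
        for i, task in enumerate(CLASS_ORDER):
            row = self.torque_direction_matrix[i]
            if np.argmax(np.abs(row)) != task.primary_axis:
                raise ValueError(
                    f"torque_direction_matrix row for {task.code} is not "
                    "diagonally dominant in its primary axis")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))


@dataclass
class TrialRecording:
    """One labeled 5 s trial: 8-channel EMG plus 6-channel load-cell data."""

    participant_id: str
    task: TaskClass
    fs: float
    emg: np.ndarray        # (n_samples, 8), mV
    loadcell: np.ndarray   # (n_samples, 6): Fx,Fy,Fz (N), Mx,My,Mz (N*m)
    acquisition_index: int = 0
    clinical_scores: Optional[dict] = None

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.loadcell = np.asarray(self.loadcell, dtype=float)
        if self.emg.ndim != 2 or self.emg.shape[1] != 8:
            raise ValueError("emg must have shape (n_samples, 8)")
        if self.loadcell.ndim != 2 or self.loadcell.shape[1] != 6:
            raise ValueError("loadcell must have shape (n_samples, 6)")
        if self.emg.shape[0] != self.loadcell.shape[0]:
            raise ValueError("emg and loadcell lengths differ")
        if not (np.all(np.isfinite(self.emg)) and np.all(np.isfinite(self.loadcell))):
            raise ValueError("non-finite values in recording")


# ---------------------------------------------------------------------------
# envelope and coupling
# ---------------------------------------------------------------------------

def torque_envelope(duration: float, fs: float, ramp: float,
                    hold: float) -> np.ndarray:
    """Unit-amplitude ramp-hold-release effort envelope.

    Rises linearly from 0 over ``ramp`` seconds, holds at exactly 1 for
    ``hold`` seconds, falls back to 0 over ``ramp`` seconds, and stays at 0
    for the remainder of the trial.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if ramp < 0 or hold < 0:
        raise ValueError("ramp and hold must be non-negative")
    if 2 * ramp + hold > duration + 1e-12:
        raise ValueError("2*ramp + hold exceeds trial duration")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if ramp == 0:
        env = np.where(t < hold, 1.0, 0.0) if hold < duration else np.ones(n)
        return env
    env = np.interp(t, [0.0, ramp, ramp + hold, 2 * ramp + hold],
                    [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
    return env


def apply_synergy_coupling(config: GeneratorConfig
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Mix the AB<->ER and AD<->IR class profiles by the coupling strength.

    With coupling c, each row of the pair becomes
    ``(1 - c/2)*own + (c/2)*partner``: c = 0 leaves the profiles independent,
    c = 1 makes the paired rows identical (both equal to their mean).
    Applied to both the torque-direction matrix and the activation matrix;
    returns new arrays, inputs unmodified.
    """
    c = config.synergy_coupling
    if not 0.0 <= c <= 1.0:
        raise ValueError("synergy_coupling must be in [0, 1]")
    idx = {task: i for i, task in enumerate(CLASS_ORDER)}
    pairs = [(TaskClass.AB, TaskClass.ER), (TaskClass.AD, TaskClass.IR)]
    out = []
    for mat in (config.torque_direction_matrix, config.activation_matrix):
        mixed = mat.copy()
        for a, b in pairs:
            ia, ib = idx[a], idx[b]
            mixed[ia] = (1 - c / 2) * mat[ia] + (c / 2) * mat[ib]
            mixed[ib] = (1 - c / 2) * mat[ib] + (c / 2) * mat[ia]
        out.append(mixed)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def loadcell_from_torques(torque: np.ndarray,
                          geometry: RigidBodyGeometry) -> np.ndarray:
    """Synthesize 6-channel load-cell data reproducing the given 4-DOF
    joint-torque series.

    Uses the minimum-norm wrench: with A the 4x6 torque map of the geometry,
    the load-cell series is ``pinv(A) @ torque`` per sample, so
    :func:`~myointent.preprocessing.compute_joint_torques` recovers the
    input exactly (A has full row rank for any valid geometry whose shoulder
    and elbow lever arms differ).
    """
    torque = np.atleast_2d(np.asarray(torque, dtype=float))
    A = geometry.torque_map()
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("geometry torque map is rank deficient; "
                         "shoulder and elbow lever arms must differ")
    return torque @ np.linalg.pinv(A).T


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float] = (20.0, 450.0)) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the EMG hardware band."""
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# trial and dataset generation
# ---------------------------------------------------------------------------

def generate_trial(config: GeneratorConfig, task: TaskClass,
                   participant_id: str, rng: np.random.Generator,
                   acquisition_index: int = 0,
                   clinical_scores: Optional[dict] = None) -> TrialRecording:
    """Generate one labeled trial for ``task``.

    The latent 4-DOF torque is ``envelope x (coupled direction row, jittered
    per trial) + N(0, torque_noise_sd)``; load-cell channels invert the
    rigid-body transform so the preprocessing stage recovers the latent
    torques.  Each EMG channel is band-limited Gaussian noise whose standard
    deviation tracks ``noise_floor + gain x envelope``, plus the power-line
    sinusoid.  Fully reproducible for a given rng state.
    """
    n = config.n_samples
    env = torque_envelope(config.trial_duration, config.fs,
                          config.envelope_ramp, config.envelope_hold)
    directions, activations = apply_synergy_coupling(config)
    row_idx = CLASS_ORDER.index(task)
    direction = directions[row_idx].copy()
    gains = activations[row_idx].copy()

    # per-trial effort and strategy variability
    amp = 1.0 + rng.uniform(-config.amplitude_jitter, config.amplitude_jitter)
    direction = direction * (1.0 + config.direction_jitter_rel * rng.standard_normal(4))
    direction = direction + config.direction_jitter_abs * rng.standard_normal(4)
    gains = gains * np.exp(config.activation_jitter * rng.standard_normal(8))

    latent = env[:, None] * (amp * direction)[None, :]
    if config.torque_noise_sd > 0:
        latent = latent + config.torque_noise_sd * rng.standard_normal((n, 4))
    loadcell = loadcell_from_torques(latent, config.geometry)

    t = np.arange(n) / config.fs
    powerline = config.powerline_amplitude * np.sin(
        2 * np.pi * config.powerline_freq * t)
    emg = np.empty((n, 8))
    for ch in range(8):
        sd = config.emg_noise_floor + gains[ch] * env
        if np.all(sd == 0):
            emg[:, ch] = powerline
        else:
            emg[:, ch] = sd * _bandlimited_noise(rng, n, config.fs) + powerline
    return TrialRecording(participant_id=participant_id, task=task,
                          fs=config.fs, emg=emg, loadcell=loadcell,
                          acquisition_index=acquisition_index,
                          clinical_scores=clinical_scores)


def sample_clinical_scores(rng: np.random.Generator) -> dict:
    """Per-participant clinical scores: UE-FMA uniform integer on the study's
    moderate-to-severe inclusion range [10, 45], reach fraction uniform on
    [0, 1].  Intentionally uncorrelated with any generated signal property."""
    return {"ue_fma": int(rng.integers(10, 46)),
            "reach_fraction": float(rng.uniform(0.0, 1.0))}


def generate_dataset(config: GeneratorConfig) -> list[TrialRecording]:
    """Generate the full cohort: ``n_participants x 8 classes x
    trials_per_class`` trials, deterministic under ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    participant_seeds = root.spawn(config.n_participants)
    trials: list[TrialRecording] = []
    for p, pseed in enumerate(participant_seeds):
        pid = f"P{p + 1:02d}"
        prng = np.random.Generator(np.random.PCG64(pseed))
        scores = sample_clinical_scores(prng)
        for task in CLASS_ORDER:
            for k in range(config.trials_per_class):
                trials.append(generate_trial(
                    config, task, pid, prng,
                    acquisition_index=k, clinical_scores=scores))
    return trials


def with_coupling(config: GeneratorConfig, coupling: float) -> GeneratorConfig:
    """Copy of ``config`` at a different synergy-coupling strength."""
    return replace(config, synergy_coupling=coupling)
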