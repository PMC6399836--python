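"""Signal conditioning and joint-torque computation.

Offline preprocessing of one recorded trial:

* zero-phase Butterworth notch filtering of power-line interference and its
  harmonics from the EMG channels;
* rigid-body conversion of the six load-cell channels (three forces, three
  moments measured at the transducer) into the four anatomical joint-torque
  DOFs (shoulder ab/adduction, horizontal ab/adduction, external/internal
  rotation, elbow flexion/extension);
* maximum voluntary torque (MVT) via a 200 ms moving average;
* retention of the three strongest trials per direction;
* segmentation of the trial to the samples where the primary-direction torque
  exceeds 20 % of the direction's MVT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg as _burg

from .core import DOF_NAMES, TaskClass

_ORTHO_TOL = 1e-10


# ---------------------------------------------------------------------------
# geometry and torque types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidBodyGeometry:
    """Rigid-body relation between the load cell and the limb.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix mapping load-cell frame vectors into the
        anatomical frame.
    lever_arm_shoulder, lever_arm_elbow
        Vectors (m, load-cell frame) from the load-cell origin to the
        glenohumeral and elbow joint centers.  The moment of the measured
        wrench about each joint center is ``rotation @ (M + r x F)``.
    axis_map
        For each of the four torque DOFs (keyed by :data:`DOF_NAMES` entries)
        a ``(joint, component, sign)`` triple selecting which anatomical
        moment component carries that DOF: joint is ``"shoulder"`` or
        ``"elbow"``, component indexes the 3-vector, sign is +/-1.
    """

    rotation: np.ndarray
    lever_arm_shoulder: np.ndarray
    lever_arm_elbow: np.ndarray
    axis_map: dict = field(default_factory=lambda: {
        "ab_ad": ("shoulder", 0, +1),
        "hab_had": ("shoulder", 1, +1),
        "er_ir": ("shoulder", 2, +1),
        "ef_ee": ("elbow", 1, +1),
    })

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "lever_arm_shoulder",
                           np.asarray(self.lever_arm_shoulder, dtype=float))
        object.__setattr__(self, "lever_arm_elbow",
                           np.asarray(self.lever_arm_elbow, dtype=float))
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")
        if set(self.axis_map) != set(DOF_NAMES):
            raise ValueError(f"axis_map must cover exactly {DOF_NAMES}")
        for dof, (joint, comp, sign) in self.axis_map.items():
            if joint not in ("shoulder", "elbow") or comp not in (0, 1, 2) \
                    or sign not in (+1, -1):
                raise ValueError(f"invalid axis_map entry for {dof}")

    def lever_arm(self, joint: str) -> np.ndarray:
        return self.lever_arm_shoulder if joint == "shoulder" else self.lever_arm_elbow

    def torque_map(self) -> np.ndarray:
        """4x6 matrix A with ``torque = A @ [Fx,Fy,Fz,Mx,My,Mz]``.

        Row order follows :data:`DOF_NAMES`.  Used both to compute joint
        torques and (via its pseudoinverse) to synthesize load-cell data from
        latent torques.
        """
        A = np.zeros((4, 6))
        for i, dof in enumerate(DOF_NAMES):
            joint, comp, sign = self.axis_map[dof]
            r = self.lever_arm(joint)
            rx = np.array([[0, -r[2], r[1]],
                           [r[2], 0, -r[0]],
                           [-r[1], r[0], 0]])
            A[i, :3] = sign * (self.rotation[comp, :] @ rx)
            A[i, 3:] = sign * self.rotation[comp, :]
        return A


def default_geometry() -> RigidBodyGeometry:
    """Nominal test-rig geometry: load cell midway along the casted forearm,
    shoulder and elbow joint centers offset along the load-cell x axis."""
    return RigidBodyGeometry(
        rotation=np.eye(3),
        lever_arm_shoulder=np.array([-0.30, 0.0, 0.05]),
        lever_arm_elbow=np.array([0.15, 0.0, 0.0]),
    )


@dataclass
class JointTorqueSeries:
    """4-channel joint-torque time series (N*m), channels ordered AB/AD,
    HAB/HAD, ER/IR, EF/EE; positive = AB, HAB, ER, EF."""

    fs: float
    torque: np.ndarray  # shape (n_samples, 4)

    def __post_init__(self):
        self.torque = np.asarray(self.torque, dtype=float)
        if self.torque.ndim != 2 or self.torque.shape[1] != 4:
            raise ValueError("torque must have shape (n_samples, 4)")
        if not np.all(np.isfinite(self.torque)):
            raise ValueError("torque contains non-finite values")

    def primary(self, task: TaskClass) -> np.ndarray:
        """Primary-direction torque for ``task``, rectified toward the tested
        direction (positive when torque is produced in that direction)."""
        return task.primary_sign * self.torque[:, task.primary_axis]

    def __len__(self) -> int:
        return self.torque.shape[0]


@dataclass
class ActiveSegment:
    """Half-open sample ranges [start, end) where the primary torque exceeds
    the segmentation threshold."""

    ranges: list  # list[tuple[int, int]]
    n_samples: int

    def __post_init__(self):
        prev_end = 0
        for start, end in self.ranges:
            if not (0 <= start < end <= self.n_samples):
                raise ValueError(f"range [{start}, {end}) out of bounds")
            if start < prev_end:
                raise ValueError("ranges must be sorted and disjoint")
            prev_end = end

    @property
    def total_samples(self) -> int:
        return sum(end - start for start, end in self.ranges)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _stabilized_ar(seg: np.ndarray, order: int, shrink: float = 0.999
                   ) -> np.ndarray | None:
    """Burg AR coefficients with poles reflected into (and shrunk inside)
    the unit circle so extrapolation cannot diverge.  None for a constant
    segment (continue the constant instead)."""
    if np.ptp(seg) == 0:
        return None
    rho, _ = _burg(seg - seg.mean(), order=order)
    z = np.roots(np.concatenate([[1.0], -rho]))
    z = np.where(np.abs(z) > 1.0, 1.0 / np.conj(z), z) * shrink
    return -np.real(np.poly(z))[1:]


def _ar_extend(x: np.ndarray, npad: int, order: int = 8,
               fit_len: int = 1000) -> np.ndarray:
    """Extend a 1-D series at both ends by autoregressive (maximum-entropy)
    extrapolation.

    Unlike mirror padding, an AR extension continues narrow-band components
    (notably the power-line tone) coherently, so the zero-phase notch below
    shows no edge transient where the extension meets the data.
    """
    fit = min(fit_len, x.size)

    def extend(seg: np.ndarray) -> np.ndarray:
        rho = _stabilized_ar(seg, min(order, seg.size // 3))
        if rho is None:
            return np.full(npad, float(seg[-1]))
        p = rho.size
        mu = seg.mean()
        buf = list(seg[-p:] - mu)
        for _ in range(npad):
            buf.append(float(np.dot(rho, buf[-1:-p - 1:-1])))
        return np.asarray(buf[p:]) + mu

    return np.concatenate([extend(x[:fit][::-1])[::-1], x, extend(x[-fit:])])


def notch_filter(x: np.ndarray, fs: float, fundamental: float = 60.0,
                 half_width: float = 2.0, order: int = 6,
                 max_harmonic: float = 450.0) -> np.ndarray:
    """Remove power-line interference and its harmonics, zero phase.

    A Butterworth band-stop of the given order is applied forward-backward
    at [k*fundamental - half_width, k*fundamental + half_width] for every
    harmonic k whose upper band edge stays below both ``max_harmonic`` (the
    hardware band edge) and the Nyquist frequency.  The signal is first
    extended ~1 s at each end by AR extrapolation so the narrow stop bands
    (which ring for ~1/half_width seconds) leave no edge transients.
    Operates along the last axis; output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if order % 2:
        raise ValueError("band-stop order must be even")
    nyq = fs / 2.0
    bands = []
    k = 1
    while k * fundamental + half_width < min(max_harmonic, nyq):
        bands.append((k * fundamental - half_width, k * fundamental + half_width))
        k += 1
    if not bands:
        return x.copy()
    if x.shape[-1] < 6 * order:
        raise ValueError(f"series too short for stable filtering (< {6 * order})")
    npad = min(int(round(fs)), x.shape[-1])
    one_d = x.ndim == 1
    rows = x[None, :] if one_d else x.reshape(-1, x.shape[-1])
    ext = np.stack([_ar_extend(row, npad) for row in rows])
    padlen = min(ext.shape[-1] - 1, int(round(fs / half_width)))
    for lo, hi in bands:
        sos = sps.butter(order // 2, [lo / nyq, hi / nyq], btype="bandstop",
                         output="sos")
        ext = sps.sosfiltfilt(sos, ext, axis=-1, padlen=padlen)
    y = ext[:, npad:-npad]
    return y[0] if one_d else y.reshape(x.shape)


def compute_joint_torques(loadcell: np.ndarray,
                          geometry: RigidBodyGeometry,
                          fs: float) -> JointTorqueSeries:
    """Convert 6-channel load-cell data to the 4-DOF joint-torque series.

    Per sample the wrench measured at the transducer (forces Fx,Fy,Fz in N,
    moments Mx,My,Mz in N*m, load-cell frame) is translated to each joint
    center and rotated into the anatomical frame:
    ``m_joint = R @ (M + r_joint x F)``.  The four torque DOFs are read from
    the components selected by ``geometry.axis_map`` with their signs.
    """
    lc = np.asarray(loadcell, dtype=float)
    if lc.ndim != 2 or lc.shape[1] != 6:
        raise ValueError("loadcell must have shape (n_samples, 6)")
    torque = lc @ geometry.torque_map().T
    return JointTorqueSeries(fs=fs, torque=torque)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average; output[i] averages x[i-window+1 .. i].
    Length = len(x) - window + 1 (first full window onward)."""
    c = np.cumsum(np.insert(np.asarray(x, dtype=float), 0, 0.0))
    return (c[window:] - c[:-window]) / window


def max_voluntary_torque(torque: np.ndarray, fs: float,
                         window_ms: float = 200.0) -> tuple[float, int]:
    """Maximum of the trailing moving average of a 1-D torque series.

    Returns ``(mvt, index)`` where ``index`` is the sample index of the end
    of the maximizing window.  The caller supplies torque already rectified
    toward the tested direction (see :meth:`JointTorqueSeries.primary`).
    """
    x = np.asarray(torque, dtype=float)
    window = int(round(window_ms / 1000.0 * fs))
    if window < 1:
        raise ValueError("window shorter than one sample")
    if x.size < window:
        raise ValueError("series shorter than one moving-average window")
    ma = moving_average(x, window)
    i = int(np.argmax(ma))
    return float(ma[i]), i + window - 1


def select_trials(mvts: Sequence[float]) -> tuple[list[int], bool]:
    """Retain the three trials with the largest MVT.

    ``mvts`` is given in acquisition order.  Returns the indices of the three
    retained trials (ties broken by earlier acquisition) and a flag that is
    True iff the experimental stop criterion was met: the top three MVTs are
    within 10 % of each other ((max - min) / max <= 0.10) and the
    chronologically last trial is not the overall maximum.
    """
    mvts = list(map(float, mvts))
    if len(mvts) < 3:
        raise ValueError("need at least 3 trials")
    order = sorted(range(len(mvts)), key=lambda i: (-mvts[i], i))
    top3 = sorted(order[:3])
    top_vals = [mvts[i] for i in top3]
    spread_ok = (max(top_vals) - min(top_vals)) <= 0.10 * max(top_vals)
    # "last trial not the greatest": the final trial must not strictly exceed
    # all earlier ones
    last_not_greatest = not all(mvts[-1] > v for v in mvts[:-1])
    criterion = bool(spread_ok and last_not_greatest)
    return top3, criterion


def segment_active(torques: JointTorqueSeries, task: TaskClass, mvt: float,
                   threshold: float = 0.20) -> ActiveSegment:
    """Samples where the rectified primary torque strictly exceeds
    ``threshold * mvt``, as maximal contiguous runs.

    An empty run list is a valid result (nothing above threshold).  Runs
    shorter than one analysis window are kept here; they simply yield no
    windows downstream.
    """
    if mvt <= 0:
        raise ValueError("mvt must be positive")
    above = torques.primary(task) > threshold * mvt
    n = above.size
    # run boundaries: False->True starts a run, True->False ends it
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    ranges = [(int(s), int(e)) for s, e in zip(run_starts, run_ends)]
    return ActiveSegment(ranges=ranges, n_samples=n)
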