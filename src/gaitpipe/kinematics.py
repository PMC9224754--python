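"""Lower-limb joint angles, gait-cycle normalization, and reference bands.

Joint angles are computed from the relative rotation between the proximal
and distal segment frames, decomposed with the Cardan sequence equivalent
to the joint coordinate system: flexion about the proximal mediolateral
axis first, then ab/adduction, then internal/external rotation (X-Y'-Z'').
Sign conventions are right-sided (flexion/dorsiflexion positive, adduction
positive, internal rotation positive) and mirrored on the left so left and
right curves superimpose.

Curves are time-normalized to 101 samples over the gait cycle (0-100 %,
ipsilateral IC to next ipsilateral IC) with a toe-off percentage marker,
and compared against a reference band (pointwise ensemble mean +/- k x SD
across reference subjects); intervals where an individual's curve exits
the band are flagged as gait deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "JointAngleCurve",
    "NormalizedCycle",
    "ReferenceBand",
    "relative_rotation",
    "cardan_angles",
    "compose_cardan",
    "joint_angle_series",
    "time_normalize",
    "ensemble_stats",
    "deviation_flags",
]

#: proximal segment of each joint
_JOINT_CHAIN = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"),
                "ankle": ("shank", "foot")}
#: sagittal-plane sign so that flexion / dorsiflexion is positive at every
#: joint (the raw Cardan X angle measures knee extension positive)
_SAGITTAL_SIGN = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}
PLANES = ("sagittal", "frontal", "transverse")


@dataclass
class JointAngleCurve:
    """One joint/plane angle series at the native capture rate, degrees."""

    joint: str
    side: str
    plane: str
    angles: np.ndarray
    rate: float
    sign_convention: str = ("flexion+/adduction+/internal+ (right-sided, "
                            "left mirrored)")

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and np.max(np.abs(finite)) >= 180.0:
            raise ValueError("joint angles must satisfy |angle| < 180 deg")


@dataclass
class NormalizedCycle:
    """A curve resampled to 101 points over 0-100 % of the gait cycle."""

    values: np.ndarray          # (101,)
    toe_off_pct: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError("normalized cycle must have 101 samples")
        if not 0.0 < self.toe_off_pct < 100.0:
            raise ValueError("toe-off marker must lie inside (0, 100) %")


@dataclass
class ReferenceBand:
    """Pointwise ensemble mean and SD across reference cycles."""

    mean: np.ndarray            # (101,)
    sd: np.ndarray              # (101,)
    n: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (101,) or self.sd.shape != (101,):
            raise ValueError("reference band must have 101 samples")
        if np.any(self.sd < 0):
            raise ValueError("SD must be non-negative")
        if self.n < 2:
            raise ValueError("a reference band needs at least 2 cycles")


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def relative_rotation(proximal: np.ndarray, distal: np.ndarray) -> np.ndarray:
    """Proximal-frame-to-distal-frame rotation, R_prox^T R_dist.

    Accepts single 3x3/4x4 matrices or stacks of them.
    """
    p = np.asarray(proximal, dtype=float)
    d = np.asarray(distal, dtype=float)
    if p.shape[-2:] == (4, 4):
        p = p[..., :3, :3]
    if d.shape[-2:] == (4, 4):
        d = d[..., :3, :3]
    if p.shape != d.shape or p.shape[-2:] != (3, 3):
        raise ValueError("expected matching 3x3 (or 4x4) rotation inputs")
    if not np.all(np.isfinite(p)) or not np.all(np.isfinite(d)):
        raise ValueError("invalid (non-finite) pose")
    return np.swapaxes(p, -1, -2) @ d


def cardan_angles(rotation: np.ndarray, degrees: bool = True
                  ) -> tuple[np.ndarray, np.ndarray]:
    """X-Y'-Z'' Cardan decomposition of rotation matrices.

    Returns ``(angles, gimbal)`` where ``angles`` has the flexion,
    ab/adduction and axial-rotation components along the last axis, and
    ``gimbal`` flags matrices within 1e-6 of the |middle angle| = 90 deg
    singularity, where the first and third angles are not separable.
    """
    r = np.asarray(rotation, dtype=float)
    single = r.ndim == 2
    rs = r.reshape(-1, 3, 3)
    for i, m in enumerate(rs):
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-6) or np.linalg.det(m) < 0:
            raise ValueError(f"input {i} is not a proper rotation")
    angles = Rotation.from_matrix(rs).as_euler("XYZ", degrees=degrees)
    gimbal = np.abs(np.cos(np.arcsin(np.clip(rs[:, 0, 2], -1, 1)))) < 1e-6
    if single:
        return angles[0], bool(gimbal[0])
    return angles.reshape(r.shape[:-2] + (3,)), gimbal.reshape(r.shape[:-2])


def compose_cardan(flexion: float, abduction: float, rotation: float,
                   degrees: bool = True) -> np.ndarray:
    """Inverse of :func:`cardan_angles` on its principal domain."""
    return Rotation.from_euler(
        "XYZ", [flexion, abduction, rotation], degrees=degrees).as_matrix()


def joint_angle_series(track, joint: str, side: str,
                       mirror_left: bool = True) -> dict[str, JointAngleCurve]:
    """All three planes of one joint from a person track's pose sequences.

    Invalid frames yield NaN angles. Left-side frontal/transverse angles are
    negated so left and right curves share the right-sided convention.
    """
    if joint not in _JOINT_CHAIN:
        raise ValueError(f"unknown joint {joint!r}")
    prox_name, dist_name = _JOINT_CHAIN[joint]
    lo = side.lower()
    prox = track.poses[prox_name if prox_name == "pelvis" else f"{prox_name}_{lo}"]
    dist = track.poses[f"{dist_name}_{lo}"]
    rel = relative_rotation(prox.transforms, dist.transforms)
    angles, _ = cardan_angles(rel)
    angles = np.asarray(angles, dtype=float)
    valid = prox.valid & dist.valid
    angles[~valid] = np.nan
    angles[:, 0] *= _SAGITTAL_SIGN[joint]
    if mirror_left and side.upper() == "L":
        angles = angles * np.array([1.0, -1.0, -1.0])
    return {
        plane: JointAngleCurve(joint=joint, side=side.upper(), plane=plane,
                               angles=angles[:, k], rate=track.rate)
        for k, plane in enumerate(PLANES)
    }


# ---------------------------------------------------------------------------
# Cycle normalization and reference bands
# ---------------------------------------------------------------------------

def time_normalize(curve: np.ndarray, rate: float, ic_time: float,
                   next_ic_time: float, to_time: float,
                   t0: float = 0.0) -> NormalizedCycle:
    """Resample one gait cycle onto 101 evenly spaced cycle points.

    ``curve`` is sampled at ``rate`` starting at session time ``t0``; the
    cycle runs from ``ic_time`` to ``next_ic_time`` with toe off at
    ``to_time`` (ic < to < next_ic). Linear interpolation.
    """
    if not ic_time < to_time < next_ic_time:
        raise ValueError("event ordering must satisfy IC < TO < next IC")
    curve = np.asarray(curve, dtype=float)
    t = t0 + np.arange(curve.size) / rate
    if ic_time < t[0] - 1e-9 or next_ic_time > t[-1] + 1e-9:
        raise ValueError("cycle extends beyond the sampled series")
    pct_times = ic_time + (next_ic_time - ic_time) * np.linspace(0, 1, 101)
    values = np.interp(pct_times, t, curve)
    to_pct = 100.0 * (to_time - ic_time) / (next_ic_time - ic_time)
    return NormalizedCycle(values=values, toe_off_pct=to_pct)


def ensemble_stats(cycles: list[NormalizedCycle]) -> ReferenceBand:
    """Pointwise mean and sample SD across normalized cycles."""
    if len(cycles) < 2:
        raise ValueError("ensemble statistics need at least 2 cycles")
    stack = np.stack([c.values for c in cycles])
    return ReferenceBand(mean=stack.mean(axis=0), sd=stack.std(axis=0, ddof=1),
                         n=len(cycles))


def deviation_flags(cycle: NormalizedCycle, band: ReferenceBand,
                    k_sd: float = 1.0) -> list[tuple[int, int]]:
    """Maximal cycle-percent intervals where the curve exits mean +/- k*SD.

    Returns half-open percent intervals ``(start, stop)`` with
    0 <= start < stop <= 101; an interval covering the whole cycle is
    ``(0, 101)``.
    """
    outside = np.abs(cycle.values - band.mean) > k_sd * band.sd
    flags: list[tuple[int, int]] = []
    start = None
    for i, out in enumerate(outside):
        if out and start is None:
            start = i
        elif not out and start is not None:
            flags.append((start, i))
            start = None
    if start is not None:
        flags.append((start, len(outside)))
    return flags
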