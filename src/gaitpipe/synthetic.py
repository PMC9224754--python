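"""Synthetic dual-instrument gait sessions with full ground truth.

The generator emulates one participant walking repeated passes along a
10 m walkway, recorded simultaneously by a markerless motion-capture (MLMC)
volume at 60 Hz and a pressure-sensitive walkway (PSW) at 100 Hz, so that
every downstream stage (event detection, spatiotemporal parameters,
kinematics, agreement statistics) can be tested against known truth.

Construction, per pass (direction alternates +Y / -Y):

* a periodic step schedule places initial contacts and toe offs from
  cadence, stance fraction, and optional left/right asymmetry factors;
  foot placements follow from speed and the step-length split, so the
  closed-form identities (stride length = speed x stride time, stance =
  DS1 + single support + DS2) hold exactly on the ground truth;
* the pelvis translates at constant speed with small vertical/lateral
  oscillation; each foot alternates an exactly stationary stance phase and
  a cubic-Hermite swing whose endpoint velocity matches the pelvis speed
  (a C1 monotone interpolant that puts the pelvis-relative heel/toe
  extrema exactly at the events) with sinusoidal vertical clearance;
* thigh and shank poses come from a two-link inverse-kinematics chain
  between the pelvis hip centres and the ankles, yielding periodic,
  plausible joint-angle curves;
* poses are flagged invalid within the capture margin of the walkway ends,
  where the biomechanical model is not yet fully identified;
* PSW footprints are emitted at contact onset = true IC + contact_latency
  and offset = true TO - contact_latency (emulating the pressure
  threshold), jittered, quantized to the PSW sample grid, and flagged
  incomplete when not entirely within the instrumented span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .events import GaitEvent
from .io import (
    HEEL_OFFSET_M,
    TOE_OFFSET_M,
    FootprintRecord,
    MarkerlessRecording,
    PersonTrack,
    PoseSeries,
    WalkwayFrame,
)
from .spatiotemporal import SpatioTemporalRow, StrideRecord, stride_parameters

__all__ = ["SyntheticSession", "generate_session", "add_extra_tracks",
           "generate_cohort"]

PARTICIPANT_ID = "participant"

_ANKLE_HEIGHT = 0.08      # m, ankle joint centre above ground in stance
_CLEARANCE = 0.05         # m, peak swing foot clearance
_PELVIS_HEIGHT = 0.85     # m, mean pelvis origin height
_PELVIS_BOB = 0.015       # m, vertical oscillation amplitude
_PELVIS_SWAY = 0.02       # m, lateral oscillation amplitude
_HIP_OFFSET = np.array([0.09, 0.0, -0.05])   # hip centre in pelvis frame (left)
_THIGH_LEN = 0.44
_SHANK_LEN = 0.44
_LEAD_IN = 1.5            # m walked outside the volume before entering
_PASS_REST = 3.0          # s between passes

_SIGMA = {"L": 1.0, "R": -1.0}


@dataclass
class SyntheticSession:
    """Paired MLMC-like and PSW-like recordings plus ground truth."""

    config: SimulationConfig
    mlmc: list[MarkerlessRecording]
    psw: list[FootprintRecord]
    truth_events: list[GaitEvent]
    truth_strides: list[StrideRecord]
    truth_parameters: list[SpatioTemporalRow]
    participant_id: str = PARTICIPANT_ID


@dataclass
class _PassPlan:
    """Step schedule of one pass: times, sides and placements."""

    direction: int
    t0: float                 # schedule anchor (pass clock zero)
    sides: list[str]
    ic_times: np.ndarray
    to_times: np.ndarray
    y_place: np.ndarray
    x_place: np.ndarray
    k0: int                   # first recorded frame on the global grid
    n_frames: int


def _plan_pass(config: SimulationConfig, pass_index: int) -> _PassPlan:
    d = 1 if pass_index % 2 == 0 else -1
    T = config.stride_time
    v = config.speed
    sl = config.stride_length
    half = config.walkway_length / 2.0
    stance = config.stance_fraction * T
    wt = dict(zip("LR", config.step_time_weights))
    wl = dict(zip("LR", config.step_length_weights))
    step_time = {s: T * wt[s] for s in "LR"}
    e_l = sl * (wl["L"] - wt["L"]) / 2.0
    e_side = {"L": e_l, "R": -e_l}
    a_head = v * stance / 2.0

    duration = (config.walkway_length + 2 * _LEAD_IN) / v
    t0 = pass_index * (duration + _PASS_REST)
    t0 = round(t0 * config.mlmc_rate) / config.mlmc_rate
    y_start = -d * (half + _LEAD_IN)

    def pelvis_y(t):
        return y_start + d * v * (t - t0)

    t_exit = t0 + duration
    sides: list[str] = []
    ic_times: list[float] = []
    t = t0 - 2.0 * T
    side = "L"
    while t < t_exit + 2.0 * T:
        sides.append(side)
        ic_times.append(t)
        side = "R" if side == "L" else "L"
        t = t + step_time[side]
    ic = np.array(ic_times)
    y_place = pelvis_y(ic) + d * (a_head + np.array([e_side[s] for s in sides]))
    x_place = np.array([d * _SIGMA[s] * config.stride_width / 2.0 for s in sides])

    t_enter = t0 + _LEAD_IN / v
    t_leave = t_enter + config.walkway_length / v
    k0 = int(np.ceil(t_enter * config.mlmc_rate - 1e-9))
    k1 = int(np.floor(t_leave * config.mlmc_rate + 1e-9))
    return _PassPlan(
        direction=d, t0=t0, sides=sides, ic_times=ic,
        to_times=ic + stance, y_place=y_place, x_place=x_place,
        k0=k0, n_frames=k1 - k0 + 1,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _foot_path(tt: np.ndarray, ics: np.ndarray, tos: np.ndarray,
               ys: np.ndarray, x: float, direction: int, speed: float
               ) -> np.ndarray:
    """Ankle trajectory (n, 3): stationary stance, Hermite swing."""
    n = tt.size
    out = np.empty((n, 3))
    out[:, 0] = x
    j = np.clip(np.searchsorted(ics, tt, side="right") - 1, 0, len(ics) - 1)
    in_stance = (tt <= tos[j]) | (j >= len(ics) - 1)
    out[:, 1] = ys[j]
    out[:, 2] = _ANKLE_HEIGHT
    sw = ~in_stance
    if np.any(sw):
        jj = j[sw]
        dur = ics[jj + 1] - tos[jj]
        tau = (tt[sw] - tos[jj]) / dur
        y0, y1 = ys[jj], ys[jj + 1]
        m = direction * speed * dur  # endpoint slope matched to pelvis speed
        h00 = 2 * tau**3 - 3 * tau**2 + 1
        h10 = tau**3 - 2 * tau**2 + tau
        h01 = -2 * tau**3 + 3 * tau**2
        h11 = tau**3 - tau**2
        out[sw, 1] = h00 * y0 + h10 * m + h01 * y1 + h11 * m
        out[sw, 2] = _ANKLE_HEIGHT + _CLEARANCE * np.sin(np.pi * tau)
    return out


def _heading(direction: int) -> np.ndarray:
    if direction == 1:
        return np.eye(3)
    return np.diag([-1.0, -1.0, 1.0])  # 180 deg about Z


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n < 1e-12, 1.0, n)


def _orient(z_axis: np.ndarray, lateral: np.ndarray) -> np.ndarray:
    """Rotation matrices (n, 3, 3) with given Z (long axis) and lateral X."""
    z = _normalize(z_axis)
    y = _normalize(np.cross(z, lateral))
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def _two_link_knee(hip: np.ndarray, ankle: np.ndarray, forward: np.ndarray
                   ) -> np.ndarray:
    """Knee centre via planar two-link IK; knee displaced toward `forward`."""
    u = ankle - hip
    dist = np.linalg.norm(u, axis=-1, keepdims=True)
    u = u / np.where(dist < 1e-12, 1.0, dist)
    a = (dist**2 + _THIGH_LEN**2 - _SHANK_LEN**2) / (2.0 * dist)
    h = np.sqrt(np.clip(_THIGH_LEN**2 - a**2, 0.0, None))
    w = forward - np.sum(forward * u, axis=-1, keepdims=True) * u
    w = _normalize(w)
    return hip + a * u + h * w


def _make_transforms(rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    n = trans.shape[0]
    t = np.tile(np.eye(4), (n, 1, 1))
    t[:, :3, :3] = rot
    t[:, :3, 3] = trans
    return t


def _build_pass_track(config: SimulationConfig, plan: _PassPlan,
                      rng: np.random.Generator
                      ) -> tuple[PersonTrack, np.ndarray]:
    rate = config.mlmc_rate
    n = plan.n_frames
    d = plan.direction
    tt = (plan.k0 + np.arange(n)) / rate
    T = config.stride_time
    phase = (tt - plan.t0) / T

    pelvis = np.column_stack([
        _PELVIS_SWAY * np.sin(2 * np.pi * phase),
        (-d * (config.walkway_length / 2.0 + _LEAD_IN)
         + d * config.speed * (tt - plan.t0)),
        _PELVIS_HEIGHT + _PELVIS_BOB * np.cos(4 * np.pi * phase),
    ])
    r_head = _heading(d)
    rot_head = np.broadcast_to(r_head, (n, 3, 3)).copy()
    forward = np.broadcast_to(d * np.array([0.0, 1.0, 0.0]), (n, 3))
    lateral = np.broadcast_to(r_head[:, 0], (n, 3))

    poses: dict[str, PoseSeries] = {}
    valid = np.abs(pelvis[:, 1]) <= (config.walkway_length / 2.0
                                     - config.capture_margin) + 1e-9

    ankles = {}
    for s in "LR":
        mask = np.array([sd == s for sd in plan.sides])
        ankles[s] = _foot_path(tt, plan.ic_times[mask], plan.to_times[mask],
                               plan.y_place[mask],
                               float(d * _SIGMA[s] * config.stride_width / 2.0),
                               d, config.speed)

    seg_transforms: dict[str, np.ndarray] = {
        "pelvis": _make_transforms(rot_head, pelvis)
    }
    for s in "LR":
        offset = _HIP_OFFSET * np.array([_SIGMA[s], 1.0, 1.0])
        hip = pelvis + (rot_head @ offset)
        ankle = ankles[s]
        knee = _two_link_knee(hip, ankle, forward)
        lo = s.lower()
        seg_transforms[f"thigh_{lo}"] = _make_transforms(_orient(hip - knee, lateral), hip)
        seg_transforms[f"shank_{lo}"] = _make_transforms(_orient(knee - ankle, lateral), knee)
        seg_transforms[f"foot_{lo}"] = _make_transforms(rot_head.copy(), ankle)

    sd = config.noise_sd_position
    for seg, t4 in seg_transforms.items():
        if sd > 0:
            t4 = t4.copy()
            t4[:, :3, 3] += rng.normal(0.0, sd, size=(n, 3))
        poses[seg] = PoseSeries(t4, valid.copy())

    return PersonTrack(PARTICIPANT_ID, rate, poses), tt


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def _truth_for_pass(config: SimulationConfig, plan: _PassPlan, pass_index: int
                    ) -> tuple[list[GaitEvent], list[StrideRecord]]:
    rate = config.mlmc_rate
    t_first = plan.k0 / rate
    t_last = (plan.k0 + plan.n_frames - 1) / rate

    def in_window(t: float) -> bool:
        return t_first - 1e-9 <= t <= t_last + 1e-9

    def ev(kind: str, side: str, t: float) -> GaitEvent:
        frame = int(round(t * rate)) - plan.k0
        return GaitEvent(kind=kind, side=side, time=t, frame=frame,
                         pass_id=pass_index, source="truth")

    events: list[GaitEvent] = []
    for i, side in enumerate(plan.sides):
        for kind, t in (("IC", plan.ic_times[i]), ("TO", plan.to_times[i])):
            if in_window(t):
                events.append(ev(kind, side, float(t)))
    events.sort(key=lambda e: e.time)

    strides: list[StrideRecord] = []
    for i in range(1, len(plan.sides) - 2):
        s = plan.sides[i]
        t_ic = plan.ic_times[i]
        t_to_contra = plan.to_times[i - 1]
        t_ic_contra = plan.ic_times[i + 1]
        t_to = plan.to_times[i]
        t_ic_next = plan.ic_times[i + 2]
        if not all(in_window(t) for t in
                   (t_ic, t_to_contra, t_ic_contra, t_to, t_ic_next)):
            continue
        strides.append(StrideRecord(
            side=s, instrument="truth",
            t_ic=float(t_ic), t_to_contra=float(t_to_contra),
            t_ic_contra=float(t_ic_contra), t_to=float(t_to),
            t_ic_next=float(t_ic_next),
            pos_ic=(float(plan.x_place[i]), float(plan.y_place[i])),
            pos_ic_next=(float(plan.x_place[i + 2]), float(plan.y_place[i + 2])),
            pos_contra=(float(plan.x_place[i + 1]), float(plan.y_place[i + 1])),
        ))
    return events, strides


def _footprints_for_pass(config: SimulationConfig, plan: _PassPlan,
                         rng: np.random.Generator) -> list[FootprintRecord]:
    d = plan.direction
    span_lo, span_hi = -config.psw_span / 2.0, config.psw_span / 2.0
    out: list[FootprintRecord] = []
    q = config.psw_rate
    for i, side in enumerate(plan.sides):
        y = plan.y_place[i]
        x = plan.x_place[i]
        heel_y = y + d * HEEL_OFFSET_M[1]
        toe_y = y + d * TOE_OFFSET_M[1]
        lo, hi = min(heel_y, toe_y), max(heel_y, toe_y)
        if hi < span_lo or lo > span_hi:
            continue  # never touches the instrumented surface
        complete = (span_lo <= lo) and (hi <= span_hi)
        jit_on = rng.normal(0.0, config.noise_sd_time_jitter) \
            if config.noise_sd_time_jitter > 0 else 0.0
        jit_off = rng.normal(0.0, config.noise_sd_time_jitter) \
            if config.noise_sd_time_jitter > 0 else 0.0
        t_on = round((plan.ic_times[i] + config.contact_latency + jit_on) * q) / q
        t_off = round((plan.to_times[i] - config.contact_latency + jit_off) * q) / q
        if t_on >= t_off:
            continue
        out.append(FootprintRecord(
            side=side, t_on=float(t_on), t_off=float(t_off),
            heel_xy=(float(x), float(heel_y)), toe_xy=(float(x), float(toe_y)),
            complete=bool(complete),
        ))
    return out


def generate_session(config: SimulationConfig) -> SyntheticSession:
    """Generate one paired MLMC + PSW session with full ground truth.

    The output is fully determined by ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    span = config.psw_span / 2.0
    walkway = WalkwayFrame(walkway_length=config.walkway_length,
                           instrumented_span=(-span, span))
    recordings: list[MarkerlessRecording] = []
    footprints: list[FootprintRecord] = []
    truth_events: list[GaitEvent] = []
    truth_strides: list[StrideRecord] = []
    for p in range(config.n_passes):
        plan = _plan_pass(config, p)
        track, _ = _build_pass_track(config, plan, rng)
        recordings.append(MarkerlessRecording(
            session_id=f"synthetic-{config.seed}", pass_id=p,
            rate=config.mlmc_rate, tracks=[track], walkway=walkway,
            t0=plan.k0 / config.mlmc_rate,
        ))
        ev, st = _truth_for_pass(config, plan, p)
        truth_events.extend(ev)
        truth_strides.extend(st)
        footprints.extend(_footprints_for_pass(config, plan, rng))

    session = SyntheticSession(
        config=config, mlmc=recordings, psw=footprints,
        truth_events=truth_events, truth_strides=truth_strides,
        truth_parameters=[stride_parameters(s) for s in truth_strides],
    )
    if config.spotter or config.n_bystanders > 0:
        session = add_extra_tracks(session, config)
    return session


# ---------------------------------------------------------------------------
# Extra person tracks
# ---------------------------------------------------------------------------

def _shifted_track(src: PersonTrack, person_id: str, dx: float, dy: float
                   ) -> PersonTrack:
    poses = {}
    for seg, ps in src.poses.items():
        t = ps.transforms.copy()
        t[:, 0, 3] += dx
        t[:, 1, 3] += dy
        poses[seg] = PoseSeries(t, ps.valid.copy())
    return PersonTrack(person_id, src.rate, poses)


def _bystander_track(n: int, rate: float, x: float, y_centre: float,
                     phase: float, person_id: str) -> PersonTrack:
    tt = np.arange(n) / rate
    y = y_centre + 0.4 * np.sin(2 * np.pi * tt / 8.0 + phase)
    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    valid = np.ones(n, dtype=bool)

    def series(px: float, pz: float, dy: float = 0.0) -> PoseSeries:
        trans = np.column_stack([np.full(n, px), y + dy, np.full(n, pz)])
        return PoseSeries(_make_transforms(eye, trans), valid)

    poses = {
        "pelvis": series(x, _PELVIS_HEIGHT),
        "thigh_l": series(x + 0.09, 0.80),
        "thigh_r": series(x - 0.09, 0.80),
        "shank_l": series(x + 0.09, 0.45),
        "shank_r": series(x - 0.09, 0.45),
        "foot_l": series(x + 0.09, _ANKLE_HEIGHT),
        "foot_r": series(x - 0.09, _ANKLE_HEIGHT),
    }
    return PersonTrack(person_id, rate, poses)


def add_extra_tracks(session: SyntheticSession, config: SimulationConfig
                     ) -> SyntheticSession:
    """Append a trailing safety spotter and loitering bystander tracks.

    The spotter follows the participant at ``spotter_lag`` metres along the
    walking direction with a constant lateral offset; bystanders wander
    slowly outside the walkway centreline corridor. Ground truth continues
    to label the participant track.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB5]))
    new_recordings = []
    for p, rec in enumerate(session.mlmc):
        d = 1 if p % 2 == 0 else -1
        tracks = list(rec.tracks)
        participant = rec.track(session.participant_id)
        if config.spotter:
            tracks.append(_shifted_track(
                participant, "spotter",
                dx=config.spotter_lateral, dy=-d * config.spotter_lag))
        for j in range(config.n_bystanders):
            side = 1 if j % 2 == 0 else -1
            x = side * (1.3 + 0.25 * j)
            y_c = float(rng.uniform(-2.0, 2.0))
            phase = float(rng.uniform(0, 2 * np.pi))
            tracks.append(_bystander_track(
                participant.n_frames, rec.rate, x, y_c, phase,
                f"bystander_{j + 1}"))
        new_recordings.append(MarkerlessRecording(
            session_id=rec.session_id, pass_id=rec.pass_id, rate=rec.rate,
            tracks=tracks, walkway=rec.walkway, t0=rec.t0,
        ))
    return SyntheticSession(
        config=session.config, mlmc=new_recordings, psw=session.psw,
        truth_events=session.truth_events, truth_strides=session.truth_strides,
        truth_parameters=session.truth_parameters,
        participant_id=session.participant_id,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n_subjects: int, base: SimulationConfig, seed: int = 0,
                    cadence_sd: float = 9.77, speed_sd: float = 0.23,
                    rho: float = 0.8, stance_sd: float = 0.01,
                    width_sd: float = 0.03) -> list[SimulationConfig]:
    """Per-subject configs drawn around the base walking condition.

    Cadence and speed are sampled from a correlated bivariate normal (faster
    walkers step faster), stance fraction and stride width vary between
    subjects, and each subject receives a deterministic child seed.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    children = ss.spawn(n_subjects)
    cov = np.array([
        [cadence_sd**2, rho * cadence_sd * speed_sd],
        [rho * cadence_sd * speed_sd, speed_sd**2],
    ])
    draws = rng.multivariate_normal([base.cadence, base.speed], cov,
                                    size=n_subjects)
    configs = []
    for i in range(n_subjects):
        cadence = float(np.clip(draws[i, 0], 80.0, 160.0))
        speed = float(np.clip(draws[i, 1], 0.6, 2.4))
        stance = float(np.clip(rng.normal(base.stance_fraction, stance_sd),
                               0.56, 0.74))
        width = float(np.clip(rng.normal(base.stride_width, width_sd),
                              0.06, 0.22))
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        configs.append(base.replace(
            cadence=cadence, speed=speed, stance_fraction=stance,
            stride_width=width, double_support_fraction=None, seed=child_seed,
        ))
    return configs
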