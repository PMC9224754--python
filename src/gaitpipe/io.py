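"""Trajectory data model, readers/writers, resampling, and pass segmentation.

A markerless motion-capture export is modelled as a set of person tracks,
each holding per-frame 4x4 rigid-body poses (segment frame -> walkway frame)
for pelvis, thighs, shanks and feet, together with a validity mask: near the
walkway ends the biomechanical model is not yet fully identified and poses
there are flagged invalid rather than interpolated.

Two on-disk formats are supported:

* a documented long-form CSV dialect (one row per frame/person/segment with
  the 12 pose numbers, row-major rotation then translation, SI units), with
  ``# key=value`` metadata header lines;
* the C3D biomechanics container, available when the optional ``ezc3d``
  package is installed.

Footprint tables from a pressure-sensitive walkway use a flat CSV with the
columns ``side,t_on_s,t_off_s,heel_x_m,heel_y_m,toe_x_m,toe_y_m,complete``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENTS",
    "HEEL_OFFSET_M",
    "TOE_OFFSET_M",
    "SegmentPose",
    "PoseSeries",
    "PersonTrack",
    "WalkwayFrame",
    "MarkerlessRecording",
    "PassSegment",
    "FootprintRecord",
    "FormatError",
    "load_recording",
    "write_recording",
    "load_footprints",
    "write_footprints",
    "resample",
    "detect_passes",
]

#: Canonical segment labels of the 7-segment lower-body model.
SEGMENTS = ("pelvis", "thigh_l", "thigh_r", "shank_l", "shank_r", "foot_l", "foot_r")

#: Heel and toe landmark positions, fixed offsets in the foot frame whose
#: origin is the ankle joint centre (x lateral, y forward, z up; metres).
HEEL_OFFSET_M = np.array([0.0, -0.06, -0.08])
TOE_OFFSET_M = np.array([0.0, 0.18, -0.08])

_POSE_COLS = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]


class FormatError(ValueError):
    """A file violated the pose-CSV / C3D / footprint-CSV contract."""


@dataclass(frozen=True)
class SegmentPose:
    """One segment's pose at one frame."""

    frame: int
    transform: np.ndarray  # (4, 4) homogeneous, segment -> walkway
    valid: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.transform, dtype=float)
        if t.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if self.valid:
            _check_rotation(t[:3, :3], where=f"frame {self.frame}")
            if not np.all(np.isfinite(t[:3, 3])):
                raise ValueError(f"non-finite translation at frame {self.frame}")


def _check_rotation(r: np.ndarray, where: str, atol: float = 1e-5) -> None:
    if not np.all(np.isfinite(r)):
        raise FormatError(f"non-finite rotation at {where}")
    if not np.allclose(r @ r.T, np.eye(3), atol=atol):
        raise FormatError(f"non-orthonormal rotation at {where}")
    if np.linalg.det(r) < 0:
        raise FormatError(f"left-handed rotation (det < 0) at {where}")


@dataclass
class PoseSeries:
    """A segment's pose sequence: (n, 4, 4) transforms plus validity mask."""

    transforms: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.transforms = np.asarray(self.transforms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.transforms.ndim != 3 or self.transforms.shape[1:] != (4, 4):
            raise ValueError("transforms must have shape (n, 4, 4)")
        if self.valid.shape != (self.transforms.shape[0],):
            raise ValueError("validity mask length mismatch")

    @property
    def n_frames(self) -> int:
        return int(self.transforms.shape[0])

    @property
    def translations(self) -> np.ndarray:
        return self.transforms[:, :3, 3]

    def apply(self, point: np.ndarray) -> np.ndarray:
        """Map a fixed segment-frame point through every pose (n, 3)."""
        p = np.asarray(point, dtype=float)
        return self.transforms[:, :3, :3] @ p + self.transforms[:, :3, 3]


@dataclass
class PersonTrack:
    """One tracked person: pose sequences for the 7 lower-body segments."""

    person_id: str
    rate: float
    poses: dict[str, PoseSeries]

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        missing = set(SEGMENTS) - set(self.poses)
        if missing:
            raise ValueError(f"track {self.person_id} missing segments: {sorted(missing)}")
        counts = {s.n_frames for s in self.poses.values()}
        if len(counts) != 1:
            raise ValueError(f"track {self.person_id} has mixed frame counts {counts}")

    @property
    def n_frames(self) -> int:
        return self.poses["pelvis"].n_frames

    @property
    def valid(self) -> np.ndarray:
        """Frames at which every segment pose is valid."""
        v = np.ones(self.n_frames, dtype=bool)
        for s in self.poses.values():
            v &= s.valid
        return v

    def landmark(self, name: str, side: str) -> np.ndarray:
        """Heel / toe / ankle trajectory for one side, (n, 3) metres.

        The ankle joint centre is the foot-segment origin (its proximal end);
        heel and toe are fixed offsets in the foot frame. Values at invalid
        frames are carried through numerically but must be masked by the
        caller via :attr:`valid`.
        """
        foot = self.poses[f"foot_{side.lower()}"]
        if name == "ankle":
            return foot.translations.copy()
        if name == "heel":
            return foot.apply(HEEL_OFFSET_M)
        if name == "toe":
            return foot.apply(TOE_OFFSET_M)
        raise ValueError(f"unknown landmark {name!r}")


@dataclass(frozen=True)
class WalkwayFrame:
    """Walkway coordinate frame: +Y along the walking path, +Z up, origin at
    the calibration-object centre. The instrumented span is the portion of
    the walkway covered by the pressure-sensitive surface."""

    walkway_length: float = 10.0
    instrumented_span: tuple[float, float] = (-1.8, 1.8)

    def __post_init__(self) -> None:
        lo, hi = self.instrumented_span
        half = self.walkway_length / 2
        if not (-half <= lo < hi <= half):
            raise ValueError("instrumented span must lie within the walkway extent")

    @property
    def extent(self) -> tuple[float, float]:
        return (-self.walkway_length / 2, self.walkway_length / 2)


@dataclass
class MarkerlessRecording:
    """One pass worth of markerless motion-capture output."""

    session_id: str
    pass_id: int
    rate: float
    tracks: list[PersonTrack]
    walkway: WalkwayFrame
    t0: float = 0.0  # session-clock time of frame 0, s

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("recording must contain at least one track")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        for t in self.tracks:
            if t.rate != self.rate:
                raise ValueError(
                    f"track {t.person_id} rate {t.rate} differs from recording rate {self.rate}"
                )

    def track(self, person_id: str) -> PersonTrack:
        for t in self.tracks:
            if t.person_id == person_id:
                return t
        raise KeyError(person_id)

    def times(self, track: PersonTrack | None = None) -> np.ndarray:
        n = (track or self.tracks[0]).n_frames
        return self.t0 + np.arange(n) / self.rate


@dataclass(frozen=True)
class PassSegment:
    """A maximal interval of consistent walking direction.

    Intervals are half-open frame ranges; ``usable`` excludes the
    capture-margin frames where poses are invalid.
    """

    start: int
    stop: int
    direction: int
    usable_start: int
    usable_stop: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not (self.start <= self.usable_start <= self.usable_stop <= self.stop):
            raise ValueError("usable interval must lie within the full interval")


@dataclass(frozen=True)
class FootprintRecord:
    """One pressure-walkway footfall."""

    side: str  # "L" or "R"
    t_on: float
    t_off: float
    heel_xy: tuple[float, float]
    toe_xy: tuple[float, float]
    complete: bool = True

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if not self.t_on < self.t_off:
            raise ValueError("footprint must have t_on < t_off")


# ---------------------------------------------------------------------------
# Pose CSV dialect
# ---------------------------------------------------------------------------

def write_recording(recording: MarkerlessRecording, path: str | Path,
                    format: str = "csv") -> Path:
    """Write a recording; round-trips with :func:`load_recording`."""
    path = Path(path)
    if format == "csv":
        return _write_csv(recording, path)
    if format == "c3d":
        return _write_c3d(recording, path)
    raise ValueError(f"unknown format {format!r}")


def load_recording(path: str | Path, format: str = "csv") -> MarkerlessRecording:
    """Load a recording written by :func:`write_recording`.

    Poses and rates are preserved exactly; frames flagged invalid stay
    invalid and are never interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _load_csv(path)
    if format == "c3d":
        return _load_c3d(path)
    raise ValueError(f"unknown format {format!r}")


def _write_csv(recording: MarkerlessRecording, path: Path) -> Path:
    lo, hi = recording.walkway.instrumented_span
    header = [
        "# gaitpipe-poses v1",
        f"# session_id={recording.session_id}",
        f"# pass_id={recording.pass_id}",
        f"# rate_hz={recording.rate!r}",
        f"# t0_s={recording.t0!r}",
        f"# walkway_length_m={recording.walkway.walkway_length!r}",
        f"# span_min_m={lo!r}",
        f"# span_max_m={hi!r}",
    ]
    frames_total = sum(t.n_frames for t in recording.tracks)
    rows = np.empty((frames_total * len(SEGMENTS), 12), dtype=float)
    meta: list[tuple[int, str, str, int]] = []
    i = 0
    for track in recording.tracks:
        for seg in SEGMENTS:
            ps = track.poses[seg]
            n = ps.n_frames
            block = np.concatenate(
                [ps.transforms[:, :3, :3].reshape(n, 9), ps.transforms[:, :3, 3]], axis=1
            )
            rows[i:i + n] = block
            meta.extend(
                (f, track.person_id, seg, int(v))
                for f, v in zip(range(n), ps.valid)
            )
            i += n
    df = pd.DataFrame(rows[:i], columns=_POSE_COLS)
    md = pd.DataFrame(meta, columns=["frame", "person_id", "segment", "valid"])
    out = pd.concat([md, df], axis=1)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        out.to_csv(fh, index=False, float_format="%.17g")
    return path


def _load_csv(path: Path) -> MarkerlessRecording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        try:
            df = pd.read_csv(fh)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"{path}: unparseable pose CSV: {exc}") from exc
    required = {"frame", "person_id", "segment", "valid", *_POSE_COLS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        rate = float(meta["rate_hz"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing rate_hz metadata") from exc
    walkway = WalkwayFrame(
        walkway_length=float(meta.get("walkway_length_m", 10.0)),
        instrumented_span=(
            float(meta.get("span_min_m", -1.8)),
            float(meta.get("span_max_m", 1.8)),
        ),
    )
    bad_seg = set(df["segment"]) - set(SEGMENTS)
    if bad_seg:
        raise FormatError(f"{path}: unknown segment labels {sorted(bad_seg)}")

    tracks = []
    for pid, g in df.groupby("person_id", sort=False):
        poses = {}
        for seg, sg in g.groupby("segment", sort=False):
            sg = sg.sort_values("frame")
            frames = sg["frame"].to_numpy()
            if not np.array_equal(frames, np.arange(len(frames))):
                raise FormatError(
                    f"{path}: person {pid} segment {seg}: frames not contiguous from 0"
                )
            n = len(sg)
            t = np.tile(np.eye(4), (n, 1, 1))
            t[:, :3, :3] = sg[_POSE_COLS[:9]].to_numpy().reshape(n, 3, 3)
            t[:, :3, 3] = sg[["tx", "ty", "tz"]].to_numpy()
            valid = sg["valid"].to_numpy().astype(bool)
            for f in np.nonzero(valid)[0]:
                _check_rotation(
                    t[f, :3, :3], where=f"{path}: person {pid} segment {seg} frame {f}"
                )
            poses[seg] = PoseSeries(t, valid)
        tracks.append(PersonTrack(person_id=str(pid), rate=rate, poses=poses))
    return MarkerlessRecording(
        session_id=meta.get("session_id", path.stem),
        pass_id=int(meta.get("pass_id", 0)),
        rate=rate,
        tracks=tracks,
        walkway=walkway,
        t0=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# C3D (optional)
# ---------------------------------------------------------------------------

def _require_ezc3d():
    try:
        import ezc3d  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "C3D support needs the optional 'ezc3d' package "
            "(pip install gaitpipe[c3d]); the CSV dialect needs no extras"
        ) from exc
    return ezc3d


def _write_c3d(recording: MarkerlessRecording, path: Path) -> Path:
    # Poses are stored as four C3D points per segment: the origin and the
    # tips of the three rotated basis vectors, from which the 4x4 pose is
    # reassembled on load. Invalid frames are stored as NaN per convention.
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    labels, data = [], []
    for track in recording.tracks:
        for seg in SEGMENTS:
            ps = track.poses[seg]
            origin = ps.transforms[:, :3, 3]
            pts = [origin] + [origin + ps.transforms[:, :3, i] for i in range(3)]
            for suffix, arr in zip(("o", "x", "y", "z"), pts):
                arr = arr.copy()
                arr[~ps.valid] = np.nan
                labels.append(f"{track.person_id}:{seg}_{suffix}")
                data.append(arr)
    points = np.zeros((4, len(labels), data[0].shape[0]))
    for i, arr in enumerate(data):
        points[:3, i, :] = arr.T
    points[3] = 1.0
    c3d["parameters"]["POINT"]["RATE"]["value"] = [float(recording.rate)]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = labels
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["m"]
    c3d["data"]["points"] = points
    c3d.write(str(path))
    return path


def _load_c3d(path: Path) -> MarkerlessRecording:
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])
    points = c3d["data"]["points"]  # (4, nlabels, nframes)
    idx = {lab: i for i, lab in enumerate(labels)}
    persons: dict[str, dict[str, PoseSeries]] = {}
    for lab in labels:
        pid, rest = lab.split(":", 1)
        seg = rest.rsplit("_", 1)[0]
        if seg in SEGMENTS and pid not in persons:
            persons[pid] = {}
    n = points.shape[2]
    for pid in persons:
        for seg in SEGMENTS:
            try:
                cols = [idx[f"{pid}:{seg}_{s}"] for s in ("o", "x", "y", "z")]
            except KeyError as exc:
                raise FormatError(f"{path}: missing point {exc} for {pid}/{seg}") from exc
            o, x, y, z = (points[:3, c, :].T for c in cols)
            t = np.tile(np.eye(4), (n, 1, 1))
            t[:, :3, 3] = o
            t[:, :3, 0] = x - o
            t[:, :3, 1] = y - o
            t[:, :3, 2] = z - o
            valid = np.isfinite(o).all(axis=1)
            t[~valid] = np.eye(4)
            persons[pid][seg] = PoseSeries(t, valid)
    tracks = [PersonTrack(pid, rate, poses) for pid, poses in persons.items()]
    return MarkerlessRecording(
        session_id=path.stem, pass_id=0, rate=rate, tracks=tracks,
        walkway=WalkwayFrame(),
    )


# ---------------------------------------------------------------------------
# Footprint CSV
# ---------------------------------------------------------------------------

_FOOT_COLS = ["side", "t_on_s", "t_off_s", "heel_x_m", "heel_y_m",
              "toe_x_m", "toe_y_m", "complete"]


def write_footprints(footprints: list[FootprintRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (f.side, f.t_on, f.t_off, f.heel_xy[0], f.heel_xy[1],
         f.toe_xy[0], f.toe_xy[1], int(f.complete))
        for f in footprints
    ]
    pd.DataFrame(rows, columns=_FOOT_COLS).to_csv(path, index=False, float_format="%.17g")
    return path


def load_footprints(path: str | Path) -> list[FootprintRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_FOOT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing footprint columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(FootprintRecord(
                side=str(row["side"]),
                t_on=float(row["t_on_s"]),
                t_off=float(row["t_off_s"]),
                heel_xy=(float(row["heel_x_m"]), float(row["heel_y_m"])),
                toe_xy=(float(row["toe_x_m"]), float(row["toe_y_m"])),
                complete=bool(row["complete"]),
            ))
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(values: np.ndarray, valid: np.ndarray, rate: float,
             target_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample a uniformly sampled series onto a new rate.

    Endpoints are preserved; validity propagates conservatively (an output
    sample is valid only when both bracketing input samples are valid).
    ``values`` may have trailing dimensions; the first axis is time.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = values.shape[0]
    if valid.shape != (n,):
        raise ValueError("validity mask length mismatch")
    duration = (n - 1) / rate
    n_out = int(np.floor(duration * target_rate + 1e-9)) + 1
    t_in = np.arange(n) / rate
    t_out = np.minimum(np.arange(n_out) / target_rate, duration)
    flat = values.reshape(n, -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_out, t_in, flat[:, j])
    lo = np.clip(np.floor(t_out * rate + 1e-9).astype(int), 0, n - 1)
    hi = np.clip(np.ceil(t_out * rate - 1e-9).astype(int), 0, n - 1)
    valid_out = valid[lo] & valid[hi]
    return out.reshape((n_out,) + values.shape[1:]), valid_out


# ---------------------------------------------------------------------------
# Pass segmentation
# ---------------------------------------------------------------------------

class NoPassError(ValueError):
    """No interval with net displacement above the minimum traversal."""


def detect_passes(track: PersonTrack, rate: float | None = None,
                  min_displacement: float = 2.0,
                  smooth_window_s: float = 0.25) -> list[PassSegment]:
    """Partition a pelvis trajectory into maximal constant-direction passes.

    Pelvis Y-velocity is smoothed with a short moving average (well below
    stride frequency) before sign detection, so jitter does not fragment a
    pass. Capture-margin frames, flagged invalid by the tracker, are trimmed
    from the usable interval of each pass.
    """
    rate = rate or track.rate
    pelvis = track.poses["pelvis"]
    y = pelvis.translations[:, 1].astype(float)
    valid = track.valid
    if valid.sum() < 2:
        raise NoPassError("fewer than 2 valid pelvis frames")

    vy = np.gradient(y) * rate
    win = max(1, int(round(smooth_window_s * rate)))
    kernel = np.ones(win) / win
    vy_s = np.convolve(vy, kernel, mode="same")
    signs = np.sign(vy_s).astype(int)

    segments: list[PassSegment] = []
    start = 0
    for stop in list(np.nonzero(np.diff(signs))[0] + 1) + [len(y)]:
        sign = signs[start]
        if sign != 0:
            disp = y[stop - 1] - y[start]
            if abs(disp) >= min_displacement:
                vidx = np.nonzero(valid[start:stop])[0]
                if vidx.size:
                    u0, u1 = start + vidx[0], start + vidx[-1] + 1
                else:
                    u0 = u1 = start
                segments.append(PassSegment(
                    start=start, stop=stop, direction=int(sign),
                    usable_start=u0, usable_stop=u1,
                ))
        start = stop
    if not segments:
        raise NoPassError(
            f"no interval with net pelvis displacement >= {min_displacement} m"
        )
    return segments
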