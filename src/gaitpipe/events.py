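"""Coordinate-based gait event detection and sequence validation.

Initial contact (IC) and toe off (TO) are identified from the displacement
of the heel and toe relative to the pelvis along the direction of walking
progression: the heel is maximally ahead of the pelvis at IC, and the toe
maximally behind at TO. The detector therefore takes local maxima of the
heel series and local minima of the toe series, with a minimum peak
separation of half the stride period estimated from the series' dominant
autocorrelation lag. Event sequences are validated against the canonical
alternation IC(s), TO(opp), IC(opp), TO(s), IC(s), and only runs of at
least a configurable number of consecutive gait cycles are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .io import FootprintRecord

__all__ = [
    "GaitEvent",
    "StrideEvents",
    "CycleRun",
    "relative_displacement",
    "estimate_stride_period",
    "lowpass",
    "detect_ic",
    "detect_to",
    "validate_sequence",
    "psw_events",
]


@dataclass(frozen=True)
class GaitEvent:
    """A detected or ground-truth gait event."""

    kind: str          # "IC" or "TO"
    side: str          # "L" or "R"
    time: float        # seconds, session clock
    frame: int         # frame index at the source instrument's rate
    pass_id: int | None = None
    source: str = "MLMC"   # "MLMC", "PSW" or "truth"
    ref: int | None = None  # e.g. index of the originating footprint

    def __post_init__(self) -> None:
        if self.kind not in ("IC", "TO"):
            raise ValueError("kind must be 'IC' or 'TO'")
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")


@dataclass(frozen=True)
class StrideEvents:
    """The five events bounding one stride, in canonical order."""

    ic: GaitEvent
    to_contra: GaitEvent
    ic_contra: GaitEvent
    to: GaitEvent
    ic_next: GaitEvent

    @property
    def side(self) -> str:
        return self.ic.side

    def all(self) -> tuple[GaitEvent, ...]:
        return (self.ic, self.to_contra, self.ic_contra, self.to, self.ic_next)


@dataclass
class CycleRun:
    """Consecutive valid gait cycles for one side."""

    side: str
    strides: list[StrideEvents]

    @property
    def n_cycles(self) -> int:
        return len(self.strides)


def _opp(side: str) -> str:
    return "R" if side == "L" else "L"


# ---------------------------------------------------------------------------
# Series utilities
# ---------------------------------------------------------------------------

def relative_displacement(landmark_y: np.ndarray, pelvis_y: np.ndarray,
                          direction: int) -> np.ndarray:
    """Landmark displacement from the pelvis along walking progression.

    ``direction`` is +1 or -1 along the walkway Y axis; the result is
    positive when the landmark is ahead of the pelvis regardless of which
    way the person is walking.
    """
    landmark_y = np.asarray(landmark_y, dtype=float)
    pelvis_y = np.asarray(pelvis_y, dtype=float)
    if landmark_y.shape != pelvis_y.shape:
        raise ValueError("landmark and pelvis series must have equal length")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    return direction * (landmark_y - pelvis_y)


def lowpass(series: np.ndarray, rate: float, cutoff_hz: float = 6.0) -> np.ndarray:
    """Zero-lag 4th-order Butterworth low-pass (2nd order, forward-backward)."""
    b, a = butter(2, cutoff_hz / (rate / 2.0))
    return filtfilt(b, a, np.asarray(series, dtype=float))


def estimate_stride_period(series: np.ndarray, rate: float,
                           lag_range_s: tuple[float, float] = (0.4, 2.5)
                           ) -> float | None:
    """Dominant period of a quasi-periodic series via its autocorrelation.

    Returns the lag (s) of the autocorrelation maximum within ``lag_range_s``,
    or None when the series is too short or aperiodic.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    lo = int(round(lag_range_s[0] * rate))
    hi = min(n - 1, int(round(lag_range_s[1] * rate)))
    if hi <= lo or n < 2 * lo:
        return None
    ac = np.correlate(x, x, mode="full")[n - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lag = lo + int(np.argmax(ac[lo:hi + 1]))
    if ac[lag] < 0.1:
        return None
    return lag / rate


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _detect_extrema(series: np.ndarray, rate: float, *, maxima: bool,
                    min_separation_s: float | None,
                    lowpass_hz: float | None) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if lowpass_hz is not None:
        x = lowpass(x, rate, lowpass_hz)
    if not maxima:
        x = -x
    if min_separation_s is None:
        period = estimate_stride_period(x if maxima else -x, rate)
        min_separation_s = 0.5 * period if period is not None else 0.4
    distance = max(1, int(round(min_separation_s * rate)))
    # plateau_size makes find_peaks report flat-topped extrema; ties resolve
    # to the earliest frame of the plateau.
    peaks, props = find_peaks(x, distance=distance, plateau_size=1)
    if peaks.size and "left_edges" in props:
        peaks = props["left_edges"]
    return peaks


def detect_ic(heel_rel: np.ndarray, rate: float, *, side: str,
              frame_offset: int = 0, t0: float = 0.0,
              pass_id: int | None = None, source: str = "MLMC",
              min_separation_s: float | None = None,
              lowpass_hz: float | None = None) -> list[GaitEvent]:
    """Initial contacts: local maxima of the heel-to-pelvis displacement.

    ``heel_rel`` is the pelvis-relative heel displacement over the usable
    interval of one pass (see :func:`relative_displacement`); ``frame_offset``
    and ``t0`` place the interval on the recording's frame/time axes.
    """
    peaks = _detect_extrema(heel_rel, rate, maxima=True,
                            min_separation_s=min_separation_s,
                            lowpass_hz=lowpass_hz)
    if peaks.size == 0:
        warnings.warn(f"no IC maxima found (side {side}, pass {pass_id})",
                      stacklevel=2)
    return [
        GaitEvent(kind="IC", side=side, time=t0 + (frame_offset + int(p)) / rate,
                  frame=frame_offset + int(p), pass_id=pass_id, source=source)
        for p in peaks
    ]


def detect_to(toe_rel: np.ndarray, rate: float, *, side: str,
              frame_offset: int = 0, t0: float = 0.0,
              pass_id: int | None = None, source: str = "MLMC",
              min_separation_s: float | None = None,
              lowpass_hz: float | None = None) -> list[GaitEvent]:
    """Toe offs: local minima of the toe-to-pelvis displacement."""
    peaks = _detect_extrema(toe_rel, rate, maxima=False,
                            min_separation_s=min_separation_s,
                            lowpass_hz=lowpass_hz)
    if peaks.size == 0:
        warnings.warn(f"no TO minima found (side {side}, pass {pass_id})",
                      stacklevel=2)
    return [
        GaitEvent(kind="TO", side=side, time=t0 + (frame_offset + int(p)) / rate,
                  frame=frame_offset + int(p), pass_id=pass_id, source=source)
        for p in peaks
    ]


# ---------------------------------------------------------------------------
# Sequence validation
# ---------------------------------------------------------------------------

def _successor_ok(prev: GaitEvent, nxt: GaitEvent) -> bool:
    if prev.kind == "IC":
        return nxt.kind == "TO" and nxt.side == _opp(prev.side)
    return nxt.kind == "IC" and nxt.side == prev.side


def validate_sequence(events: list[GaitEvent], min_cycles: int = 3,
                      max_gap_s: float | None = 1.5,
                      ) -> tuple[list[CycleRun], list[tuple[GaitEvent, str]]]:
    """Partition events into runs obeying the canonical alternation.

    The canonical order within a stride of side ``s`` is IC(s), TO(opp),
    IC(opp), TO(s), IC(s). Maximal runs obeying it are split where the
    order breaks, where the pass changes, or where consecutive events are
    further apart than ``max_gap_s``. Runs contributing fewer than
    ``min_cycles`` consecutive cycles are discarded; discarded events are
    returned with a reason.
    """
    events = sorted(events, key=lambda e: e.time)
    chains: list[list[GaitEvent]] = []
    for ev in events:
        if chains:
            prev = chains[-1][-1]
            ok = (_successor_ok(prev, ev)
                  and (prev.pass_id == ev.pass_id)
                  and (max_gap_s is None or ev.time - prev.time <= max_gap_s))
        else:
            ok = False
        if ok:
            chains[-1].append(ev)
        else:
            chains.append([ev])

    runs: list[CycleRun] = []
    used: set[int] = set()
    for chain in chains:
        for side in ("L", "R"):
            strides: list[StrideEvents] = []
            i = 0
            while i + 4 < len(chain):
                window = chain[i:i + 5]
                if window[0].kind == "IC" and window[0].side == side:
                    strides.append(StrideEvents(*window))
                    i += 4  # next stride starts at this stride's closing IC
                else:
                    i += 1
            if len(strides) >= min_cycles:
                runs.append(CycleRun(side=side, strides=strides))
                for s in strides:
                    used.update(id(e) for e in s.all())

    discarded = []
    for chain in chains:
        n_cyc = max((sum(1 for _ in _iter_strides(chain, s)) for s in ("L", "R")),
                    default=0)
        for ev in chain:
            if id(ev) not in used:
                reason = ("run shorter than %d cycles" % min_cycles
                          if n_cyc > 0 else "breaks canonical event order")
                discarded.append((ev, reason))
    return runs, discarded


def _iter_strides(chain: list[GaitEvent], side: str):
    i = 0
    while i + 4 < len(chain):
        if chain[i].kind == "IC" and chain[i].side == side:
            yield chain[i:i + 5]
            i += 4
        else:
            i += 1


# ---------------------------------------------------------------------------
# Pressure-walkway events
# ---------------------------------------------------------------------------

class FootfallOverlapError(ValueError):
    """Same-side footprints with overlapping contact intervals."""


def psw_events(footprints: list[FootprintRecord], rate: float = 100.0
               ) -> list[GaitEvent]:
    """Events from walkway footprints: IC at contact onset, TO at offset.

    Footprints that did not occur entirely within the pressure-sensitive
    area (``complete=False``) are excluded before events are emitted.
    """
    ordered = sorted(range(len(footprints)), key=lambda i: footprints[i].t_on)
    last_off: dict[str, float] = {}
    for i in ordered:
        f = footprints[i]
        if f.side in last_off and f.t_on < last_off[f.side] - 1e-9:
            raise FootfallOverlapError(
                f"side {f.side} footprint at t_on={f.t_on:.3f}s overlaps the "
                f"previous same-side contact ending {last_off[f.side]:.3f}s"
            )
        last_off[f.side] = max(last_off.get(f.side, -np.inf), f.t_off)

    out: list[GaitEvent] = []
    for i in ordered:
        f = footprints[i]
        if not f.complete:
            continue
        out.append(GaitEvent(kind="IC", side=f.side, time=f.t_on,
                             frame=int(round(f.t_on * rate)), source="PSW", ref=i))
        out.append(GaitEvent(kind="TO", side=f.side, time=f.t_off,
                             frame=int(round(f.t_off * rate)), source="PSW", ref=i))
    out.sort(key=lambda e: e.time)
    return out
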