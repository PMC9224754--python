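"""The twelve spatiotemporal gait parameters, per stride and per subject.

A stride runs from one initial contact (IC) to the next ipsilateral IC and
carries five events in canonical order, IC, TO(contra), IC(contra), TO,
IC(next), from which the temporal parameters decompose exactly:

* stride time = stance + swing,
* stance = 1st double support + single support + 2nd double support.

Spatial parameters are measured parallel to the walking direction from the
foot reference positions at the contacts: the ankle-joint-centre ground
projection for markerless motion capture, and the heel coordinate for
pressure-walkway footprints. Each stride carries its ipsilateral step (the
contralateral-IC to ipsilateral-IC half ending the stride).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .events import CycleRun, GaitEvent, StrideEvents, psw_events, validate_sequence
from .io import FootprintRecord, PersonTrack

__all__ = [
    "PARAMETERS",
    "StrideRecord",
    "SpatioTemporalRow",
    "SubjectSummary",
    "build_strides",
    "strides_from_track",
    "strides_from_footprints",
    "stride_parameters",
    "summarize_subject",
    "rows_to_frame",
]

log = logging.getLogger(__name__)

#: Parameter name -> unit, in the conventional reporting order.
PARAMETERS = {
    "cadence": "steps/min",
    "speed": "m/s",
    "step_length": "m",
    "stride_length": "m",
    "stride_width": "m",
    "step_time": "s",
    "stride_time": "s",
    "stance_time": "s",
    "swing_time": "s",
    "single_support_time": "s",
    "double_support_1": "s",
    "double_support_2": "s",
}


@dataclass(frozen=True)
class StrideRecord:
    """One stride: event times plus foot reference positions (x, y in m)."""

    side: str
    instrument: str          # "MLMC", "PSW" or "truth"
    t_ic: float
    t_to_contra: float
    t_ic_contra: float
    t_to: float
    t_ic_next: float
    pos_ic: tuple[float, float]        # ipsilateral foot at t_ic
    pos_ic_next: tuple[float, float]   # ipsilateral foot at t_ic_next
    pos_contra: tuple[float, float]    # contralateral foot at t_ic_contra

    def __post_init__(self) -> None:
        order = (self.t_ic, self.t_to_contra, self.t_ic_contra, self.t_to,
                 self.t_ic_next)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(
                "stride events must satisfy "
                "t_IC < t_TO_contra < t_IC_contra < t_TO < t_IC_next; got "
                f"{order}"
            )


@dataclass(frozen=True)
class SpatioTemporalRow:
    """The twelve spatiotemporal parameters of one stride."""

    cadence: float
    speed: float
    step_length: float
    stride_length: float
    stride_width: float
    step_time: float
    stride_time: float
    stance_time: float
    swing_time: float
    single_support_time: float
    double_support_1: float
    double_support_2: float
    side: str = "L"
    instrument: str = "MLMC"

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def stride_parameters(stride: StrideRecord) -> SpatioTemporalRow:
    """Closed-form spatiotemporal parameters of one stride.

    Temporal parameters are differences of the five event times; spatial
    parameters are taken from the foot reference positions, parallel (Y)
    and perpendicular (X) to the walking direction. Cadence is derived from
    the stride time (two steps per stride), so every row is self-contained.
    """
    stride_time = stride.t_ic_next - stride.t_ic
    step_time = stride.t_ic_next - stride.t_ic_contra
    stance_time = stride.t_to - stride.t_ic
    swing_time = stride.t_ic_next - stride.t_to
    ds1 = stride.t_to_contra - stride.t_ic
    single = stride.t_ic_contra - stride.t_to_contra
    ds2 = stride.t_to - stride.t_ic_contra
    stride_length = abs(stride.pos_ic_next[1] - stride.pos_ic[1])
    step_length = abs(stride.pos_ic_next[1] - stride.pos_contra[1])
    stride_width = abs(stride.pos_ic[0] - stride.pos_contra[0])
    return SpatioTemporalRow(
        cadence=120.0 / stride_time,
        speed=stride_length / stride_time,
        step_length=step_length,
        stride_length=stride_length,
        stride_width=stride_width,
        step_time=step_time,
        stride_time=stride_time,
        stance_time=stance_time,
        swing_time=swing_time,
        single_support_time=single,
        double_support_1=ds1,
        double_support_2=ds2,
        side=stride.side,
        instrument=stride.instrument,
    )


# ---------------------------------------------------------------------------
# Stride assembly
# ---------------------------------------------------------------------------

def build_strides(runs: list[CycleRun], get_position, instrument: str
                  ) -> list[StrideRecord]:
    """One :class:`StrideRecord` per stride in the validated cycle runs.

    ``get_position(event) -> (x, y) | None`` supplies the foot reference
    position at an IC event; strides whose positions are unavailable (e.g.
    the contact frame is invalid) are skipped with a logged reason.
    """
    out: list[StrideRecord] = []
    for run in runs:
        for s in run.strides:
            p_ic = get_position(s.ic)
            p_next = get_position(s.ic_next)
            p_contra = get_position(s.ic_contra)
            if p_ic is None or p_next is None or p_contra is None:
                log.info("stride at t=%.3f s (%s) skipped: missing foot position",
                         s.ic.time, s.side)
                continue
            try:
                out.append(StrideRecord(
                    side=s.side, instrument=instrument,
                    t_ic=s.ic.time, t_to_contra=s.to_contra.time,
                    t_ic_contra=s.ic_contra.time, t_to=s.to.time,
                    t_ic_next=s.ic_next.time,
                    pos_ic=tuple(p_ic), pos_ic_next=tuple(p_next),
                    pos_contra=tuple(p_contra),
                ))
            except ValueError as exc:
                log.info("stride at t=%.3f s skipped: %s", s.ic.time, exc)
    return out


def strides_from_track(runs: list[CycleRun], track: PersonTrack
                       ) -> list[StrideRecord]:
    """Markerless strides: foot reference = ankle ground projection."""
    ankle = {s: track.landmark("ankle", s) for s in ("l", "r")}
    valid = track.valid

    def get_position(ev: GaitEvent):
        f = ev.frame
        if not (0 <= f < track.n_frames) or not valid[f]:
            return None
        p = ankle[ev.side.lower()][f]
        return (float(p[0]), float(p[1]))

    return build_strides(runs, get_position, instrument="MLMC")


def strides_from_footprints(footprints: list[FootprintRecord],
                            rate: float = 100.0, min_cycles: int = 1
                            ) -> list[StrideRecord]:
    """Pressure-walkway strides, from complete footprints only.

    The instrumented span yields only a couple of complete strides per pass,
    so the consecutive-cycle minimum defaults to 1 here; the canonical-order
    validation still applies.
    """
    events = psw_events(footprints, rate=rate)
    runs, _ = validate_sequence(events, min_cycles=min_cycles)

    def get_position(ev: GaitEvent):
        if ev.ref is None:
            return None
        return footprints[ev.ref].heel_xy

    return build_strides(runs, get_position, instrument="PSW")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class SubjectSummary:
    """Per-subject, per-task parameter means and SDs across strides."""

    subject: str
    task: str           # "SS" or "FC"
    instrument: str
    n_strides: int
    mean: dict[str, float]
    sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(PARAMETERS),
            "unit": [PARAMETERS[p] for p in PARAMETERS],
            "mean": [self.mean[p] for p in PARAMETERS],
            "sd": [self.sd[p] for p in PARAMETERS],
        })


def rows_to_frame(rows: list[SpatioTemporalRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def summarize_subject(rows: list[SpatioTemporalRow], subject: str, task: str,
                      instrument: str) -> SubjectSummary:
    """Arithmetic mean and sample SD (n-1) of each parameter across strides."""
    if not rows:
        raise ValueError(f"no strides to summarize for subject {subject}")
    df = rows_to_frame(rows)
    if len(rows) == 1:
        warnings.warn(f"subject {subject}: single stride, SD reported as 0",
                      stacklevel=2)
        sd = {p: 0.0 for p in PARAMETERS}
    else:
        sd = {p: float(df[p].std(ddof=1)) for p in PARAMETERS}
    return SubjectSummary(
        subject=subject, task=task, instrument=instrument, n_strides=len(rows),
        mean={p: float(df[p].mean()) for p in PARAMETERS}, sd=sd,
    )
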