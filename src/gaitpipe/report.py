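"""End-to-end pipeline orchestration and per-subject gait reports.

``analyze_session`` runs the measurement chain on one recorded session:
participant selection, pass segmentation, coordinate-based event detection,
sequence validation, and stride parameter extraction for both instruments.
``run_pipeline`` drives the full study flow (generate/load -> select ->
events -> spatiotemporal -> kinematics -> agreement -> report) writing CSV
artifacts, structured JSON logs and a deterministic HTML report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from html import escape
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementResults, compare_instruments
from .config import SimulationConfig
from .events import CycleRun, GaitEvent, detect_ic, detect_to, relative_displacement, validate_sequence
from .io import FootprintRecord, MarkerlessRecording, detect_passes
from .kinematics import (
    NormalizedCycle,
    ReferenceBand,
    deviation_flags,
    ensemble_stats,
    joint_angle_series,
    time_normalize,
)
from .selection import SelectionResult, select_participant
from .spatiotemporal import (
    PARAMETERS,
    SpatioTemporalRow,
    StrideRecord,
    SubjectSummary,
    rows_to_frame,
    stride_parameters,
    strides_from_footprints,
    strides_from_track,
    summarize_subject,
)
from .synthetic import generate_cohort, generate_session

log = logging.getLogger(__name__)

__all__ = ["SessionAnalysis", "analyze_session", "GaitReport", "build_report",
           "run_pipeline", "PipelineError", "events_to_frame"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class SessionAnalysis:
    """Everything the measurement chain extracts from one session."""

    selections: list[SelectionResult]
    mlmc_events: list[GaitEvent]
    mlmc_runs: list[CycleRun]
    mlmc_strides: list[StrideRecord]
    mlmc_rows: list[SpatioTemporalRow]
    psw_strides: list[StrideRecord]
    psw_rows: list[SpatioTemporalRow]
    discarded: list[tuple[GaitEvent, str]]


def analyze_session(recordings: list[MarkerlessRecording],
                    footprints: list[FootprintRecord] | None = None,
                    min_cycles: int = 3,
                    lowpass_hz: float | None = None,
                    psw_rate: float = 100.0) -> SessionAnalysis:
    """Run selection, event detection and stride extraction on one session.

    Each recording is segmented into constant-direction passes; initial
    contacts and toe offs are detected from pelvis-relative heel/toe
    displacement over the usable (valid-pose) interval of each pass, and
    only runs of ``min_cycles`` consecutive cycles contribute strides.
    """
    selections: list[SelectionResult] = []
    all_events: list[GaitEvent] = []
    runs: list[CycleRun] = []
    strides: list[StrideRecord] = []
    discarded: list[tuple[GaitEvent, str]] = []

    for rec in recordings:
        sel = select_participant(rec)
        selections.append(sel)
        track = rec.track(sel.chosen)
        passes = detect_passes(track)
        pelvis_y = track.poses["pelvis"].translations[:, 1]
        heel = {s: track.landmark("heel", s)[:, 1] for s in ("l", "r")}
        toe = {s: track.landmark("toe", s)[:, 1] for s in ("l", "r")}
        rec_events: list[GaitEvent] = []
        for k, seg in enumerate(passes):
            u0, u1 = seg.usable_start, seg.usable_stop
            if u1 - u0 < 2:
                continue
            pass_id = rec.pass_id * 1000 + k
            for side in ("L", "R"):
                lo = side.lower()
                heel_rel = relative_displacement(heel[lo][u0:u1],
                                                 pelvis_y[u0:u1], seg.direction)
                toe_rel = relative_displacement(toe[lo][u0:u1],
                                                pelvis_y[u0:u1], seg.direction)
                rec_events += detect_ic(heel_rel, rec.rate, side=side,
                                        frame_offset=u0, t0=rec.t0,
                                        pass_id=pass_id, lowpass_hz=lowpass_hz)
                rec_events += detect_to(toe_rel, rec.rate, side=side,
                                        frame_offset=u0, t0=rec.t0,
                                        pass_id=pass_id, lowpass_hz=lowpass_hz)
        rec_runs, rec_discarded = validate_sequence(rec_events,
                                                    min_cycles=min_cycles)
        all_events += rec_events
        runs += rec_runs
        discarded += rec_discarded
        strides += strides_from_track(rec_runs, track)

    mlmc_rows = [stride_parameters(s) for s in strides]
    psw_strides: list[StrideRecord] = []
    psw_rows: list[SpatioTemporalRow] = []
    if footprints:
        psw_strides = strides_from_footprints(footprints, rate=psw_rate)
        psw_rows = [stride_parameters(s) for s in psw_strides]
    return SessionAnalysis(
        selections=selections, mlmc_events=sorted(all_events, key=lambda e: e.time),
        mlmc_runs=runs, mlmc_strides=strides, mlmc_rows=mlmc_rows,
        psw_strides=psw_strides, psw_rows=psw_rows, discarded=discarded,
    )


def events_to_frame(events: list[GaitEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "source": e.source, "pass": e.pass_id, "side": e.side, "kind": e.kind,
        "frame": e.frame, "time_s": e.time,
    } for e in events])


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class GaitReport:
    """A deterministic per-subject gait report document."""

    subject: str
    task: str
    html: str
    flagged: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.html)
        return path


def _summary_table(summary: SubjectSummary) -> str:
    rows = "".join(
        f"<tr><td>{p}</td><td>{PARAMETERS[p]}</td>"
        f"<td>{summary.mean[p]:.4g}</td><td>{summary.sd[p]:.4g}</td></tr>"
        for p in PARAMETERS
    )
    return (f"<h3>{escape(summary.instrument)} "
            f"({summary.n_strides} strides)</h3>"
            "<table><tr><th>parameter</th><th>unit</th><th>mean</th>"
            f"<th>SD</th></tr>{rows}</table>")


def build_report(subject: str, task: str,
                 mlmc_summary: SubjectSummary | None = None,
                 psw_summary: SubjectSummary | None = None,
                 agreement: AgreementResults | None = None,
                 cycles: dict[str, NormalizedCycle] | None = None,
                 bands: dict[str, ReferenceBand] | None = None,
                 k_sd: float = 1.0,
                 metadata: dict | None = None) -> GaitReport:
    """Assemble the per-subject report from pipeline artifacts.

    The document is a self-contained deterministic HTML body: identical
    inputs produce byte-identical output. Sections for absent artifacts are
    omitted with a notice. When both normalized joint-angle cycles and
    reference bands are given, out-of-band intervals are flagged as gait
    deviations.
    """
    if mlmc_summary is None and psw_summary is None:
        raise PipelineError("report", f"no summaries available for {subject}")
    parts = [
        "<html><head><meta charset='utf-8'>"
        f"<title>Gait report {escape(subject)}</title></head><body>",
        f"<h1>Gait report: {escape(subject)} ({escape(task)})</h1>",
    ]
    for s in (psw_summary, mlmc_summary):
        if s is not None:
            parts.append(_summary_table(s))
    if agreement is not None:
        parts.append("<h3>Instrument agreement</h3><pre>"
                     + escape(agreement.to_frame().to_string(index=False))
                     + "</pre>")
    else:
        parts.append("<p><em>Agreement section omitted: only one instrument "
                     "available.</em></p>")

    flagged: dict[str, list[tuple[int, int]]] = {}
    if cycles and bands:
        parts.append(f"<h3>Joint-angle deviations (outside mean &plusmn; "
                     f"{k_sd:g} SD)</h3><ul>")
        for name in sorted(cycles):
            if name not in bands:
                continue
            flags = deviation_flags(cycles[name], bands[name], k_sd=k_sd)
            flagged[name] = flags
            pretty = (", ".join(f"{a}&ndash;{b}%" for a, b in flags)
                      if flags else "none")
            parts.append(f"<li>{escape(name)}: {pretty}</li>")
        parts.append("</ul>")
    if metadata:
        parts.append("<h3>Run metadata</h3><pre>"
                     + escape(json.dumps(metadata, indent=2, sort_keys=True))
                     + "</pre>")
    parts.append("</body></html>")
    return GaitReport(subject=subject, task=task, html="\n".join(parts),
                      flagged=flagged)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: SimulationConfig, outdir: str | Path,
                 n_subjects: int = 1, task: str = "SS",
                 with_psw: bool = True) -> dict[str, Path]:
    """Generate -> select -> events -> parameters -> kinematics -> agreement
    -> report, writing artifacts and a JSON-lines log under ``outdir``.

    With ``n_subjects >= 2`` a cohort is generated around ``config`` and the
    agreement battery is run on per-subject means; with a single subject (or
    ``with_psw=False``) the agreement stage is skipped with a notice.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logpath = outdir / "pipeline_log.jsonl"
    artifacts: dict[str, Path] = {}
    records: list[dict] = []

    def stage(name: str, **info):
        records.append({"stage": name, **info})

    configs = (generate_cohort(n_subjects, config, seed=config.seed)
               if n_subjects >= 2 else [config])
    psw_summaries: list[SubjectSummary] = []
    mlmc_summaries: list[SubjectSummary] = []
    first_analysis: SessionAnalysis | None = None

    for i, cfg in enumerate(configs):
        subject = f"subj{i:03d}"
        try:
            session = generate_session(cfg)
        except Exception as exc:
            raise PipelineError("generate", str(exc)) from exc
        stage("generate", subject=subject, seed=cfg.seed,
              config_hash=_config_hash(cfg))
        try:
            analysis = analyze_session(
                session.mlmc, session.psw if with_psw else None)
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc
        stage("analyze", subject=subject,
              mlmc_strides=len(analysis.mlmc_strides),
              psw_strides=len(analysis.psw_strides),
              selections=[s.chosen for s in analysis.selections])
        if first_analysis is None:
            first_analysis = analysis
        if analysis.mlmc_rows:
            mlmc_summaries.append(summarize_subject(
                analysis.mlmc_rows, subject, task, "MLMC"))
        if analysis.psw_rows:
            psw_summaries.append(summarize_subject(
                analysis.psw_rows, subject, task, "PSW"))

    assert first_analysis is not None
    ev_path = outdir / "events.csv"
    events_to_frame(first_analysis.mlmc_events).to_csv(ev_path, index=False)
    artifacts["events"] = ev_path
    rows_path = outdir / "strides_mlmc.csv"
    rows_to_frame(first_analysis.mlmc_rows).to_csv(rows_path, index=False)
    artifacts["strides_mlmc"] = rows_path
    if first_analysis.psw_rows:
        p = outdir / "strides_psw.csv"
        rows_to_frame(first_analysis.psw_rows).to_csv(p, index=False)
        artifacts["strides_psw"] = p
    stage("spatiotemporal", mlmc_subjects=len(mlmc_summaries),
          psw_subjects=len(psw_summaries))

    agreement = None
    if with_psw and len(psw_summaries) >= 2 and \
            len(psw_summaries) == len(mlmc_summaries):
        agreement = compare_instruments(psw_summaries, mlmc_summaries)
        agr_path = outdir / "agreement.csv"
        agreement.to_csv(agr_path)
        artifacts["agreement"] = agr_path
        stage("agreement", n=len(psw_summaries))
    else:
        stage("agreement", skipped=True,
              reason="needs PSW data for >= 2 matched subjects")

    report = build_report(
        subject="subj000", task=task,
        mlmc_summary=mlmc_summaries[0] if mlmc_summaries else None,
        psw_summary=psw_summaries[0] if psw_summaries else None,
        agreement=agreement,
        metadata={"seed": config.seed, "config_hash": _config_hash(config),
                  "version": __version__},
    )
    rep_path = outdir / "report.html"
    report.write(rep_path)
    artifacts["report"] = rep_path
    stage("report", path=rep_path.name)

    with open(logpath, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    artifacts["log"] = logpath
    return artifacts
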