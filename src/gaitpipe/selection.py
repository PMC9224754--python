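"""Select the study participant's track among multiple reconstructed persons.

Markerless pose estimation reconstructs every person visible on camera:
the participant, a trailing safety spotter, and bystanders. The participant
is identified from pose position relative to the walkway frame: eligible
tracks are those that actually traverse the walkway (net pelvis displacement
along Y above a minimum fraction of the usable length), and among those the
track closest to the walkway centreline is chosen, with near-ties resolved
by earliest entry into the usable volume. All per-track scores are returned
for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import MarkerlessRecording

__all__ = ["TrackScore", "SelectionResult", "SelectionError", "select_participant"]


class SelectionError(ValueError):
    """No track satisfies the traversal requirement."""


@dataclass(frozen=True)
class TrackScore:
    person_id: str
    net_displacement: float     # |net pelvis Y displacement| over valid frames, m
    mean_abs_lateral: float     # mean |pelvis X| over valid frames, m
    valid_fraction: float
    first_valid_frame: int | None
    eligible: bool


@dataclass(frozen=True)
class SelectionResult:
    chosen: str
    scores: tuple[TrackScore, ...]
    rationale: str   # "single_track" | "min_lateral" | "tie_break_entry"

    def to_json(self) -> str:
        return json.dumps({
            "chosen": self.chosen,
            "rationale": self.rationale,
            "scores": [vars(s) for s in self.scores],
        }, indent=2)


def select_participant(recording: MarkerlessRecording,
                       min_traversal_fraction: float = 0.6,
                       tie_margin: float = 0.05) -> SelectionResult:
    """Choose the participant track of a recording.

    Parameters
    ----------
    min_traversal_fraction : float
        Minimum net pelvis Y displacement, as a fraction of the usable
        walkway length (walkway minus the invalid capture margins), for a
        track to be eligible.
    tie_margin : float
        When two eligible tracks' mean absolute lateral offsets differ by
        less than this (m), the one entering the usable volume earlier wins.
    """
    scores: list[TrackScore] = []
    # Usable length: span of valid pelvis positions of the farthest-travelling
    # track, bounded by the walkway extent.
    usable_lengths = []
    for track in recording.tracks:
        y = track.poses["pelvis"].translations[:, 1]
        valid = track.valid
        if valid.sum() >= 2:
            yv = y[valid]
            usable_lengths.append(yv.max() - yv.min())
    usable = min(max(usable_lengths, default=0.0), recording.walkway.walkway_length)
    threshold = min_traversal_fraction * usable

    for track in recording.tracks:
        pelvis = track.poses["pelvis"].translations
        valid = track.valid
        nvalid = int(valid.sum())
        if nvalid >= 2:
            yv = pelvis[valid, 1]
            xv = pelvis[valid, 0]
            net = float(abs(yv[-1] - yv[0]))
            lat = float(np.mean(np.abs(xv)))
            first = int(np.nonzero(valid)[0][0])
        else:
            net, lat, first = 0.0, float("inf"), None
        scores.append(TrackScore(
            person_id=track.person_id,
            net_displacement=net,
            mean_abs_lateral=lat,
            valid_fraction=nvalid / max(track.n_frames, 1),
            first_valid_frame=first,
            eligible=net >= threshold and nvalid >= 2,
        ))

    eligible = [s for s in scores if s.eligible]
    if not eligible:
        raise SelectionError(
            "no track traverses the walkway (threshold "
            f"{threshold:.2f} m); scores: "
            + "; ".join(f"{s.person_id}: net={s.net_displacement:.2f} m"
                        for s in scores)
        )
    if len(scores) == 1:
        return SelectionResult(scores[0].person_id, tuple(scores), "single_track")

    best = min(eligible, key=lambda s: s.mean_abs_lateral)
    contenders = [s for s in eligible
                  if s.mean_abs_lateral - best.mean_abs_lateral < tie_margin]
    if len(contenders) > 1:
        chosen = min(contenders,
                     key=lambda s: (s.first_valid_frame
                                    if s.first_valid_frame is not None else 10**9))
        return SelectionResult(chosen.person_id, tuple(scores), "tie_break_entry")
    return SelectionResult(best.person_id, tuple(scores), "min_lateral")
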