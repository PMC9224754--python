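"""Feasibility checklist tallying.

A feasibility checklist poses yes/no questions in three areas of focus -
implementation, practicality, and expansion - and answers each question
separately at every experimental location. An area's success rate is the
fraction of yes answers over questions x locations. The packaged checklist
records a six-location community deployment of a markerless motion-capture
system; tallying is generic, so user checklists with different questions,
areas or location sets work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["FeasibilityChecklist", "load_checklist", "packaged_checklist_path",
           "tally_area", "tally_rows", "tally_all"]


@dataclass
class FeasibilityChecklist:
    """Per-question, per-location yes/no answers, grouped into areas."""

    table: pd.DataFrame          # columns: area, group, question, <locations...>
    locations: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"area", "question"}
        if not required <= set(self.table.columns):
            raise ValueError("checklist needs 'area' and 'question' columns")
        if not self.locations:
            raise ValueError("checklist needs at least one location column")
        if self.table.empty:
            raise ValueError("checklist has no questions")
        answers = self.table[list(self.locations)]
        if answers.isna().any().any():
            raise ValueError("every question must be answered at every location")
        bad = set(answers.values.ravel()) - {"yes", "no"}
        if bad:
            raise ValueError(f"answers must be 'yes' or 'no'; found {sorted(bad)}")

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.table["area"]))


def packaged_checklist_path() -> Path:
    return Path(resources.files("gaitpipe.data") / "feasibility_checklist.csv")


def load_checklist(path: str | Path | None = None) -> FeasibilityChecklist:
    """Load a checklist CSV; defaults to the packaged six-location checklist."""
    path = Path(path) if path is not None else packaged_checklist_path()
    df = pd.read_csv(path, dtype=str)
    meta = [c for c in ("area", "group", "question") if c in df.columns]
    locations = tuple(c for c in df.columns if c not in meta)
    return FeasibilityChecklist(table=df, locations=locations)


def _round_half_up(value: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1e-{ndigits}"),
                                               rounding=ROUND_HALF_UP))


def tally_area(checklist: FeasibilityChecklist, area: str
               ) -> tuple[int, int, float]:
    """(successes, total, success rate %) for one area.

    The rate is rounded half-up to one decimal place; the tally is invariant
    to the ordering of questions and locations.
    """
    sub = checklist.table[checklist.table["area"] == area]
    if sub.empty:
        raise KeyError(f"area {area!r} not present in checklist")
    answers = sub[list(checklist.locations)]
    successes = int((answers == "yes").to_numpy().sum())
    total = answers.size
    return successes, total, _round_half_up(100.0 * successes / total)


def tally_rows(checklist: FeasibilityChecklist) -> pd.DataFrame:
    """Per-question successes across locations (e.g. 5/6 rows)."""
    answers = checklist.table[list(checklist.locations)]
    return pd.DataFrame({
        "area": checklist.table["area"],
        "question": checklist.table["question"],
        "successes": (answers == "yes").sum(axis=1),
        "total": len(checklist.locations),
    })


def tally_all(checklist: FeasibilityChecklist) -> pd.DataFrame:
    rows = []
    for area in checklist.areas:
        s, t, r = tally_area(checklist, area)
        rows.append({"area": area, "successes": s, "total": t, "rate_pct": r})
    return pd.DataFrame(rows)
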