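"""Participant eligibility from visual-analog-scale (VAS) sweetness ratings.

Participants rate passion-fruit juice sweetened with five graded sucrose
concentrations on a 9-cm line (4.5 cm = ideal sweetness).  A participant is
eligible when the marks increase strictly with concentration AND the mark
for the 9.4 g/100 g sample lies within a tolerance of the ideal center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "VASResponse",
    "ScreeningDecision",
    "screen_participant",
    "screen_table",
    "SUCROSE_CONCENTRATIONS",
    "REFERENCE_CONCENTRATION",
]

SUCROSE_CONCENTRATIONS = (4.7, 7.05, 9.4, 11.75, 14.1)  # g / 100 g
REFERENCE_CONCENTRATION = 9.4
SCALE_CM = 9.0


class ScreeningError(ValueError):
    """Raised for malformed VAS responses."""


@dataclass(frozen=True)
class VASResponse:
    """One participant's marks: (concentration g/100 g, mark position cm)."""

    responses: tuple[tuple[float, float], ...]
    participant_id: str

    def __post_init__(self) -> None:
        concentrations = [c for c, _ in self.responses]
        missing = set(SUCROSE_CONCENTRATIONS) - set(concentrations)
        if missing:
            raise ScreeningError(
                f"participant {self.participant_id}: missing concentrations "
                f"{sorted(missing)}"
            )
        if len(set(concentrations)) != len(concentrations):
            raise ScreeningError(
                f"participant {self.participant_id}: duplicate concentrations"
            )
        for c, mark in self.responses:
            if not (0.0 <= mark <= SCALE_CM):
                raise ScreeningError(
                    f"participant {self.participant_id}: mark {mark} cm outside "
                    f"[0, {SCALE_CM}]"
                )

    def mark(self, concentration: float) -> float:
        for c, m in self.responses:
            if c == concentration:
                return m
        raise ScreeningError(f"no mark for concentration {concentration}")

    def marks_in_concentration_order(self) -> list[float]:
        ordered = sorted(self.responses, key=lambda cm: cm[0])
        return [m for _, m in ordered]


@dataclass(frozen=True)
class ScreeningDecision:
    eligible: bool
    reasons: tuple[str, ...]


def screen_participant(v: VASResponse, ideal_mark: float = 4.5,
                       tolerance: float = 1.0) -> ScreeningDecision:
    """Eligibility: strict ordering of marks by concentration, and the
    reference-concentration mark near the scale center.

    Ties count as ordering failures.  With tolerance = inf the rule reduces
    to ordering only.  The decision depends only on the order pattern and
    the 9.4 g/100 g mark, never on the listing order of the responses.
    """
    reasons: list[str] = []
    marks = v.marks_in_concentration_order()
    if any(b <= a for a, b in zip(marks, marks[1:])):
        reasons.append("ordering criterion: marks not strictly increasing "
                       "with sucrose concentration")
    ref = v.mark(REFERENCE_CONCENTRATION)
    if not math.isinf(tolerance) and abs(ref - ideal_mark) > tolerance:
        reasons.append(
            f"ideal-sweetness criterion: mark for {REFERENCE_CONCENTRATION} "
            f"g/100 g at {ref} cm, more than {tolerance} cm from {ideal_mark} cm"
        )
    return ScreeningDecision(eligible=not reasons, reasons=tuple(reasons))


def screen_table(csv_path: str | Path, ideal_mark: float = 4.5,
                 tolerance: float = 1.0) -> pd.DataFrame:
    """Screen a CSV of (participant_id, concentration, mark) rows; returns
    an eligibility table with one row per participant."""
    df = pd.read_csv(csv_path, dtype={"participant_id": str})
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        response = VASResponse(
            responses=tuple(zip(grp["concentration"], grp["mark"])),
            participant_id=pid,
        )
        decision = screen_participant(response, ideal_mark, tolerance)
        rows.append({
            "participant_id": pid,
            "eligible": decision.eligible,
            "reasons": "; ".join(decision.reasons),
        })
    return pd.DataFrame(rows, columns=["participant_id", "eligible", "reasons"])
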