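"""Clinician-style comparison tables and textual feedback.

Two sign conventions coexist in clinical comparison reports and both are
preserved, labelled on every field, instead of being unified:

* ``range_diff`` — demonstration minus subject (a positive value means the
  subject moved through *less* range than demonstrated);
* ``max_diff`` / ``min_diff`` — user minus ideal (a positive value means
  the user exceeded the ideal extreme).

Rounding is half-away-from-zero, either to the nearest integer (clinical
summary style) or to one decimal (validation-table style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .features import KinematicSummary


@dataclass
class JointComparison:
    joint: str
    range_diff: float        # demo ROM - subject ROM
    max_diff: float          # user theta_max - ideal theta_max
    min_diff: float          # user theta_min - ideal theta_min
    feedback_text: str = ""
    sign_conventions: dict = field(default_factory=lambda: {
        "range_diff": "demo - subject",
        "max_diff": "user - ideal",
        "min_diff": "user - ideal",
    })


@dataclass
class FeedbackReport:
    comparisons: list[JointComparison]
    rounding_mode: str = "integer"   # "integer" | "one_decimal"
    tolerance: float = 5.0
    messages: list[str] = field(default_factory=list)


def round_for_report(value: float, mode: str = "integer") -> float:
    """Half-away-from-zero rounding (so 6.65 -> 6.7, -7.95 -> -8)."""
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite value {value}")
    factor = 1.0 if mode == "integer" else 10.0
    if mode not in ("integer", "one_decimal"):
        raise ValueError(f"unknown rounding mode {mode!r}")
    scaled = abs(value) * factor
    rounded = math.floor(scaled + 0.5) / factor
    out = math.copysign(rounded, value)
    return int(out) if mode == "integer" else out


def _display_name(joint: str) -> str:
    return joint.replace("_", " ").capitalize()


def feedback_text(comparison: JointComparison, tolerance: float = 5.0,
                  mode: str = "integer") -> str:
    """Template feedback from a joint comparison.

    Deviations within the tolerance (boundary inclusive) produce
    "No significant deviation".  A subject maximum exceeding the
    demonstration maximum reads "extending X deg more than demo"; a range
    shortfall reads "flexing X deg less than demo".
    """
    name = _display_name(comparison.joint)
    # range_diff is demo-minus-subject; max_diff is user-minus-ideal
    if comparison.range_diff > tolerance:
        amount = round_for_report(comparison.range_diff, mode)
        return f"{name} flexing {amount}\N{DEGREE SIGN} less than demo"
    if comparison.max_diff > tolerance:
        amount = round_for_report(comparison.max_diff, mode)
        return f"{name} extending {amount}\N{DEGREE SIGN} more than demo"
    return "No significant deviation"


def compare_joint(user: KinematicSummary, ideal: KinematicSummary,
                  joint: str, tolerance: float = 5.0,
                  mode: str = "integer") -> JointComparison:
    """Compare a subject's kinematic summary against the demonstration.

    ``range_diff`` follows the demo-minus-subject convention;
    ``max_diff``/``min_diff`` follow user-minus-ideal.  Feedback text is
    attached per the template rules of :func:`feedback_text`.
    """
    comp = JointComparison(
        joint=joint,
        range_diff=ideal.rom - user.rom,
        max_diff=user.theta_max - ideal.theta_max,
        min_diff=user.theta_min - ideal.theta_min,
    )
    comp.feedback_text = feedback_text(comp, tolerance=tolerance, mode=mode)
    return comp


def rom_deviation_percent(automated: float, clinician: float) -> float:
    """Relative ROM deviation |automated - clinician| / clinician * 100,
    rounded to one decimal for reports."""
    if clinician <= 0:
        raise ValueError(f"clinician ROM must be positive, got {clinician}")
    return round_for_report(abs(automated - clinician) / clinician * 100.0,
                            mode="one_decimal")


def build_report(comparisons: list[JointComparison], tolerance: float = 5.0,
                 mode: str = "integer") -> FeedbackReport:
    """Assemble a deterministic feedback report from joint comparisons."""
    messages = [c.feedback_text for c in comparisons]
    return FeedbackReport(comparisons=comparisons, rounding_mode=mode,
                          tolerance=tolerance, messages=messages)


def comparison_table(report: FeedbackReport) -> "pd.DataFrame":
    """Tabular layout of a feedback report for CSV export."""
    import pandas as pd

    mode = report.rounding_mode
    rows = []
    for c in report.comparisons:
        rows.append({
            "joint": c.joint,
            "range_diff_deg": round_for_report(c.range_diff, mode),
            "max_diff_deg": round_for_report(c.max_diff, mode),
            "min_diff_deg": round_for_report(c.min_diff, mode),
            "feedback": c.feedback_text,
        })
    return pd.DataFrame(rows, columns=["joint", "range_diff_deg",
                                       "max_diff_deg", "min_diff_deg", "feedback"])
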