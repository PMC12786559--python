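"""Outcome-table report generation (two arms plus delta columns).

The report mirrors the standard budget-impact presentation: clinical
rows (persons screened, colonoscopies, detections by stage, NNS, APL
detected, CRC prevented) followed by economic rows (screening,
colonoscopy, treatment, prevention credit, overall total).  Formatted
values follow the table conventions — person counts to the nearest
integer, money totals in USD millions rounded to integers, per-patient
values in whole USD — while the full-precision values are always kept
alongside.  Percentage deltas use the FIT arm as denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import ArmResult
from .params import STAGES

__all__ = ["ReportRow", "outcome_report", "format_report"]


@dataclass(frozen=True)
class ReportRow:
    label: str
    kind: str  # count | money_total | money_per_patient
    fit: float
    ng: float


def _rows(ng: ArmResult, fit: ArmResult) -> list[ReportRow]:
    rows = [
        ReportRow("Patients screened", "count", fit.clinical.patients_screened, ng.clinical.patients_screened),
        ReportRow(
            "Patients with follow-up colonoscopy completed",
            "count",
            fit.clinical.colonoscopies_completed,
            ng.clinical.colonoscopies_completed,
        ),
        ReportRow("Patients with detected CRC", "count", fit.clinical.crc_detected_total, ng.clinical.crc_detected_total),
    ]
    for i, stage in enumerate(STAGES):
        rows.append(
            ReportRow(
                f"Detected CRC, stage {stage}",
                "count",
                fit.clinical.crc_detected_by_stage[i],
                ng.clinical.crc_detected_by_stage[i],
            )
        )
    rows += [
        ReportRow("Number to screen to detect one CRC", "count", fit.clinical.nns_per_crc, ng.clinical.nns_per_crc),
        ReportRow("Patients with detected APL", "count", fit.clinical.apl_detected, ng.clinical.apl_detected),
        ReportRow(
            "CRC prevented through APL detection over 10 years",
            "count",
            fit.clinical.crc_prevented_10yr,
            ng.clinical.crc_prevented_10yr,
        ),
        ReportRow("Cost of screening by stool-test", "money_total", fit.economic.test_cost_total, ng.economic.test_cost_total),
        ReportRow(
            "Cost of follow-up colonoscopy after positive stool-test",
            "money_total",
            fit.economic.colonoscopy_cost_total,
            ng.economic.colonoscopy_cost_total,
        ),
        ReportRow(
            "Total screening cost (initial and follow-up colonoscopy)",
            "money_total",
            fit.economic.screening_cost_total,
            ng.economic.screening_cost_total,
        ),
        ReportRow(
            "Cost of screening per patient screened",
            "money_per_patient",
            fit.economic.screening_cost_per_screened,
            ng.economic.screening_cost_per_screened,
        ),
        ReportRow("Total CRC treatment cost", "money_total", fit.economic.treatment_cost_total, ng.economic.treatment_cost_total),
        ReportRow(
            "Total direct CRC cost per patient screened",
            "money_per_patient",
            fit.economic.direct_cost_per_screened,
            ng.economic.direct_cost_per_screened,
        ),
        ReportRow(
            "Total direct CRC cost per detected CRC",
            "money_per_patient",
            fit.economic.direct_cost_per_detected_crc,
            ng.economic.direct_cost_per_detected_crc,
        ),
        ReportRow(
            "CRC cost saved (prevented through APL detection)",
            "money_total",
            -fit.economic.prevented_cost,
            -ng.economic.prevented_cost,
        ),
        ReportRow(
            "Total direct and avoided cost (overall total)",
            "money_total",
            fit.economic.overall_total_cost,
            ng.economic.overall_total_cost,
        ),
    ]
    return rows


def outcome_report(ng: ArmResult, fit: ArmResult) -> pd.DataFrame:
    """Full-precision outcome table with delta columns (ng − FIT)."""
    rows = _rows(ng, fit)
    df = pd.DataFrame(
        {
            "outcome": [r.label for r in rows],
            "kind": [r.kind for r in rows],
            "fit": [r.fit for r in rows],
            "ng_mtsdna": [r.ng for r in rows],
        }
    )
    df["delta"] = df["ng_mtsdna"] - df["fit"]
    df["delta_pct"] = [
        (ng_v - fit_v) / fit_v * 100.0 if fit_v != 0.0 and math.isfinite(fit_v) else math.nan
        for fit_v, ng_v in zip(df["fit"], df["ng_mtsdna"])
    ]
    return df


def _fmt(value: float, kind: str) -> str:
    if not math.isfinite(value):
        return "undefined"
    if kind == "count":
        return f"{round(value):,}"
    if kind == "money_total":
        return f"USD {round(value / 1e6):,} M"
    return f"USD {round(value):,}"


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Render the report at table precision (counts, USD M, whole USD)."""
    out = pd.DataFrame({"outcome": report["outcome"]})
    for col in ("fit", "ng_mtsdna", "delta"):
        out[col] = [
            _fmt(v, k) for v, k in zip(report[col], report["kind"])
        ]
    out["delta_pct"] = [
        f"{round(p)}%" if math.isfinite(p) else "undefined" for p in report["delta_pct"]
    ]
    return out
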