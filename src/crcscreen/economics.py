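"""Economic ledger: converts a cohort flow into the cost outcome set.

Payer-perspective accounting over a 10-year horizon, undiscounted:

* stool-test billing (per returned kit for ng mt-sDNA, per offered
  person for FIT, plus any per-offered program cost),
* follow-up colonoscopy, priced with polypectomy whenever a lesion
  (CRC, APL, or NAA) is present in the attendee, otherwise without
  (an optional fraction of no-lesion colonoscopies may be billed with
  biopsy via ``fp_biopsy_fraction``),
* CRC treatment: screen-detected cases at their stage-group cost,
  and every undetected prevalent cancer at the symptomatic per-case
  cost (a late-stage-weighted average), since undiagnosed cancers are
  assumed to present clinically within 10 years,
* a prevention credit: treatment cost avoided because removed APLs
  would otherwise have progressed to CRC.

Cancers arising from APLs that were *not* detected are excluded from
the treatment ledger; only detected-APL prevention enters, as a credit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .cohort import CohortFlow
from .params import STAGES, BillingRule, ParameterSet

__all__ = [
    "SymptomaticSource",
    "SymptomaticCosting",
    "EconomicOutcomes",
    "symptomatic_unit_cost",
    "screening_test_cost",
    "colonoscopy_cost",
    "treatment_cost",
    "prevention_credit",
    "summarize_economics",
]


class SymptomaticSource(str, enum.Enum):
    STAGE_DISTRIBUTION = "stage_distribution"
    DIRECT_UNIT_COST = "direct_unit_cost"


def symptomatic_unit_cost(params: ParameterSet) -> float:
    """Per-case treatment cost of a symptomatically detected CRC.

    The stage-group distribution of symptomatic presentation, weighted
    by the stage-group treatment costs.
    """
    costs = params.costs
    return float(
        sum(
            costs.symptomatic_stage_group_distribution[g]
            * costs.treatment_cost_by_stage_group[g]
            for g in costs.treatment_cost_by_stage_group
        )
    )


@dataclass(frozen=True)
class SymptomaticCosting:
    """How a symptomatic (non-screen-detected) CRC case is costed."""

    unit_cost: float
    source: SymptomaticSource

    @classmethod
    def from_params(cls, params: ParameterSet) -> "SymptomaticCosting":
        unit = symptomatic_unit_cost(params)
        lo = min(params.costs.treatment_cost_by_stage_group.values())
        hi = max(params.costs.treatment_cost_by_stage_group.values())
        if not (lo <= unit <= hi):
            raise ValueError(
                f"symptomatic unit cost {unit!r} outside stage-group range [{lo}, {hi}]"
            )
        return cls(unit_cost=unit, source=SymptomaticSource.STAGE_DISTRIBUTION)

    @classmethod
    def from_unit_cost(cls, unit_cost: float) -> "SymptomaticCosting":
        if unit_cost < 0:
            raise ValueError("unit_cost must be >= 0")
        return cls(unit_cost=float(unit_cost), source=SymptomaticSource.DIRECT_UNIT_COST)


@dataclass(frozen=True)
class EconomicOutcomes:
    """Economic outcome set for one arm, in exact USD."""

    test_cost_total: float
    colonoscopy_cost_total: float
    screening_cost_total: float
    screening_cost_per_screened: float
    treatment_cost_total: float
    direct_cost_total: float
    direct_cost_per_screened: float
    direct_cost_per_detected_crc: float
    prevented_cost: float  # credit; reported as a negative row
    overall_total_cost: float


def screening_test_cost(flow: CohortFlow, params: ParameterSet) -> float:
    """Stool-test billing plus any per-offered program cost."""
    costs = params.costs
    if costs.billing_rule is BillingRule.ADHERENT_ONLY:
        billed = flow.screened
    else:
        billed = flow.cohort_size
    return billed * costs.test_unit_cost + flow.cohort_size * costs.program_cost_per_offered


def colonoscopy_cost(flow: CohortFlow, params: ParameterSet) -> float:
    """Follow-up colonoscopy cost with the lesion-based polypectomy rule."""
    costs = params.costs
    lesion_attendees = (
        float(flow.attendees_crc_by_stage.sum()) + flow.attendees_apl + flow.attendees_naa
    )
    fp_poly = flow.attendees_fp * costs.fp_biopsy_fraction
    fp_plain = flow.attendees_fp - fp_poly
    return (
        (lesion_attendees + fp_poly) * costs.colonoscopy_cost_polypectomy
        + fp_plain * costs.colonoscopy_cost_no_polypectomy
    )


def _screen_detected_treatment_cost(flow: CohortFlow, params: ParameterSet) -> float:
    costs = params.costs
    stage_costs = np.array(
        [costs.treatment_cost_by_stage_group[costs.stage_to_group_map[s]] for s in STAGES]
    )
    return float(np.dot(flow.detected_crc_by_stage, stage_costs))


def treatment_cost(
    flow: CohortFlow, params: ParameterSet, symptomatic: SymptomaticCosting | None = None
) -> float:
    """Treatment cost of screen-detected plus symptomatic cancers.

    Undetected prevalent cancers (including those in unscreened persons)
    present symptomatically within the horizon and are costed at the
    symptomatic per-case unit cost.
    """
    if symptomatic is None:
        symptomatic = SymptomaticCosting.from_params(params)
    return (
        _screen_detected_treatment_cost(flow, params)
        + flow.undetected_prevalent_crc * symptomatic.unit_cost
    )


def prevention_credit(
    flow: CohortFlow, params: ParameterSet, symptomatic: SymptomaticCosting | None = None
) -> float:
    """Treatment cost avoided through APL removal.

    Each prevented cancer would have presented symptomatically, so the
    credit values it at the symptomatic per-case cost.
    """
    if symptomatic is None:
        symptomatic = SymptomaticCosting.from_params(params)
    prevented = flow.detected_apl * params.prevalence.apl_to_crc_10yr
    return prevented * symptomatic.unit_cost


def summarize_economics(
    flow: CohortFlow, params: ParameterSet, symptomatic: SymptomaticCosting | None = None
) -> EconomicOutcomes:
    """Fill the full economic ledger for one arm.

    Ratios with a zero denominator (nothing screened, nothing detected)
    are reported as NaN rather than raising.
    """
    if symptomatic is None:
        symptomatic = SymptomaticCosting.from_params(params)
    test_total = screening_test_cost(flow, params)
    colo_total = colonoscopy_cost(flow, params)
    screening_total = test_total + colo_total
    treat_total = treatment_cost(flow, params, symptomatic)
    direct_total = screening_total + treat_total
    prevented = prevention_credit(flow, params, symptomatic)
    detected = flow.detected_crc_total
    return EconomicOutcomes(
        test_cost_total=test_total,
        colonoscopy_cost_total=colo_total,
        screening_cost_total=screening_total,
        screening_cost_per_screened=screening_total / flow.screened
        if flow.screened > 0
        else math.nan,
        treatment_cost_total=treat_total,
        direct_cost_total=direct_total,
        direct_cost_per_screened=direct_total / flow.screened
        if flow.screened > 0
        else math.nan,
        direct_cost_per_detected_crc=direct_total / detected if detected > 0 else math.nan,
        prevented_cost=prevented,
        overall_total_cost=direct_total - prevented,
    )
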