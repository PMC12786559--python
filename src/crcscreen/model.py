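"""One-call evaluation of a screening arm: flow, clinical, and economic outcomes."""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import ClinicalOutcomes, CohortFlow, clinical_summary, run_cohort
from .economics import EconomicOutcomes, SymptomaticCosting, summarize_economics
from .params import ParameterSet

__all__ = ["ArmResult", "run_arm"]


@dataclass(frozen=True)
class ArmResult:
    """Complete model output for one arm at one parameter set."""

    params: ParameterSet
    flow: CohortFlow
    clinical: ClinicalOutcomes
    economic: EconomicOutcomes


def run_arm(params: ParameterSet, symptomatic: SymptomaticCosting | None = None) -> ArmResult:
    """Propagate the cohort and fill both outcome ledgers for one arm."""
    flow = run_cohort(params)
    return ArmResult(
        params=params,
        flow=flow,
        clinical=clinical_summary(flow, params),
        economic=summarize_economics(flow, params, symptomatic),
    )
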