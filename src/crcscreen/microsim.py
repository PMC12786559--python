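"""Individual-level Monte Carlo simulation of the same decision tree.

This is the stochastic oracle for the expected-value cohort engine: each
simulated person takes the identical event sequence with Bernoulli /
multinomial draws — disease state, stool-test completion, test result,
colonoscopy attendance, lesion detection — and accumulates the same cost
items.  Empirical means must converge to the cohort engine's
expectations at n^(-1/2), which makes every deterministic output
testable against an independent stochastic computation.

Draws come from a single ``numpy.random.Generator`` seeded explicitly;
the per-person event order is fixed, so runs are reproducible across
platforms at the same seed.  Persons are independent (no household or
cluster structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ClinicalOutcomes
from .economics import EconomicOutcomes, SymptomaticCosting
from .params import STAGES, BillingRule, ParameterSet

__all__ = [
    "STATE_LABELS",
    "SimulationSummary",
    "simulate",
    "person_records",
    "validate_person_records",
    "compare_to_cohort",
]

#: Disease states in draw order: CRC stages I-IV, APL, NAA, negative.
STATE_LABELS: tuple[str, ...] = ("crc_I", "crc_II", "crc_III", "crc_IV", "apl", "naa", "negative")


@dataclass(frozen=True)
class SimulationSummary:
    """Empirical outcome estimates with standard errors.

    ``estimates`` maps outcome name -> (value, standard error).  Count
    outcomes use the binomial SE; cost totals use the sample SD of the
    per-person cost times sqrt(n).
    """

    n: int
    seed: int
    estimates: dict[str, tuple[float, float]]

    def value(self, name: str) -> float:
        return self.estimates[name][0]

    def se(self, name: str) -> float:
        return self.estimates[name][1]


@dataclass
class _Draws:
    """Raw per-person event arrays from one simulation run."""

    state: np.ndarray  # int index into STATE_LABELS
    screened: np.ndarray
    test_positive: np.ndarray
    colonoscopy: np.ndarray
    lesion_detected: np.ndarray
    would_progress: np.ndarray  # APL that would become CRC if unresected
    test_cost: np.ndarray
    colonoscopy_cost: np.ndarray
    treatment_cost: np.ndarray
    prevented_cost: np.ndarray


def _simulate_draws(
    params: ParameterSet,
    n: int,
    seed: int,
    symptomatic: SymptomaticCosting | None,
) -> _Draws:
    if n <= 0:
        raise ValueError("n must be > 0")
    if symptomatic is None:
        symptomatic = SymptomaticCosting.from_params(params)
    rng = np.random.default_rng(seed)
    prev = params.prevalence
    costs = params.costs

    state_probs = np.array(
        [prev.crc_prevalence * f for f in prev.crc_stage_distribution]
        + [prev.apl_prevalence, prev.naa_prevalence, prev.negative_prevalence]
    )
    state = rng.choice(len(STATE_LABELS), size=n, p=state_probs)

    screened = rng.random(n) < params.adherence.screening_adherence

    # positive-test probability by state; negatives flip at 1 - specificity
    p_pos = np.array(
        list(params.test.sens_crc_by_stage)
        + [params.test.sens_apl, params.test.sens_naa, 1.0 - params.test.specificity]
    )
    test_positive = screened & (rng.random(n) < p_pos[state])

    colonoscopy = test_positive & (rng.random(n) < params.adherence.followup_adherence)

    # detection at colonoscopy: CRC at sens_crc, APL at the size-weighted
    # sensitivity, NAA found with certainty (costing only), negatives never
    p_detect = np.array(
        [params.colonoscopy.sens_crc] * 4
        + [params.colonoscopy.sens_apl_weighted, 1.0, 0.0]
    )
    lesion_detected = colonoscopy & (rng.random(n) < p_detect[state])

    is_crc = state < 4
    is_apl = state == 4
    is_negative = state == 6

    # 10-year progression draw for every APL; only detected ones are credited
    would_progress = is_apl & (rng.random(n) < prev.apl_to_crc_10yr)

    test_cost = np.zeros(n)
    if costs.billing_rule is BillingRule.ADHERENT_ONLY:
        test_cost[screened] = costs.test_unit_cost
    else:
        test_cost[:] = costs.test_unit_cost
    test_cost += costs.program_cost_per_offered

    colo_cost = np.zeros(n)
    lesion_present = colonoscopy & ~is_negative
    colo_cost[lesion_present] = costs.colonoscopy_cost_polypectomy
    fp = colonoscopy & is_negative
    fp_biopsy = fp & (rng.random(n) < costs.fp_biopsy_fraction)
    colo_cost[fp & ~fp_biopsy] = costs.colonoscopy_cost_no_polypectomy
    colo_cost[fp_biopsy] = costs.colonoscopy_cost_polypectomy

    treatment = np.zeros(n)
    stage_cost = np.array(
        [costs.treatment_cost_by_stage_group[costs.stage_to_group_map[s]] for s in STAGES]
    )
    detected_crc = is_crc & lesion_detected
    treatment[detected_crc] = stage_cost[state[detected_crc]]
    # undetected prevalent CRC presents symptomatically: draw a stage group
    undetected_crc = is_crc & ~lesion_detected
    groups = ("localized", "regional", "distant")
    group_probs = np.array([costs.symptomatic_stage_group_distribution[g] for g in groups])
    group_costs = np.array([costs.treatment_cost_by_stage_group[g] for g in groups])
    k = int(undetected_crc.sum())
    if k:
        sympt_groups = rng.choice(3, size=k, p=group_probs)
        treatment[undetected_crc] = group_costs[sympt_groups]

    prevented_cost = np.zeros(n)
    prevented = is_apl & lesion_detected & would_progress
    prevented_cost[prevented] = symptomatic.unit_cost

    return _Draws(
        state=state,
        screened=screened,
        test_positive=test_positive,
        colonoscopy=colonoscopy,
        lesion_detected=lesion_detected,
        would_progress=would_progress,
        test_cost=test_cost,
        colonoscopy_cost=colo_cost,
        treatment_cost=treatment,
        prevented_cost=prevented_cost,
    )


def _count(mask: np.ndarray, n: int, scale: float) -> tuple[float, float]:
    """Scaled count with binomial standard error."""
    x = float(mask.sum())
    p = x / n
    se = math.sqrt(n * p * (1.0 - p))
    return x * scale, se * scale


def _total(per_person: np.ndarray, scale: float) -> tuple[float, float]:
    """Scaled cost total with CLT standard error."""
    n = per_person.size
    total = float(per_person.sum())
    se = float(per_person.std(ddof=1)) * math.sqrt(n) if n > 1 else 0.0
    return total * scale, se * scale


def simulate(
    params: ParameterSet,
    n: int,
    seed: int,
    symptomatic: SymptomaticCosting | None = None,
) -> SimulationSummary:
    """Simulate ``n`` persons and summarize every model outcome.

    Estimates are scaled to the parameter set's cohort size so they are
    directly comparable with the cohort engine's expectations.
    """
    d = _simulate_draws(params, n, seed, symptomatic)
    scale = params.cohort_size / n
    is_crc = d.state < 4
    is_apl = d.state == 4

    est: dict[str, tuple[float, float]] = {}
    est["patients_screened"] = _count(d.screened, n, scale)
    est["colonoscopies_completed"] = _count(d.colonoscopy, n, scale)
    est["crc_detected_total"] = _count(is_crc & d.lesion_detected, n, scale)
    for i, stage in enumerate(STAGES):
        est[f"crc_detected_stage_{stage}"] = _count(
            (d.state == i) & d.lesion_detected, n, scale
        )
    est["apl_detected"] = _count(is_apl & d.lesion_detected, n, scale)
    est["crc_prevented_10yr"] = _count(
        is_apl & d.lesion_detected & d.would_progress, n, scale
    )
    est["undetected_prevalent_crc"] = _count(is_crc & ~d.lesion_detected, n, scale)

    est["test_cost_total"] = _total(d.test_cost, scale)
    est["colonoscopy_cost_total"] = _total(d.colonoscopy_cost, scale)
    est["screening_cost_total"] = _total(d.test_cost + d.colonoscopy_cost, scale)
    est["treatment_cost_total"] = _total(d.treatment_cost, scale)
    est["prevented_cost"] = _total(d.prevented_cost, scale)
    direct = d.test_cost + d.colonoscopy_cost + d.treatment_cost
    est["direct_cost_total"] = _total(direct, scale)
    est["overall_total_cost"] = _total(direct - d.prevented_cost, scale)

    return SimulationSummary(n=n, seed=seed, estimates=est)


def person_records(
    params: ParameterSet,
    n: int,
    seed: int,
    symptomatic: SymptomaticCosting | None = None,
) -> pd.DataFrame:
    """Per-person event log (one row per simulated person) for audit."""
    d = _simulate_draws(params, n, seed, symptomatic)
    return pd.DataFrame(
        {
            "disease_state": [STATE_LABELS[i] for i in d.state],
            "screened": d.screened,
            "test_positive": d.test_positive,
            "colonoscopy": d.colonoscopy,
            "lesion_detected": d.lesion_detected,
            "test_cost": d.test_cost,
            "colonoscopy_cost": d.colonoscopy_cost,
            "treatment_cost": d.treatment_cost,
            "prevented_cost": d.prevented_cost,
        }
    )


def validate_person_records(records: pd.DataFrame) -> None:
    """Check the event implication chain on a per-person log.

    lesion_detected => colonoscopy => test_positive => screened.
    Raises ``ValueError`` on any violation.
    """
    chain = ("lesion_detected", "colonoscopy", "test_positive", "screened")
    for narrower, wider in zip(chain, chain[1:]):
        bad = records[narrower] & ~records[wider]
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} person(s) have {narrower} without {wider}"
            )


def compare_to_cohort(
    summary: SimulationSummary,
    clinical: ClinicalOutcomes,
    economic: EconomicOutcomes,
    z_threshold: float = 4.0,
) -> pd.DataFrame:
    """z-score every shared outcome against the cohort expectations.

    Returns a frame with columns (outcome, expected, simulated, se, z,
    flagged); ``flagged`` marks |z| above ``z_threshold``.  Outcomes
    with zero Monte Carlo SE (deterministic under the parameter set)
    get z = 0 when they match exactly and infinity otherwise.
    """
    expected: dict[str, float] = {
        "patients_screened": clinical.patients_screened,
        "colonoscopies_completed": clinical.colonoscopies_completed,
        "crc_detected_total": clinical.crc_detected_total,
        "apl_detected": clinical.apl_detected,
        "crc_prevented_10yr": clinical.crc_prevented_10yr,
        "test_cost_total": economic.test_cost_total,
        "colonoscopy_cost_total": economic.colonoscopy_cost_total,
        "screening_cost_total": economic.screening_cost_total,
        "treatment_cost_total": economic.treatment_cost_total,
        "prevented_cost": economic.prevented_cost,
        "direct_cost_total": economic.direct_cost_total,
        "overall_total_cost": economic.overall_total_cost,
    }
    for stage, value in zip(STAGES, clinical.crc_detected_by_stage):
        expected[f"crc_detected_stage_{stage}"] = value

    rows = []
    for name, exp in expected.items():
        sim, se = summary.estimates[name]
        if se > 1e-9 * max(1.0, abs(sim)):
            z = (sim - exp) / se
        elif math.isclose(sim, exp, rel_tol=1e-9, abs_tol=1e-6):
            # deterministic under these parameters (e.g. constant per-person
            # cost) and matching exactly
            z = 0.0
        elif sim == 0.0 and exp != 0.0:
            # no events observed at this n: the empirical SE is degenerate
            # and carries no information, so the outcome cannot be judged
            z = math.nan
        else:
            z = math.inf
        rows.append((name, exp, sim, se, z, abs(z) > z_threshold))
    return pd.DataFrame(
        rows, columns=["outcome", "expected", "simulated", "se", "z", "flagged"]
    )
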