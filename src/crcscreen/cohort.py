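"""Expected-value propagation of the cohort through the screening decision tree.

One round of screening is a fixed event sequence: disease-state
partition -> stool-test completion (screening adherence) -> test result
(state-specific sensitivity / specificity) -> follow-up colonoscopy
attendance -> lesion detection at colonoscopy.  Counts are continuous
expected persons; nothing is rounded until report formatting.

Disease states are prevalent CRC at stages I-IV, advanced precancerous
lesion (APL), non-advanced adenoma (NAA), and no neoplastic finding
("negative").  Cancers not detected in this round — unscreened persons,
false negatives, positives who skip colonoscopy, and colonoscopy misses
— are assumed to present symptomatically within the 10-year horizon.
Detected APLs are removed; a fixed fraction of them would otherwise have
progressed to CRC within 10 years, which is the prevention ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import STAGES, ParameterSet

__all__ = [
    "CohortFlow",
    "ClinicalOutcomes",
    "partition_cohort",
    "apply_screening_test",
    "apply_followup_colonoscopy",
    "tally_undetected",
    "run_cohort",
    "clinical_summary",
    "flow_to_frame",
]


def _zeros() -> np.ndarray:
    return np.zeros(4)


@dataclass(frozen=True)
class CohortFlow:
    """Expected person-counts at every node of the decision tree.

    Stage-indexed arrays follow :data:`crcscreen.params.STAGES` order.
    Counts are expected values and therefore fractional.
    """

    cohort_size: float
    screened: float = 0.0
    not_screened: float = 0.0
    # among screened, by disease state
    present_crc_by_stage: np.ndarray = field(default_factory=_zeros)
    present_apl: float = 0.0
    present_naa: float = 0.0
    present_negative: float = 0.0
    # screen positives
    positives_crc_by_stage: np.ndarray = field(default_factory=_zeros)
    positives_apl: float = 0.0
    positives_naa: float = 0.0
    positives_fp: float = 0.0
    # follow-up colonoscopy attendees
    attendees_crc_by_stage: np.ndarray = field(default_factory=_zeros)
    attendees_apl: float = 0.0
    attendees_naa: float = 0.0
    attendees_fp: float = 0.0
    # colonoscopy findings
    detected_crc_by_stage: np.ndarray = field(default_factory=_zeros)
    detected_apl: float = 0.0
    # cohort-wide residuals (unscreened + false negative + non-attendee + miss)
    undetected_prevalent_crc: float = math.nan
    undetected_apl: float = math.nan

    @property
    def detected_crc_total(self) -> float:
        return float(self.detected_crc_by_stage.sum())

    @property
    def detected_naa_attendees(self) -> float:
        """NAA attendees; tracked for polypectomy costing only."""
        return self.attendees_naa

    @property
    def fp_attendees(self) -> float:
        return self.attendees_fp

    @property
    def colonoscopies_completed(self) -> float:
        return float(
            self.attendees_crc_by_stage.sum()
            + self.attendees_apl
            + self.attendees_naa
            + self.attendees_fp
        )

    @property
    def present_total(self) -> float:
        return float(
            self.present_crc_by_stage.sum()
            + self.present_apl
            + self.present_naa
            + self.present_negative
        )


@dataclass(frozen=True)
class ClinicalOutcomes:
    """Clinical summary of one arm (expected values, unrounded)."""

    patients_screened: float
    colonoscopies_completed: float
    crc_detected_total: float
    crc_detected_by_stage: tuple[float, float, float, float]
    nns_per_crc: float
    apl_detected: float
    crc_prevented_10yr: float


def partition_cohort(params: ParameterSet) -> CohortFlow:
    """Split the cohort by screening completion and disease state."""
    prev = params.prevalence
    screened = params.cohort_size * params.adherence.screening_adherence
    stage_dist = np.asarray(prev.crc_stage_distribution)
    return CohortFlow(
        cohort_size=params.cohort_size,
        screened=screened,
        not_screened=params.cohort_size - screened,
        present_crc_by_stage=screened * prev.crc_prevalence * stage_dist,
        present_apl=screened * prev.apl_prevalence,
        present_naa=screened * prev.naa_prevalence,
        present_negative=screened * prev.negative_prevalence,
    )


def apply_screening_test(flow: CohortFlow, params: ParameterSet) -> CohortFlow:
    """Apply state-specific stool-test sensitivity and specificity."""
    test = params.test
    return replace(
        flow,
        positives_crc_by_stage=flow.present_crc_by_stage
        * np.asarray(test.sens_crc_by_stage),
        positives_apl=flow.present_apl * test.sens_apl,
        positives_naa=flow.present_naa * test.sens_naa,
        positives_fp=flow.present_negative * (1.0 - test.specificity),
    )


def apply_followup_colonoscopy(flow: CohortFlow, params: ParameterSet) -> CohortFlow:
    """Attendance at diagnostic colonoscopy and lesion detection there.

    Colonoscopy sensitivity applies to screen-positive attendees only;
    test negatives and non-attendees cannot be detected in this round.
    """
    fu = params.adherence.followup_adherence
    colo = params.colonoscopy
    attendees_crc = flow.positives_crc_by_stage * fu
    attendees_apl = flow.positives_apl * fu
    return replace(
        flow,
        attendees_crc_by_stage=attendees_crc,
        attendees_apl=attendees_apl,
        attendees_naa=flow.positives_naa * fu,
        attendees_fp=flow.positives_fp * fu,
        detected_crc_by_stage=attendees_crc * colo.sens_crc,
        detected_apl=attendees_apl * colo.sens_apl_weighted,
    )


def tally_undetected(flow: CohortFlow, params: ParameterSet) -> CohortFlow:
    """Close the conservation ledger over the whole cohort.

    Everything prevalent that was not screen-detected — in unscreened
    persons, false negatives, positive non-attendees, or colonoscopy
    misses — remains undetected this round.
    """
    prev = params.prevalence
    total_crc = params.cohort_size * prev.crc_prevalence
    total_apl = params.cohort_size * prev.apl_prevalence
    return replace(
        flow,
        undetected_prevalent_crc=total_crc - flow.detected_crc_total,
        undetected_apl=total_apl - flow.detected_apl,
    )


def run_cohort(params: ParameterSet) -> CohortFlow:
    """Run the full decision tree for one arm."""
    flow = partition_cohort(params)
    flow = apply_screening_test(flow, params)
    flow = apply_followup_colonoscopy(flow, params)
    return tally_undetected(flow, params)


def clinical_summary(flow: CohortFlow, params: ParameterSet) -> ClinicalOutcomes:
    """Collapse a completed flow to the clinical outcome set.

    The number needed to screen (NNS) is patients screened per detected
    CRC; with zero detections it is reported as infinity.  CRC prevented
    over 10 years is detected APL times the APL-to-CRC transition
    probability.
    """
    detected_total = flow.detected_crc_total
    nns = flow.screened / detected_total if detected_total > 0 else math.inf
    return ClinicalOutcomes(
        patients_screened=flow.screened,
        colonoscopies_completed=flow.colonoscopies_completed,
        crc_detected_total=detected_total,
        crc_detected_by_stage=tuple(float(x) for x in flow.detected_crc_by_stage),
        nns_per_crc=nns,
        apl_detected=flow.detected_apl,
        crc_prevented_10yr=flow.detected_apl * params.prevalence.apl_to_crc_10yr,
    )


def flow_to_frame(flow: CohortFlow) -> pd.DataFrame:
    """Tidy (node, state, stage, persons) audit export of a flow."""
    rows: list[tuple[str, str, str, float]] = [
        ("offered", "any", "", flow.cohort_size),
        ("screened", "any", "", flow.screened),
        ("not_screened", "any", "", flow.not_screened),
    ]
    stage_nodes = {
        "present": flow.present_crc_by_stage,
        "positive": flow.positives_crc_by_stage,
        "colonoscopy": flow.attendees_crc_by_stage,
        "detected": flow.detected_crc_by_stage,
    }
    for node, arr in stage_nodes.items():
        for stage, count in zip(STAGES, arr):
            rows.append((node, "crc", stage, float(count)))
    rows += [
        ("present", "apl", "", flow.present_apl),
        ("present", "naa", "", flow.present_naa),
        ("present", "negative", "", flow.present_negative),
        ("positive", "apl", "", flow.positives_apl),
        ("positive", "naa", "", flow.positives_naa),
        ("positive", "negative", "", flow.positives_fp),
        ("colonoscopy", "apl", "", flow.attendees_apl),
        ("colonoscopy", "naa", "", flow.attendees_naa),
        ("colonoscopy", "negative", "", flow.attendees_fp),
        ("detected", "apl", "", flow.detected_apl),
        ("undetected", "crc", "", flow.undetected_prevalent_crc),
        ("undetected", "apl", "", flow.undetected_apl),
    ]
    return pd.DataFrame(rows, columns=["node", "state", "stage", "persons"])
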