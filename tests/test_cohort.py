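"""Cohort decision-tree propagation: node counts, conservation, monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcscreen import default_parameters, run_cohort, clinical_summary
from crcscreen.cohort import (
    apply_followup_colonoscopy,
    apply_screening_test,
    flow_to_frame,
    partition_cohort,
    tally_undetected,
)


def _with(params, **updates):
    data = params.model_dump(mode="json")
    for dotted, value in updates.items():
        node = data
        parts = dotted.split("__")
        for p in parts[:-1]:
            node = node[p]
        node[parts[-1]] = value
    return type(params).model_validate(data)


class TestPartition:
    def test_screened_counts(self, ng_params, fit_params):
        assert partition_cohort(ng_params).screened == pytest.approx(713_000)
        assert partition_cohort(fit_params).screened == pytest.approx(321_000)

    def test_zero_adherence_empties_tree(self, ng_params):
        p = _with(ng_params, adherence__screening_adherence=0.0)
        flow = partition_cohort(p)
        assert flow.screened == 0
        assert flow.present_total == 0

    def test_states_sum_to_screened(self, fit_params):
        flow = partition_cohort(fit_params)
        assert flow.present_total == pytest.approx(flow.screened, rel=1e-12)


class TestScreeningTest:
    def test_false_positives_hand_computed(self, ng_params):
        # 713,000 × (1 − 0.0045 − 0.104 − 0.344) × (1 − 0.927)
        flow = apply_screening_test(partition_cohort(ng_params), ng_params)
        assert flow.positives_fp == pytest.approx(713_000 * 0.5475 * 0.073, rel=1e-9)
        assert flow.positives_fp == pytest.approx(28_497, abs=1.0)

    def test_perfect_specificity_no_false_positives(self, ng_params):
        p = _with(ng_params, test__specificity=1.0)
        flow = apply_screening_test(partition_cohort(p), p)
        assert flow.positives_fp == 0

    def test_perfect_sensitivity_positives_equal_present(self, fit_params):
        p = _with(
            fit_params,
            test__sens_crc_by_stage=[1.0, 1.0, 1.0, 1.0],
            test__sens_apl=1.0,
            test__sens_naa=1.0,
        )
        flow = apply_screening_test(partition_cohort(p), p)
        np.testing.assert_allclose(flow.positives_crc_by_stage, flow.present_crc_by_stage)
        assert flow.positives_apl == pytest.approx(flow.present_apl)
        assert flow.positives_naa == pytest.approx(flow.present_naa)


class TestFollowupColonoscopy:
    def test_colonoscopies_completed_near_published(self, ng_params, fit_params):
        for params, published in ((ng_params, 72_604), (fit_params, 10_702)):
            flow = run_cohort(params)
            assert flow.colonoscopies_completed == pytest.approx(published, rel=5e-3)

    def test_detected_crc_near_published(self, ng_params):
        assert run_cohort(ng_params).detected_crc_total == pytest.approx(2235, abs=1.0)

    def test_zero_followup_adherence(self, ng_params):
        p = _with(ng_params, adherence__followup_adherence=0.0)
        flow = run_cohort(p)
        assert flow.colonoscopies_completed == 0
        assert flow.detected_crc_total == 0
        assert flow.detected_apl == 0


class TestUndetectedLedger:
    def test_conservation_identity(self, ng_params):
        flow = run_cohort(ng_params)
        total_crc = ng_params.cohort_size * ng_params.prevalence.crc_prevalence
        assert flow.undetected_prevalent_crc == pytest.approx(
            total_crc - flow.detected_crc_total, rel=1e-12
        )
        assert flow.undetected_prevalent_crc == pytest.approx(4500 - 2234.16, abs=0.5)

    def test_zero_screening_leaves_all_prevalent_undetected(self, ng_params):
        p = _with(ng_params, adherence__screening_adherence=0.0)
        assert run_cohort(p).undetected_prevalent_crc == pytest.approx(4500)

    def test_perfect_chain_leaves_only_colonoscopy_misses(self, ng_params):
        p = _with(
            ng_params,
            adherence__screening_adherence=1.0,
            adherence__followup_adherence=1.0,
            test__sens_crc_by_stage=[1.0, 1.0, 1.0, 1.0],
        )
        # 4500 × (1 − 0.95): only colonoscopy misses remain
        assert run_cohort(p).undetected_prevalent_crc == pytest.approx(225.0)


class TestClinicalSummary:
    def test_published_rows(self, ng_params, fit_params):
        ng = clinical_summary(run_cohort(ng_params), ng_params)
        fit = clinical_summary(run_cohort(fit_params), fit_params)
        assert ng.crc_prevented_10yr == pytest.approx(1856, rel=5e-3)
        assert fit.crc_prevented_10yr == pytest.approx(263, rel=5e-3)
        assert round(fit.nns_per_crc) == 737
        assert round(ng.nns_per_crc) == 319

    def test_zero_detection_reports_infinite_nns(self, ng_params):
        p = _with(ng_params, adherence__followup_adherence=0.0)
        out = clinical_summary(run_cohort(p), p)
        assert math.isinf(out.nns_per_crc)
        assert out.crc_prevented_10yr == 0


# -- properties -------------------------------------------------------------

_prob = st.floats(0.05, 1.0, allow_nan=False)


@settings(max_examples=25, deadline=None)
@given(
    adh=_prob,
    fu=_prob,
    sens_apl=_prob,
    sens_stage=_prob,
    spec=st.floats(0.5, 1.0),
)
def test_detections_monotone_in_adherence_and_sensitivity(adh, fu, sens_apl, sens_stage, spec):
    """Raising any adherence or sensitivity never lowers detections."""
    base = default_parameters("fit")
    p = _with(
        base,
        adherence__screening_adherence=adh,
        adherence__followup_adherence=fu,
        test__sens_apl=sens_apl,
        test__sens_crc_by_stage=[sens_stage] * 4,
        test__specificity=spec,
    )
    flow = run_cohort(p)
    for dotted, bump in [
        ("adherence__screening_adherence", min(1.0, adh * 1.1)),
        ("adherence__followup_adherence", min(1.0, fu * 1.1)),
        ("test__sens_apl", min(1.0, sens_apl * 1.1)),
        ("test__sens_crc_by_stage", [min(1.0, sens_stage * 1.1)] * 4),
    ]:
        bumped = run_cohort(_with(p, **{dotted: bump}))
        assert bumped.detected_crc_total >= flow.detected_crc_total - 1e-9
        assert bumped.detected_apl >= flow.detected_apl - 1e-9


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(0.1, 10.0), adh=_prob, fu=_prob)
def test_scale_equivariance(scale, adh, fu):
    """Doubling the cohort doubles every expected count."""
    base = _with(
        default_parameters("ng_mtsdna"),
        adherence__screening_adherence=adh,
        adherence__followup_adherence=fu,
    )
    scaled = _with(base, cohort_size=base.cohort_size * scale)
    f1, f2 = run_cohort(base), run_cohort(scaled)
    assert f2.screened == pytest.approx(f1.screened * scale, rel=1e-9)
    assert f2.colonoscopies_completed == pytest.approx(
        f1.colonoscopies_completed * scale, rel=1e-9
    )
    assert f2.detected_crc_total == pytest.approx(f1.detected_crc_total * scale, rel=1e-9)
    assert f2.undetected_prevalent_crc == pytest.approx(
        f1.undetected_prevalent_crc * scale, rel=1e-9
    )


@settings(max_examples=20, deadline=None)
@given(adh=_prob, fu=_prob, spec=st.floats(0.5, 1.0))
def test_state_conservation_along_tree(adh, fu, spec):
    """present >= positives >= attendees >= detected for every state, and
    screened + not_screened = cohort."""
    p = _with(
        default_parameters("fit"),
        adherence__screening_adherence=adh,
        adherence__followup_adherence=fu,
        test__specificity=spec,
    )
    flow = run_cohort(p)
    assert flow.screened + flow.not_screened == pytest.approx(p.cohort_size, rel=1e-12)
    assert np.all(flow.present_crc_by_stage + 1e-9 >= flow.positives_crc_by_stage)
    assert np.all(flow.positives_crc_by_stage + 1e-9 >= flow.attendees_crc_by_stage)
    assert np.all(flow.attendees_crc_by_stage + 1e-9 >= flow.detected_crc_by_stage)
    assert flow.present_apl + 1e-9 >= flow.positives_apl >= flow.attendees_apl
    assert flow.attendees_apl + 1e-9 >= flow.detected_apl


def test_flow_frame_is_tidy_audit_export(ng_params):
    df = flow_to_frame(run_cohort(ng_params))
    assert list(df.columns) == ["node", "state", "stage", "persons"]
    assert (df.persons >= 0).all()
    screened = df.query("node == 'screened'").persons.item()
    present = df.query("node == 'present'").persons.sum()
    assert present == pytest.approx(screened, rel=1e-12)
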