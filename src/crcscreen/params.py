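"""Model inputs: validated parameter types and the published default parameter sets.

The model compares two parallel screening arms offered to 1,000,000
average-risk adults: a next-generation multi-target stool DNA test
(ng mt-sDNA) and a fecal immunochemical test (FIT).  Every input —
disease prevalence, per-stage test sensitivity, specificity, real-world
adherence, and unit costs — is a published point estimate; the model is
deterministic given a :class:`ParameterSet`.

Two quantities the defaults need are not published directly and are
recovered by :mod:`crcscreen.calibration`: the stage distribution of
prevalent colorectal cancer (CRC) and the per-case treatment cost of a
symptomatically detected cancer (represented here as a stage-group
distribution).  Their frozen values are documented on the fields below.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Arm",
    "BillingRule",
    "StageGroup",
    "STAGES",
    "STAGE_GROUPS",
    "DiseasePrevalence",
    "TestPerformance",
    "ColonoscopyPerformance",
    "AdherenceProfile",
    "CostInputs",
    "ParameterSet",
    "default_parameters",
    "weighted_apl_colonoscopy_sensitivity",
    "load_parameters",
    "parameters_table",
]

logger = logging.getLogger(__name__)

#: CRC stages modelled (AJCC I-IV), in fixed order.
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

#: SEER-style summary stage groups used for treatment costing.
STAGE_GROUPS: tuple[str, ...] = ("localized", "regional", "distant")

#: Tolerance for a probability distribution to be accepted before normalization.
DIST_TOL = 1e-6


class Arm(str, enum.Enum):
    """Screening arm identifier."""

    NG_MTSDNA = "ng_mtsdna"
    FIT = "fit"


class BillingRule(str, enum.Enum):
    """Who is charged for the stool test kit.

    ``adherent_only``: only returned kits are billed (ng mt-sDNA).
    ``all_offered``: every offered person is billed (FIT).
    """

    ADHERENT_ONLY = "adherent_only"
    ALL_OFFERED = "all_offered"


class StageGroup(str, enum.Enum):
    LOCALIZED = "localized"
    REGIONAL = "regional"
    DISTANT = "distant"


def _check_probability(v: float, name: str) -> float:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    return v


def _normalize_distribution(values: Sequence[float], name: str) -> tuple[float, ...]:
    total = float(sum(values))
    if any(v < 0 for v in values):
        raise ValueError(f"{name} entries must be non-negative, got {values!r}")
    if abs(total - 1.0) > DIST_TOL:
        raise ValueError(
            f"{name} must sum to 1 within {DIST_TOL:g} (got sum={total!r})"
        )
    return tuple(float(v) / total for v in values)


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class DiseasePrevalence(_Frozen):
    """Point prevalence of colorectal neoplasia in the screened population.

    ``crc_stage_distribution`` is the split of prevalent CRC over stages
    I-IV.  The default is recovered by inverting the published
    stage-level detection counts of the ng mt-sDNA arm
    (:func:`crcscreen.calibration.derive_stage_distribution`).
    """

    crc_prevalence: float = Field(description="fraction of cohort with prevalent CRC")
    crc_stage_distribution: tuple[float, float, float, float] = Field(
        description="fractions of prevalent CRC in stages I-IV"
    )
    apl_prevalence: float = Field(
        description="fraction with an advanced precancerous lesion (APL)"
    )
    naa_prevalence: float = Field(description="fraction with a non-advanced adenoma")
    apl_to_crc_10yr: float = Field(
        description="probability an unresected APL becomes CRC within 10 years"
    )

    @field_validator(
        "crc_prevalence", "apl_prevalence", "naa_prevalence", "apl_to_crc_10yr"
    )
    @classmethod
    def _prob(cls, v: float, info) -> float:
        return _check_probability(v, info.field_name)

    @field_validator("crc_stage_distribution")
    @classmethod
    def _dist(cls, v: Sequence[float]) -> tuple[float, ...]:
        return _normalize_distribution(v, "crc_stage_distribution")

    @model_validator(mode="after")
    def _total_prevalence(self) -> "DiseasePrevalence":
        total = self.crc_prevalence + self.apl_prevalence + self.naa_prevalence
        if total > 1.0 + DIST_TOL:
            raise ValueError(
                f"crc + apl + naa prevalence must not exceed 1 (got {total!r})"
            )
        return self

    @property
    def negative_prevalence(self) -> float:
        """Fraction with no neoplastic finding (the remainder state)."""
        return 1.0 - self.crc_prevalence - self.apl_prevalence - self.naa_prevalence


class TestPerformance(_Frozen):
    """Stool-test operating characteristics, per disease state."""

    sens_crc_by_stage: tuple[float, float, float, float] = Field(
        description="sensitivity for CRC at stages I-IV"
    )
    sens_apl: float = Field(description="sensitivity for APL")
    sens_naa: float = Field(description="sensitivity for non-advanced adenoma")
    specificity: float = Field(
        description="probability of a negative result given no neoplastic finding"
    )

    @field_validator("sens_apl", "sens_naa", "specificity")
    @classmethod
    def _prob(cls, v: float, info) -> float:
        return _check_probability(v, info.field_name)

    @field_validator("sens_crc_by_stage")
    @classmethod
    def _probs(cls, v: Sequence[float]) -> tuple[float, ...]:
        return tuple(_check_probability(x, "sens_crc_by_stage") for x in v)


def weighted_apl_colonoscopy_sensitivity(
    apl_size_mix: Iterable[tuple[float, float]]
) -> float:
    """Size-weighted colonoscopy sensitivity for APL.

    ``apl_size_mix`` is a list of ``(size-class prevalence fraction,
    size-class sensitivity)`` pairs; the fractions must sum to 1.
    Returns the prevalence-weighted mean sensitivity.
    """
    mix = [(float(f), float(s)) for f, s in apl_size_mix]
    fractions = [f for f, _ in mix]
    _normalize_distribution(fractions, "apl_size_mix fractions")
    for _, s in mix:
        _check_probability(s, "apl_size_mix sensitivity")
    return float(sum(f * s for f, s in mix))


class ColonoscopyPerformance(_Frozen):
    """Diagnostic colonoscopy performance after a positive stool test."""

    sens_crc: float = Field(description="colonoscopy sensitivity for CRC")
    sens_apl_weighted: float = Field(
        description="APL sensitivity, weighted over lesion-size classes"
    )
    apl_size_mix: tuple[tuple[float, float], ...] = Field(
        description="(size-class prevalence, size-class sensitivity) pairs"
    )

    @field_validator("sens_crc", "sens_apl_weighted")
    @classmethod
    def _prob(cls, v: float, info) -> float:
        return _check_probability(v, info.field_name)

    @model_validator(mode="after")
    def _consistent_weighting(self) -> "ColonoscopyPerformance":
        expected = weighted_apl_colonoscopy_sensitivity(self.apl_size_mix)
        if abs(expected - self.sens_apl_weighted) > 1e-6:
            raise ValueError(
                "sens_apl_weighted must equal the prevalence-weighted mean of the "
                f"size-class sensitivities ({expected!r}), got {self.sens_apl_weighted!r}"
            )
        return self

    @classmethod
    def from_size_mix(
        cls, sens_crc: float, apl_size_mix: Iterable[tuple[float, float]]
    ) -> "ColonoscopyPerformance":
        mix = tuple((float(f), float(s)) for f, s in apl_size_mix)
        return cls(
            sens_crc=sens_crc,
            sens_apl_weighted=weighted_apl_colonoscopy_sensitivity(mix),
            apl_size_mix=mix,
        )


class AdherenceProfile(_Frozen):
    """Real-world adherence along the screening pathway."""

    screening_adherence: float = Field(
        description="probability an offered person completes the stool test"
    )
    followup_adherence: float = Field(
        description="probability a test-positive person completes colonoscopy"
    )

    @field_validator("screening_adherence", "followup_adherence")
    @classmethod
    def _prob(cls, v: float, info) -> float:
        return _check_probability(v, info.field_name)


class CostInputs(_Frozen):
    """Unit costs (2024 USD) and billing conventions."""

    test_unit_cost: float = Field(description="USD per stool-test kit")
    billing_rule: BillingRule = Field(
        description="whether non-returned kits are billed"
    )
    program_cost_per_offered: float = Field(
        default=0.0,
        description="additional program cost per offered person (scenario knob)",
    )
    colonoscopy_cost_no_polypectomy: float = Field(description="USD per colonoscopy")
    colonoscopy_cost_polypectomy: float = Field(
        description="USD per colonoscopy with polypectomy/biopsy"
    )
    treatment_cost_by_stage_group: dict[str, float] = Field(
        description="10-year treatment cost per case by SEER summary stage group"
    )
    stage_to_group_map: dict[str, str] = Field(
        description="mapping from stage I-IV to stage group"
    )
    symptomatic_stage_group_distribution: dict[str, float] = Field(
        description="stage-group mix of symptomatically detected CRC"
    )
    fp_biopsy_fraction: float = Field(
        default=0.0,
        description="fraction of no-lesion colonoscopies billed with biopsy",
    )

    @field_validator(
        "test_unit_cost",
        "program_cost_per_offered",
        "colonoscopy_cost_no_polypectomy",
        "colonoscopy_cost_polypectomy",
    )
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v!r}")
        return v

    @field_validator("fp_biopsy_fraction")
    @classmethod
    def _prob(cls, v: float) -> float:
        return _check_probability(v, "fp_biopsy_fraction")

    @field_validator("treatment_cost_by_stage_group")
    @classmethod
    def _groups(cls, v: Mapping[str, float]) -> dict[str, float]:
        if set(v) != set(STAGE_GROUPS):
            raise ValueError(
                f"treatment_cost_by_stage_group keys must be {STAGE_GROUPS}, got {sorted(v)}"
            )
        for g, c in v.items():
            if c < 0:
                raise ValueError(f"treatment cost for {g} must be >= 0, got {c!r}")
        return dict(v)

    @field_validator("stage_to_group_map")
    @classmethod
    def _stage_map(cls, v: Mapping[str, str]) -> dict[str, str]:
        if set(v) != set(STAGES):
            raise ValueError(f"stage_to_group_map keys must be {STAGES}, got {sorted(v)}")
        for s, g in v.items():
            if g not in STAGE_GROUPS:
                raise ValueError(f"unknown stage group {g!r} for stage {s}")
        return dict(v)

    @field_validator("symptomatic_stage_group_distribution")
    @classmethod
    def _sympt_dist(cls, v: Mapping[str, float]) -> dict[str, float]:
        if set(v) != set(STAGE_GROUPS):
            raise ValueError(
                "symptomatic_stage_group_distribution keys must be "
                f"{STAGE_GROUPS}, got {sorted(v)}"
            )
        norm = _normalize_distribution(
            [v[g] for g in STAGE_GROUPS], "symptomatic_stage_group_distribution"
        )
        return dict(zip(STAGE_GROUPS, norm))


class ParameterSet(_Frozen):
    """Complete inputs for one screening arm."""

    arm_label: str
    cohort_size: float = Field(gt=0, description="persons offered screening")
    prevalence: DiseasePrevalence
    test: TestPerformance
    colonoscopy: ColonoscopyPerformance
    adherence: AdherenceProfile
    costs: CostInputs


# ---------------------------------------------------------------------------
# Published default parameter sets
# ---------------------------------------------------------------------------

# Stage distribution of prevalent CRC, recovered once by
# calibration.derive_stage_distribution from the ng arm's published
# stage-level detections (639, 377, 871, 348) and frozen here.
DEFAULT_CRC_STAGE_DISTRIBUTION = (0.30886946, 0.17261654, 0.37048867, 0.14802533)

# Stage-group mix of symptomatically detected CRC.  With the published
# stage-group treatment costs this mix implies a per-case cost of
# ~USD 329,880, consistent (within 0.1%) with the three independent
# estimates produced by calibration.derive_symptomatic_unit_cost.
DEFAULT_SYMPTOMATIC_STAGE_GROUP_DISTRIBUTION = {
    "localized": 0.37,
    "regional": 0.39,
    "distant": 0.24,
}

# APL size-class mix and per-class colonoscopy sensitivity:
# <6 mm (1.3%, 75%), 6-<10 mm (7.4%, 85%), >=10 mm (91.3%, 95%).
DEFAULT_APL_SIZE_MIX = ((0.013, 0.75), (0.074, 0.85), (0.913, 0.95))

_SHARED_DEFAULTS = dict(
    cohort_size=1_000_000,
    prevalence=dict(
        crc_prevalence=0.0045,
        crc_stage_distribution=DEFAULT_CRC_STAGE_DISTRIBUTION,
        apl_prevalence=0.104,
        naa_prevalence=0.344,
        apl_to_crc_10yr=0.08,
    ),
    colonoscopy=dict(
        sens_crc=0.95,
        sens_apl_weighted=weighted_apl_colonoscopy_sensitivity(DEFAULT_APL_SIZE_MIX),
        apl_size_mix=DEFAULT_APL_SIZE_MIX,
    ),
)

_COST_SHARED = dict(
    colonoscopy_cost_no_polypectomy=1602.0,
    colonoscopy_cost_polypectomy=2223.0,
    treatment_cost_by_stage_group={
        "localized": 174_362.0,
        "regional": 375_526.0,
        "distant": 495_464.0,
    },
    stage_to_group_map={"I": "localized", "II": "localized", "III": "regional", "IV": "distant"},
    symptomatic_stage_group_distribution=DEFAULT_SYMPTOMATIC_STAGE_GROUP_DISTRIBUTION,
    fp_biopsy_fraction=0.0,
)

_ARM_DEFAULTS: dict[Arm, dict] = {
    Arm.NG_MTSDNA: dict(
        arm_label="ng mt-sDNA",
        test=dict(
            sens_crc_by_stage=(0.88, 0.929, 1.0, 1.0),
            sens_apl=0.433,
            sens_naa=0.125,
            specificity=0.927,
        ),
        adherence=dict(screening_adherence=0.713, followup_adherence=0.771),
        costs=dict(
            test_unit_cost=591.92,
            billing_rule=BillingRule.ADHERENT_ONLY,
            **_COST_SHARED,
        ),
    ),
    Arm.FIT: dict(
        arm_label="FIT",
        test=dict(
            sens_crc_by_stage=(0.56, 0.786, 0.733, 0.833),
            sens_apl=0.233,
            sens_naa=0.067,
            specificity=0.957,
        ),
        adherence=dict(screening_adherence=0.321, followup_adherence=0.451),
        costs=dict(
            test_unit_cost=18.05,
            billing_rule=BillingRule.ALL_OFFERED,
            **_COST_SHARED,
        ),
    ),
}


def default_parameters(arm: Arm | str) -> ParameterSet:
    """Return the published default :class:`ParameterSet` for one arm."""
    arm = Arm(arm)
    payload = {**_SHARED_DEFAULTS, **_ARM_DEFAULTS[arm]}
    return ParameterSet.model_validate(payload)


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------


def _deep_merge(base: dict, override: Mapping, path: str = "") -> dict:
    merged = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ValueError(f"unknown parameter key {here!r}")
        if isinstance(value, Mapping) and isinstance(base[key], Mapping):
            merged[key] = _deep_merge(dict(base[key]), value, here)
        else:
            logger.info("parameter override: %s = %r (default %r)", here, value, base[key])
            merged[key] = value
    return merged


def _expand_dotted(data: Mapping) -> dict:
    """Allow flat ``a.b.c: value`` keys alongside nested mappings."""
    out: dict = {}
    for key, value in data.items():
        parts = str(key).split(".")
        node = out
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        leaf = value
        if isinstance(value, Mapping):
            leaf = _expand_dotted(value)
        if isinstance(node.get(parts[-1]), dict) and isinstance(leaf, dict):
            node[parts[-1]] = _deep_merge_free(node[parts[-1]], leaf)
        else:
            node[parts[-1]] = leaf
    return out


def _deep_merge_free(a: dict, b: Mapping) -> dict:
    out = dict(a)
    for k, v in b.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _deep_merge_free(dict(out[k]), v)
        else:
            out[k] = v
    return out


def load_parameters(path: str | Path, arm: Arm | str | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML/JSON config file.

    The file may set ``arm`` (``ng_mtsdna`` or ``fit``) and override any
    subset of fields, either nested or with dotted keys
    (``adherence.screening_adherence: 0.5``).  Omitted fields fall back
    to the arm defaults; unknown keys and out-of-range values raise a
    descriptive :class:`ValueError` / validation error.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} must contain a mapping, got {type(raw).__name__}")
    raw = _expand_dotted(raw)
    file_arm = raw.pop("arm", None)
    if arm is None:
        arm = file_arm
    if arm is None:
        raise ValueError(f"config {path} does not name an arm and none was given")
    defaults = {**_SHARED_DEFAULTS, **_ARM_DEFAULTS[Arm(arm)]}
    # normalize defaults to plain nested dicts for merging
    defaults = json.loads(ParameterSet.model_validate(defaults).model_dump_json())
    merged = _deep_merge(defaults, raw)
    return ParameterSet.model_validate(merged)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_UNITS = {
    "cohort_size": "persons",
    "test_unit_cost": "USD/kit",
    "program_cost_per_offered": "USD/person",
    "colonoscopy_cost_no_polypectomy": "USD",
    "colonoscopy_cost_polypectomy": "USD",
    "treatment_cost_by_stage_group": "USD/case",
}

_SOURCES = {
    "prevalence.crc_prevalence": "FDA SSED (BLUE-C)",
    "prevalence.apl_prevalence": "FDA SSED (BLUE-C)",
    "prevalence.naa_prevalence": "FDA SSED (BLUE-C)",
    "prevalence.crc_stage_distribution": "calibrated (stage-detection inversion)",
    "prevalence.apl_to_crc_10yr": "Stryker et al. 1987",
    "test": "FDA SSED (BLUE-C)",
    "colonoscopy": "USPSTF modelling reports",
    "adherence": "real-world adherence studies",
    "costs.test_unit_cost": "CMS lab fee schedule",
    "costs.colonoscopy_cost_no_polypectomy": "commercial/Medicare weighted",
    "costs.colonoscopy_cost_polypectomy": "commercial/Medicare weighted",
    "costs.treatment_cost_by_stage_group": "Fitch et al. 2015, inflated",
    "costs.symptomatic_stage_group_distribution": "calibrated (ledger inversion)",
}


def _source_for(path: str) -> str:
    for prefix in sorted(_SOURCES, key=len, reverse=True):
        if path == prefix or path.startswith(prefix + "."):
            return _SOURCES[prefix]
    return ""


def parameters_table(params: ParameterSet) -> pd.DataFrame:
    """Flatten a parameter set to a tidy (field, value, unit, source) table."""
    rows: list[dict] = []

    def walk(obj, path: str) -> None:
        if isinstance(obj, Mapping):
            for k, v in obj.items():
                walk(v, f"{path}.{k}" if path else str(k))
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                walk(v, f"{path}[{i}]")
        else:
            leaf = path.split(".")[-1].split("[")[0]
            rows.append(
                {
                    "field": path,
                    "value": obj.value if isinstance(obj, enum.Enum) else obj,
                    "unit": _UNITS.get(leaf, ""),
                    "source": _source_for(path),
                }
            )

    walk(params.model_dump(mode="json"), "")
    return pd.DataFrame(rows, columns=["field", "value", "unit", "source"])
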