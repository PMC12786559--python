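"""Deterministic scenario analyses and the break-even adherence search.

Three scenario families are implemented:

* a one-way ±10% sweep over the model's input parameters (tornado-style:
  one input at a time, per arm for arm-specific inputs),
* FIT adherence uplift scenarios (+20/40/60%, multiplicative on the
  real-world adherence values, per knob and jointly), and
* FIT program-cost scenarios (a per-offered-person program cost of
  USD 20-100 added to the FIT arm).

plus a bisection search for the smallest FIT adherence multiplier at
which the FIT arm's overall total cost falls to the ng mt-sDNA arm's.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import ArmResult, run_arm
from .params import Arm, ParameterSet

__all__ = [
    "Transform",
    "AdherenceKnob",
    "ScenarioSpec",
    "ScenarioResult",
    "apply_scenario",
    "run_scenario",
    "one_way_sweep",
    "DEFAULT_ONE_WAY_PARAMETERS",
    "fit_adherence_scenarios",
    "fit_program_cost_scenarios",
    "breakeven_adherence_multiplier",
    "results_to_frame",
]


class Transform(str, enum.Enum):
    MULTIPLY = "multiply"
    SET = "set"
    ADD = "add"


class AdherenceKnob(str, enum.Enum):
    SCREENING = "screening"
    FOLLOWUP = "followup"
    JOINT = "joint"


@dataclass(frozen=True)
class ScenarioSpec:
    """One parameter perturbation, applied to one or both arms."""

    label: str
    parameter_path: str  # dotted, e.g. "adherence.screening_adherence"
    transform: Transform
    value: float
    arms: tuple[str, ...] = (Arm.NG_MTSDNA.value, Arm.FIT.value)


@dataclass(frozen=True)
class ScenarioResult:
    """Both arms' outcomes under one scenario."""

    spec: ScenarioSpec
    ng: ArmResult
    fit: ArmResult

    @property
    def overall_delta(self) -> float:
        """ng minus FIT overall total cost, USD (negative = ng cost-saving)."""
        return self.ng.economic.overall_total_cost - self.fit.economic.overall_total_cost


def _get_path(data: dict, parts: Sequence[str], full: str):
    node = data
    for p in parts:
        if not isinstance(node, dict) or p not in node:
            raise KeyError(f"parameter path {full!r} not found (at {p!r})")
        node = node[p]
    return node


def _set_path(data: dict, parts: Sequence[str], value, full: str) -> None:
    node = data
    for p in parts[:-1]:
        if not isinstance(node, dict) or p not in node:
            raise KeyError(f"parameter path {full!r} not found (at {p!r})")
        node = node[p]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise KeyError(f"parameter path {full!r} not found (at {parts[-1]!r})")
    node[parts[-1]] = value


#: Dotted-path prefixes whose leaves are probabilities (cap at 1 on overshoot).
_PROBABILITY_PREFIXES = (
    "adherence.",
    "prevalence.",
    "test.",
    "colonoscopy.sens",
    "costs.fp_biopsy_fraction",
)


def _is_probability_path(path: str) -> bool:
    return any(path.startswith(p) for p in _PROBABILITY_PREFIXES)


def apply_scenario(params: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a new parameter set with the spec's perturbation applied.

    A transform that pushes a probability above 1 is capped at 1 with a
    warning, mirroring saturation of an adherence or sensitivity.
    """
    data = params.model_dump(mode="json")
    parts = spec.parameter_path.split(".")
    old = _get_path(data, parts, spec.parameter_path)
    if not isinstance(old, (int, float)) or isinstance(old, bool):
        raise TypeError(
            f"parameter path {spec.parameter_path!r} is not numeric (got {old!r})"
        )
    if spec.transform is Transform.MULTIPLY:
        new = old * spec.value
    elif spec.transform is Transform.ADD:
        new = old + spec.value
    else:
        new = spec.value
    if _is_probability_path(spec.parameter_path) and new > 1.0:
        warnings.warn(
            f"{spec.parameter_path} transformed to {new:.4f} > 1; capped at 1.0",
            stacklevel=2,
        )
        new = 1.0
    _set_path(data, parts, new, spec.parameter_path)
    return ParameterSet.model_validate(data)


def run_scenario(
    base_ng: ParameterSet, base_fit: ParameterSet, spec: ScenarioSpec
) -> ScenarioResult:
    ng = base_ng
    fit = base_fit
    if Arm.NG_MTSDNA.value in spec.arms:
        ng = apply_scenario(ng, spec)
    if Arm.FIT.value in spec.arms:
        fit = apply_scenario(fit, spec)
    return ScenarioResult(spec=spec, ng=run_arm(ng), fit=run_arm(fit))


#: One-way sweep inputs: (parameter path, arms it applies to).
#: Shared inputs are varied once in both arms simultaneously;
#: arm-specific inputs (test cost, the two adherences) per arm.
DEFAULT_ONE_WAY_PARAMETERS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("prevalence.apl_prevalence", ("ng_mtsdna", "fit")),
    ("prevalence.crc_prevalence", ("ng_mtsdna", "fit")),
    ("prevalence.apl_to_crc_10yr", ("ng_mtsdna", "fit")),
    ("costs.colonoscopy_cost_no_polypectomy", ("ng_mtsdna", "fit")),
    ("costs.colonoscopy_cost_polypectomy", ("ng_mtsdna", "fit")),
    ("costs.test_unit_cost", ("ng_mtsdna",)),
    ("costs.test_unit_cost", ("fit",)),
    ("adherence.screening_adherence", ("ng_mtsdna",)),
    ("adherence.screening_adherence", ("fit",)),
    ("adherence.followup_adherence", ("ng_mtsdna",)),
    ("adherence.followup_adherence", ("fit",)),
    ("costs.treatment_cost_by_stage_group.localized", ("ng_mtsdna", "fit")),
    ("costs.treatment_cost_by_stage_group.regional", ("ng_mtsdna", "fit")),
    ("costs.treatment_cost_by_stage_group.distant", ("ng_mtsdna", "fit")),
)


def one_way_sweep(
    base_ng: ParameterSet,
    base_fit: ParameterSet,
    rel_change: float = 0.10,
    parameter_list: Iterable[tuple[str, tuple[str, ...]]] | None = None,
) -> list[ScenarioResult]:
    """One result per (parameter, ±rel_change), tornado-ready."""
    if rel_change <= -1.0:
        raise ValueError("rel_change must be > -1")
    if parameter_list is None:
        parameter_list = DEFAULT_ONE_WAY_PARAMETERS
    results = []
    for path, arms in parameter_list:
        for sign in (-1.0, +1.0):
            mult = 1.0 + sign * rel_change
            arm_tag = "both" if len(arms) > 1 else Arm(arms[0]).value
            spec = ScenarioSpec(
                label=f"{path} [{arm_tag}] x{mult:g}",
                parameter_path=path,
                transform=Transform.MULTIPLY,
                value=mult,
                arms=tuple(arms),
            )
            results.append(run_scenario(base_ng, base_fit, spec))
    return results


def fit_adherence_scenarios(
    base_ng: ParameterSet,
    base_fit: ParameterSet,
    multipliers: Sequence[float] = (1.2, 1.4, 1.6),
) -> list[ScenarioResult]:
    """FIT adherence uplift: each knob separately, then both jointly.

    Multipliers act on the real-world FIT adherence values; the ng arm
    stays at its base.  The joint scenarios are labelled
    ``fit adherence (joint) x<m>``.
    """
    results = []
    for m in multipliers:
        for path in ("adherence.screening_adherence", "adherence.followup_adherence"):
            spec = ScenarioSpec(
                label=f"fit {path.split('.')[1]} x{m:g}",
                parameter_path=path,
                transform=Transform.MULTIPLY,
                value=m,
                arms=("fit",),
            )
            results.append(run_scenario(base_ng, base_fit, spec))
        # joint: both knobs multiplied together
        spec = ScenarioSpec(
            label=f"fit adherence (joint) x{m:g}",
            parameter_path="adherence.screening_adherence",
            transform=Transform.MULTIPLY,
            value=m,
            arms=("fit",),
        )
        fit = apply_scenario(base_fit, spec)
        fit = apply_scenario(
            fit,
            ScenarioSpec(
                label=spec.label,
                parameter_path="adherence.followup_adherence",
                transform=Transform.MULTIPLY,
                value=m,
                arms=("fit",),
            ),
        )
        results.append(ScenarioResult(spec=spec, ng=run_arm(base_ng), fit=run_arm(fit)))
    return results


def fit_program_cost_scenarios(
    base_ng: ParameterSet,
    base_fit: ParameterSet,
    program_costs: Sequence[float] = (20.0, 40.0, 60.0, 80.0, 100.0),
) -> list[ScenarioResult]:
    """Add a per-offered-person program cost to the FIT arm."""
    results = []
    for cost in program_costs:
        if cost < 0:
            raise ValueError("program cost must be >= 0")
        spec = ScenarioSpec(
            label=f"fit program cost USD {cost:g}",
            parameter_path="costs.program_cost_per_offered",
            transform=Transform.SET,
            value=float(cost),
            arms=("fit",),
        )
        results.append(run_scenario(base_ng, base_fit, spec))
    return results


def _fit_overall_at_multiplier(
    base_fit: ParameterSet, knob: AdherenceKnob, mult: float
) -> float:
    paths = {
        AdherenceKnob.SCREENING: ("adherence.screening_adherence",),
        AdherenceKnob.FOLLOWUP: ("adherence.followup_adherence",),
        AdherenceKnob.JOINT: (
            "adherence.screening_adherence",
            "adherence.followup_adherence",
        ),
    }[knob]
    fit = base_fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for path in paths:
            fit = apply_scenario(
                fit,
                ScenarioSpec(
                    label="breakeven probe",
                    parameter_path=path,
                    transform=Transform.MULTIPLY,
                    value=mult,
                    arms=("fit",),
                ),
            )
    return run_arm(fit).economic.overall_total_cost


def breakeven_adherence_multiplier(
    base_ng: ParameterSet,
    base_fit: ParameterSet,
    knob: AdherenceKnob | str = AdherenceKnob.SCREENING,
    tol: float = 1e-4,
) -> float | None:
    """Smallest FIT adherence multiplier at which FIT's overall total cost
    drops to the ng arm's, by bisection to ``tol``.

    Returns ``None`` if no crossing occurs before the adherence
    saturates at 1 (reported, not raised).  Requires FIT to cost more
    than ng at multiplier 1.
    """
    knob = AdherenceKnob(knob)
    ng_total = run_arm(base_ng).economic.overall_total_cost
    if _fit_overall_at_multiplier(base_fit, knob, 1.0) <= ng_total:
        return 1.0
    adh = base_fit.adherence
    if knob is AdherenceKnob.SCREENING:
        saturation = 1.0 / adh.screening_adherence
    elif knob is AdherenceKnob.FOLLOWUP:
        saturation = 1.0 / adh.followup_adherence
    else:
        saturation = 1.0 / max(adh.screening_adherence, adh.followup_adherence)
    if _fit_overall_at_multiplier(base_fit, knob, saturation) > ng_total:
        return None
    lo, hi = 1.0, saturation
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _fit_overall_at_multiplier(base_fit, knob, mid) <= ng_total:
            hi = mid
        else:
            lo = mid
    return hi


def results_to_frame(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Tidy (scenario, arm, outcome, value) export of scenario results."""
    rows = []
    for res in results:
        for arm, armres in (("fit", res.fit), ("ng_mtsdna", res.ng)):
            for src in (armres.clinical, armres.economic):
                for name, value in vars(src).items():
                    if isinstance(value, tuple):
                        for stage, v in zip(("I", "II", "III", "IV"), value):
                            rows.append((res.spec.label, arm, f"{name}_{stage}", v))
                    else:
                        rows.append((res.spec.label, arm, name, value))
        rows.append((res.spec.label, "delta", "overall_total_cost_ng_minus_fit", res.overall_delta))
    return pd.DataFrame(rows, columns=["scenario", "arm", "outcome", "value"])
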