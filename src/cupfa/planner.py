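"""Rule-based anteversion planner.

The patient's functional anteversion (FA) triple — standing, sitting, and
standing-to-sitting change — is compared against the same triple computed for
an average pelvis at the same planned cup position.  Each quantity is labelled
``greater`` / ``appropriate`` / ``less`` relative to the population value
within a tolerance band, and the label triple is looked up in an eight-row
clinical scenario table.  The output is a quantitative adjustment to the
planned intra-operative anteversion (or a flag recommending alternative
articulation options when pelvic mobility is so limited that cup adjustments
become unpredictable).

The adjustment for each scenario is the raw FA discrepancy of the concerning
quantity (population minus patient for deficits, patient minus population for
excesses).  FA is mildly nonlinear in planned anteversion, so an optional
exact mode instead root-solves for the anteversion at which the concerning
patient FA matches the population FA recomputed at the same adjusted cup
position.

Note one structural fact about the label space: because the change in FA is
identically the sitting FA minus the standing FA (for patient and population
alike), the change discrepancy always equals the sitting discrepancy minus
the standing discrepancy.  With a common tolerance on all three quantities
the pattern (greater, less, appropriate) therefore cannot occur — standing
excess plus sitting deficit forces a change deficit of at least twice the
tolerance.  The scenario table keeps the row (it becomes reachable when the
change tolerance exceeds the sum of the other two), and its guidance — this
would indicate good mobility despite the posture mismatch, so leave the plan
alone — applies whenever it does fire.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy import optimize

from .errors import ValidationError
from .geometry import (
    DEFAULT_WINDOW,
    CupPlan,
    FunctionalOrientation,
    SpinopelvicProfile,
    ValidationWindow,
    profile_fa,
)
from .population import PopulationReference, population_fa

__all__ = [
    "Label",
    "ClassificationBand",
    "TriplePattern",
    "Recommendation",
    "SCENARIO_TABLE",
    "classify",
    "match_scenario",
    "recommend",
    "constrained_decrease",
]

Label = Literal["greater", "appropriate", "less"]


@dataclass(frozen=True)
class ClassificationBand:
    """Half-widths (degrees) within which a patient FA counts as appropriate.

    One tolerance per compared quantity; the single-argument form applies the
    same half-width to all three.  Boundary values are classified inward
    (a discrepancy of exactly the tolerance is still appropriate).
    """

    standing_deg: float = 5.0
    sitting_deg: float = 5.0
    change_deg: float = 5.0

    def __post_init__(self) -> None:
        for name in ("standing_deg", "sitting_deg", "change_deg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def uniform(cls, tolerance_deg: float = 5.0) -> "ClassificationBand":
        return cls(tolerance_deg, tolerance_deg, tolerance_deg)


DEFAULT_BAND = ClassificationBand()


class TriplePattern(NamedTuple):
    """Labels for standing FA, sitting FA and change in FA."""

    standing: Label
    sitting: Label
    change: Label


@dataclass(frozen=True)
class _Scenario:
    scenario_id: int
    pattern: TriplePattern
    action: Literal["decrease_standing", "maintain", "increase_sitting",
                    "increase_greater", "increase_change",
                    "constrained_decrease", "articulation", "none"]
    narrative: str


# Row order follows the clinical scenario table of the planning tool.
SCENARIO_TABLE: tuple[_Scenario, ...] = (
    _Scenario(1, TriplePattern("greater", "appropriate", "appropriate"),
              "decrease_standing",
              "Standing FA exceeds the population value: risk of posterior "
              "impingement when standing. Decrease intra-operative anteversion "
              "by the standing-FA discrepancy."),
    _Scenario(2, TriplePattern("greater", "less", "appropriate"),
              "maintain",
              "Standing FA high and sitting FA low despite normal mobility — "
              "an unlikely combination; adjustments could trade one risk for "
              "the other, so maintain the planned anteversion."),
    _Scenario(3, TriplePattern("appropriate", "less", "appropriate"),
              "increase_sitting",
              "Sitting FA below the population value: risk of posterior "
              "instability when seated. Increase intra-operative anteversion "
              "by the sitting-FA discrepancy."),
    _Scenario(4, TriplePattern("appropriate", "less", "less"),
              "increase_greater",
              "Both sitting FA and the standing-to-sitting change are low: "
              "posterior instability risk when seated. Increase intra-operative "
              "anteversion by the larger of the two discrepancies."),
    _Scenario(5, TriplePattern("appropriate", "appropriate", "less"),
              "increase_change",
              "Standing-to-sitting change in FA is low (stiff pelvis): "
              "increase intra-operative anteversion by the change discrepancy."),
    _Scenario(6, TriplePattern("greater", "appropriate", "less"),
              "constrained_decrease",
              "Standing FA high with reduced mobility but adequate sitting FA: "
              "decrease intra-operative anteversion by the standing-FA "
              "discrepancy, stopping before sitting FA would fall below the "
              "population value."),
    _Scenario(7, TriplePattern("greater", "less", "less"),
              "articulation",
              "Very limited pelvic mobility: anteversion adjustments have "
              "unpredictable effects. Consider additional articulation options "
              "(dual mobility, constrained liner, large femoral head)."),
    _Scenario(8, TriplePattern("appropriate", "appropriate", "appropriate"),
              "none",
              "Adequate pelvic mobility and appropriate FA throughout: "
              "no change to the planned anteversion required."),
)

_PATTERN_INDEX = {s.pattern: s for s in SCENARIO_TABLE}


@dataclass(frozen=True)
class Recommendation:
    """Planner output: scenario, signed adjustment, and supporting detail."""

    scenario_id: int | Literal["unhandled"]
    adjusted_anteversion_deg: float
    adjustment_deg: float
    articulation_flag: bool
    narrative: str
    pattern: TriplePattern
    patient_fa: FunctionalOrientation
    population_fa: FunctionalOrientation

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario_id": self.scenario_id,
                "adjusted_anteversion_deg": round(self.adjusted_anteversion_deg, 1),
                "adjustment_deg": round(self.adjustment_deg, 1),
                "articulation_flag": self.articulation_flag,
                "narrative": self.narrative,
                "pattern": list(self.pattern),
                "patient_fa": self.patient_fa.as_dict(),
                "population_fa": self.population_fa.as_dict(),
            },
            indent=2,
        )


def classify(
    patient_value: float, population_value: float, tolerance_deg: float
) -> Label:
    """Label a patient FA value relative to the population value."""
    diff = patient_value - population_value
    if not math.isfinite(diff):
        raise ValidationError("classify requires finite values")
    if diff > tolerance_deg:
        return "greater"
    if diff < -tolerance_deg:
        return "less"
    return "appropriate"


def match_scenario(pattern: TriplePattern) -> int | Literal["unhandled"]:
    """Exact lookup against the eight scenario rows; anything else is unhandled."""
    scenario = _PATTERN_INDEX.get(pattern)
    return scenario.scenario_id if scenario else "unhandled"


def constrained_decrease(
    plan: CupPlan,
    profile: SpinopelvicProfile,
    reference: PopulationReference,
    target_decrease: float,
    step: float = 0.1,
) -> float:
    """Largest anteversion decrease (<= target) keeping sitting FA adequate.

    Scans d = 0, step, 2*step, ... target and returns the last d for which the
    patient's sitting FA at planned anteversion A - d is still at least the
    population sitting FA at the originally planned position.  The population
    value is the fixed target of the stopping rule: recomputing it at A - d
    would move both sides of the comparison in lockstep (FA is monotone in
    tilt at fixed cup position), making the constraint either always or never
    binding and the rule vacuous.
    """
    if target_decrease < 0:
        raise ValidationError("target_decrease must be >= 0")
    n_steps = int(math.floor(target_decrease / step + 1e-9))
    candidates = [k * step for k in range(n_steps + 1)]
    if candidates[-1] < target_decrease - 1e-9:
        candidates.append(target_decrease)

    pop_sit = population_fa(plan, reference).fa_sitting_deg
    achieved = 0.0
    for d in candidates:
        trial = CupPlan(plan.inclination_deg, plan.anteversion_deg - d)
        patient_sit = profile_fa(trial, profile).fa_sitting_deg
        if patient_sit < pop_sit:
            break
        achieved = d
    return achieved


def _exact_adjustment(
    plan: CupPlan,
    profile: SpinopelvicProfile,
    reference: PopulationReference,
    quantity: Literal["fa_standing_deg", "fa_sitting_deg", "fa_change_deg"],
    window: ValidationWindow,
    fallback: float,
) -> float:
    """Anteversion shift making the concerning patient FA hit the population
    FA target at the originally planned cup position (root solve).

    The target is held at the planned position: recomputing the population FA
    at the trial anteversion would shift the target in lockstep with the
    patient and leave (almost) nothing to solve.  Falls back to the raw
    discrepancy when the target is outside the patient's reachable range.
    """
    target = getattr(population_fa(plan, reference), quantity)

    def gap(a: float) -> float:
        trial = CupPlan(plan.inclination_deg, a)
        return getattr(profile_fa(trial, profile, window), quantity) - target

    lo, hi = window.anteversion_deg
    try:
        root = optimize.brentq(gap, lo, hi, xtol=1e-6)
    except ValueError:  # no sign change inside the window
        return fallback
    return root - plan.anteversion_deg


def recommend(
    plan: CupPlan,
    profile: SpinopelvicProfile,
    reference: PopulationReference,
    band: ClassificationBand = DEFAULT_BAND,
    window: ValidationWindow = DEFAULT_WINDOW,
    exact: bool = False,
) -> Recommendation:
    """Full planning pass: FA triples, classification, scenario, adjustment."""
    patient = profile_fa(plan, profile, window)
    population = population_fa(plan, reference)

    d_stand = patient.fa_standing_deg - population.fa_standing_deg
    d_sit = patient.fa_sitting_deg - population.fa_sitting_deg
    d_change = patient.fa_change_deg - population.fa_change_deg

    pattern = TriplePattern(
        classify(patient.fa_standing_deg, population.fa_standing_deg, band.standing_deg),
        classify(patient.fa_sitting_deg, population.fa_sitting_deg, band.sitting_deg),
        classify(patient.fa_change_deg, population.fa_change_deg, band.change_deg),
    )
    scenario = _PATTERN_INDEX.get(pattern)
    articulation = False
    notes: list[str] = []

    if scenario is None:
        scenario_id: int | Literal["unhandled"] = "unhandled"
        adjustment = 0.0
        narrative = (
            "Pattern (" + ", ".join(pattern) + ") is not one of the eight "
            "clinical scenarios; no automatic adjustment — manual review advised."
        )
    else:
        scenario_id = scenario.scenario_id
        narrative = scenario.narrative
        action = scenario.action
        if action == "decrease_standing":
            adjustment = (
                _exact_adjustment(plan, profile, reference, "fa_standing_deg",
                                  window, fallback=-d_stand)
                if exact else -d_stand
            )
        elif action == "increase_sitting":
            adjustment = (
                _exact_adjustment(plan, profile, reference, "fa_sitting_deg",
                                  window, fallback=-d_sit)
                if exact else -d_sit
            )
        elif action == "increase_change":
            adjustment = (
                _exact_adjustment(plan, profile, reference, "fa_change_deg",
                                  window, fallback=-d_change)
                if exact else -d_change
            )
        elif action == "increase_greater":
            if exact:
                quantity = (
                    "fa_sitting_deg" if abs(d_sit) >= abs(d_change) else "fa_change_deg"
                )
                adjustment = _exact_adjustment(
                    plan, profile, reference, quantity, window,
                    fallback=max(abs(d_sit), abs(d_change)),
                )
            else:
                adjustment = max(abs(d_sit), abs(d_change))
        elif action == "constrained_decrease":
            adjustment = -constrained_decrease(plan, profile, reference, d_stand)
        elif action == "articulation":
            adjustment = 0.0
            articulation = True
        else:  # maintain / none
            adjustment = 0.0

    adjusted = plan.anteversion_deg + adjustment
    lo, hi = window.anteversion_deg
    if not lo <= adjusted <= hi:
        clamped = min(max(adjusted, lo), hi)
        notes.append(
            f"adjusted anteversion {adjusted:.1f} outside the validation window "
            f"[{lo:g}, {hi:g}]; clamped to {clamped:.1f}"
        )
        adjustment = clamped - plan.anteversion_deg
        adjusted = clamped

    if notes:
        narrative = narrative + " [" + "; ".join(notes) + "]"

    return Recommendation(
        scenario_id=scenario_id,
        adjusted_anteversion_deg=adjusted,
        adjustment_deg=adjustment,
        articulation_flag=articulation,
        narrative=narrative,
        pattern=pattern,
        patient_fa=patient,
        population_fa=population,
    )
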