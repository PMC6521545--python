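"""Synthetic spinopelvic profiles for testing and simulation.

Real inputs to the planner are standing and sitting pelvic tilts measured on
lateral radiographs.  This module emulates such cohorts with a correlated
bivariate normal on (standing, sitting) tilt, parameterised by the pooled
literature means and SDs, and constructs profiles that exercise each row of
the planner's scenario table by searching tilt space for pairs the classifier
maps to the requested label pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ScenarioConstructionError, ValidationError
from .geometry import CupPlan, SpinopelvicProfile
from .planner import (
    DEFAULT_BAND,
    ClassificationBand,
    SCENARIO_TABLE,
    recommend,
)
from .population import PopulationReference

__all__ = [
    "ProfileSamplerParams",
    "sample_profiles",
    "scenario_fixtures",
    "profiles_to_csv",
]


@dataclass(frozen=True)
class ProfileSamplerParams:
    """Bivariate-normal model of (standing, sitting) pelvic tilt, degrees.

    Defaults are the subject-weighted pooled means of the packaged study
    table with pooled SDs where studies report them.  The standing–sitting
    correlation is not reported in the source cohorts; 0.4 is a moderate
    default and is freely configurable.
    """

    standing_mean_deg: float = 0.3
    standing_sd_deg: float = 7.9
    sitting_mean_deg: float = 25.8
    sitting_sd_deg: float = 10.4
    correlation: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.standing_sd_deg < 0 or self.sitting_sd_deg < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValidationError("correlation must lie in [-1, 1]")


def sample_profiles(
    n: int, params: ProfileSamplerParams = ProfileSamplerParams()
) -> list[SpinopelvicProfile]:
    """Draw n correlated (standing, sitting) tilt pairs; deterministic under seed."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(params.seed)
    cov = np.array(
        [
            [params.standing_sd_deg ** 2,
             params.correlation * params.standing_sd_deg * params.sitting_sd_deg],
            [params.correlation * params.standing_sd_deg * params.sitting_sd_deg,
             params.sitting_sd_deg ** 2],
        ]
    )
    mean = [params.standing_mean_deg, params.sitting_mean_deg]
    draws = rng.multivariate_normal(mean, cov, size=n, method="cholesky" if
                                    params.standing_sd_deg > 0 and
                                    params.sitting_sd_deg > 0 and
                                    abs(params.correlation) < 1 else "svd")
    return [SpinopelvicProfile.from_degrees(s, t) for s, t in draws]


def scenario_fixtures(
    plan: CupPlan,
    reference: PopulationReference,
    band: ClassificationBand = DEFAULT_BAND,
    tilt_search_halfwidth_deg: float = 30.0,
    search_step_deg: float = 1.0,
    require_all: bool = True,
) -> dict[int, SpinopelvicProfile]:
    """One profile per reachable scenario row, found by inverting the classifier.

    Searches tilt pairs offset from the reference pose on a regular grid and
    keeps, for each scenario id, the first profile whose recommendation maps
    to it.  With ``require_all`` (the default) raises
    :class:`ScenarioConstructionError` naming any pattern no tilt pair can
    realise under the given band; otherwise returns the reachable subset.

    Note that the (greater, less, appropriate) row is unreachable under every
    tolerance band: the change discrepancy is identically the sitting minus
    the standing discrepancy, so that row needs a change tolerance above the
    sum of the other two, while (appropriate, appropriate, less) needs one
    below the same sum.  The classifier structure itself makes the row
    vacuous — consistent with its clinical description as an unlikely
    combination.
    """
    offsets = np.arange(
        -tilt_search_halfwidth_deg,
        tilt_search_halfwidth_deg + search_step_deg / 2,
        search_step_deg,
    )
    found: dict[int, SpinopelvicProfile] = {}
    # reference pose first so scenario 8 gets the exact reference tilts
    ref_profile = reference.as_profile()
    rec = recommend(plan, ref_profile, reference, band)
    if rec.scenario_id != "unhandled":
        found[rec.scenario_id] = ref_profile

    for ds in offsets:
        for dt in offsets:
            profile = SpinopelvicProfile.from_degrees(
                reference.standing_tilt_deg + float(ds),
                reference.sitting_tilt_deg + float(dt),
            )
            rec = recommend(plan, profile, reference, band)
            sid = rec.scenario_id
            if sid != "unhandled" and sid not in found:
                found[sid] = profile
                if len(found) == len(SCENARIO_TABLE):
                    return found

    missing = [s.pattern for s in SCENARIO_TABLE if s.scenario_id not in found]
    if missing and require_all:
        raise ScenarioConstructionError(
            "no spinopelvic profile realises pattern(s) "
            + "; ".join("(" + ", ".join(p) + ")" for p in missing)
            + f" under band {band}"
        )
    return found


def profiles_to_csv(
    profiles: Iterable[SpinopelvicProfile], path: str | Path
) -> None:
    """Write profiles as patient_id,standing_tilt,sitting_tilt."""
    frame = pd.DataFrame(
        [
            {
                "patient_id": i + 1,
                "standing_tilt": p.standing_tilt.tilt_deg,
                "sitting_tilt": p.sitting_tilt.tilt_deg,
            }
            for i, p in enumerate(profiles)
        ]
    )
    frame.to_csv(path, index=False)
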