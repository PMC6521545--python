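"""Population pelvic-tilt reference pooled from published cohort studies.

Standing and sitting sagittal pelvic tilt vary widely between individuals;
the planning tool compares each patient against a normal-population baseline
built by pooling cohort means from the literature, weighted by the number of
subjects in each study.  The packaged study table (``data/pelvic_tilt_studies.csv``)
holds six cohorts totalling 378 subjects; its subject-weighted means are
standing 0.3 deg, sitting 25.8 deg, standing-to-sitting change 25.4 deg.

The change column is pooled directly from each study's reported change mean
rather than recomputed as sitting minus standing of the pooled means: studies
report the change independently, and the two readings differ in general.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TableParseError, ValidationError
from .geometry import CupPlan, FunctionalOrientation, SpinopelvicProfile, profile_fa

__all__ = [
    "StudyRecord",
    "PopulationReference",
    "weighted_reference",
    "population_fa",
    "load_study_table",
    "save_study_table",
    "default_study_table",
    "default_reference",
]

_COLUMNS = [
    "study", "year", "n",
    "stand_mean", "stand_sd",
    "sit_mean", "sit_sd",
    "change_mean", "change_sd",
]


@dataclass(frozen=True)
class StudyRecord:
    """Summary pelvic-tilt statistics of one cohort study (degrees).

    The change mean is stored as reported by the study; it need not equal
    ``sit_mean - stand_mean`` and is never recomputed silently.
    """

    name: str
    year: int
    n_subjects: int
    standing_mean_deg: float
    sitting_mean_deg: float
    change_mean_deg: float
    standing_sd_deg: float | None = None
    sitting_sd_deg: float | None = None
    change_sd_deg: float | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(
                f"study {self.name!r}: n_subjects must be >= 1, got {self.n_subjects}"
            )
        for field in ("standing_mean_deg", "sitting_mean_deg", "change_mean_deg"):
            if not math.isfinite(getattr(self, field)):
                raise ValidationError(f"study {self.name!r}: {field} must be finite")


@dataclass(frozen=True)
class PopulationReference:
    """Subject-weighted pooled pelvic-tilt means (degrees) and total n."""

    standing_tilt_deg: float
    sitting_tilt_deg: float
    change_tilt_deg: float
    total_n: int

    def as_profile(self) -> SpinopelvicProfile:
        return SpinopelvicProfile.from_degrees(
            self.standing_tilt_deg, self.sitting_tilt_deg
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "standing_tilt_deg": self.standing_tilt_deg,
                "sitting_tilt_deg": self.sitting_tilt_deg,
                "change_tilt_deg": self.change_tilt_deg,
                "total_n": self.total_n,
            },
            indent=2,
        )


def weighted_reference(studies: Sequence[StudyRecord]) -> PopulationReference:
    """Pool study means into a population reference, weighting by subjects.

    Full precision is retained; rounding to the customary one decimal happens
    only at presentation.
    """
    if not studies:
        raise ValidationError("weighted_reference requires at least one study")
    n = np.array([s.n_subjects for s in studies], dtype=float)
    stand = np.array([s.standing_mean_deg for s in studies])
    sit = np.array([s.sitting_mean_deg for s in studies])
    change = np.array([s.change_mean_deg for s in studies])
    return PopulationReference(
        standing_tilt_deg=float(np.average(stand, weights=n)),
        sitting_tilt_deg=float(np.average(sit, weights=n)),
        change_tilt_deg=float(np.average(change, weights=n)),
        total_n=int(n.sum()),
    )


def population_fa(plan: CupPlan, ref: PopulationReference) -> FunctionalOrientation:
    """FA triple an average pelvis would give the planned cup.

    The change value is the difference of the standing and sitting FA values
    (not the model applied to the pooled change tilt).
    """
    return profile_fa(plan, ref.as_profile())


def _parse_optional(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableParseError(
            f"row {row}: column {column!r} is not numeric: {value!r}"
        ) from None


def load_study_table(path: str | Path) -> list[StudyRecord]:
    """Read a study table CSV; ``NR`` or empty cells mark missing SDs."""
    try:
        frame = pd.read_csv(path, na_values=["NR", ""], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{path}: file is empty") from None
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise TableParseError(f"{path}: missing required columns {missing}")

    records: list[StudyRecord] = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            n = int(row["n"])
        except (TypeError, ValueError):
            raise TableParseError(
                f"row {rownum}: column 'n' is not an integer: {row['n']!r}"
            ) from None
        for col in ("stand_mean", "sit_mean", "change_mean"):
            if pd.isna(row[col]):
                raise TableParseError(f"row {rownum}: column {col!r} is missing")
        records.append(
            StudyRecord(
                name=str(row["study"]),
                year=int(row["year"]),
                n_subjects=n,
                standing_mean_deg=float(row["stand_mean"]),
                sitting_mean_deg=float(row["sit_mean"]),
                change_mean_deg=float(row["change_mean"]),
                standing_sd_deg=_parse_optional(row["stand_sd"], rownum, "stand_sd"),
                sitting_sd_deg=_parse_optional(row["sit_sd"], rownum, "sit_sd"),
                change_sd_deg=_parse_optional(row["change_sd"], rownum, "change_sd"),
            )
        )
    if not records:
        raise TableParseError(f"{path}: no study rows")
    return records


def save_study_table(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write study records back to the CSV dialect of :func:`load_study_table`."""
    def cell(v: float | None):
        return "NR" if v is None else v

    frame = pd.DataFrame(
        [
            {
                "study": r.name,
                "year": r.year,
                "n": r.n_subjects,
                "stand_mean": r.standing_mean_deg,
                "stand_sd": cell(r.standing_sd_deg),
                "sit_mean": r.sitting_mean_deg,
                "sit_sd": cell(r.sitting_sd_deg),
                "change_mean": r.change_mean_deg,
                "change_sd": cell(r.change_sd_deg),
            }
            for r in records
        ],
        columns=_COLUMNS,
    )
    frame.to_csv(path, index=False)


def default_study_table() -> list[StudyRecord]:
    """The packaged six-cohort study table (378 subjects)."""
    with resources.as_file(
        resources.files("cupfa").joinpath("data/pelvic_tilt_studies.csv")
    ) as path:
        return load_study_table(path)


def default_reference() -> PopulationReference:
    """Weighted reference of the packaged study table."""
    return weighted_reference(default_study_table())
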