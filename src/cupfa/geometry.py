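"""Geometric model of acetabular-cup functional anteversion (FA).

The cup is represented by the unit vector normal to the flat face of the
component, expressed in a global (room-fixed) frame:

    x = lateral, y = anterior, z = superior.

With the pelvis in the neutral pose (anterior pelvic plane parallel to the
coronal plane) the cup normal points inferiorly, ``(0, 0, -1)``.  Planned cup
position is applied as two successive rotations — inclination ``I`` in the
coronal (x–z) plane, then anteversion ``A`` about the vertical (z) axis — and
sagittal pelvic tilt ``PT`` is a rotation about the lateral (x) axis, positive
for posterior tilt (as in sitting).  Projecting the tilted normal onto the
axial plane and taking the signed angle of the anterior over the lateral
component gives the functional anteversion: the transverse-plane anteversion
the cup actually presents in that posture.

Composing the three rotations gives the closed form (degrees)

    FA(I, A, PT) = atan2(sin I sin A cos PT + cos I sin PT,  sin I cos A)

which the vector pipeline in this module reproduces to floating-point
accuracy.  The axis convention above is the unique natural reading of the
inclination→anteversion→tilt sequence that is consistent with the standard
worked values of the model (FA = 34.2 deg at I=40, A=20, PT=15 and
FA = 27.5 deg at I=35, A=20, PT=6).

All public angles are in degrees; radians appear only inside trig calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ContractError, DegenerateOrientationError, ValidationError

__all__ = [
    "Vector3",
    "CupPlan",
    "PelvicTilt",
    "SpinopelvicProfile",
    "FunctionalOrientation",
    "ValidationWindow",
    "DEFAULT_WINDOW",
    "cup_normal",
    "apply_pelvic_tilt",
    "axial_anteversion",
    "functional_anteversion",
    "delta_fa",
    "profile_fa",
]

_UNIT_TOL = 1e-9


class Vector3(NamedTuple):
    """Direction in the global frame: x lateral, y anterior, z superior."""

    x: float
    y: float
    z: float

    @property
    def norm(self) -> float:
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class ValidationWindow:
    """Accepted input ranges, overridable per call.

    Inclination is additionally hard-limited to the open interval (0, 90):
    at 0 deg the cup normal is vertical and at 90 deg purely lateral, and the
    axial-plane anteversion angle degenerates at either bound.
    """

    inclination_deg: tuple[float, float] = (10.0, 80.0)
    anteversion_deg: tuple[float, float] = (-10.0, 50.0)
    tilt_deg: tuple[float, float] = (-45.0, 60.0)


DEFAULT_WINDOW = ValidationWindow()


def _check_range(value: float, lo: float, hi: float, name: str) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if not lo <= value <= hi:
        raise ValidationError(
            f"{name}={value:g} outside the validation window [{lo:g}, {hi:g}]"
        )


@dataclass(frozen=True)
class CupPlan:
    """Planned intra-operative cup position, referenced to the neutral pelvis."""

    inclination_deg: float
    anteversion_deg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.inclination_deg):
            raise ValidationError("inclination_deg must be finite")
        if not math.isfinite(self.anteversion_deg):
            raise ValidationError("anteversion_deg must be finite")
        if not 0.0 < self.inclination_deg < 90.0:
            raise ValidationError(
                f"inclination_deg={self.inclination_deg:g} must lie strictly "
                "between 0 and 90 (axial projection degenerates at the bounds)"
            )

    def validate(self, window: ValidationWindow = DEFAULT_WINDOW) -> "CupPlan":
        _check_range(self.inclination_deg, *window.inclination_deg, name="inclination_deg")
        _check_range(self.anteversion_deg, *window.anteversion_deg, name="anteversion_deg")
        return self


@dataclass(frozen=True)
class PelvicTilt:
    """Signed sagittal pelvic tilt from the neutral pose; positive = posterior."""

    tilt_deg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tilt_deg):
            raise ValidationError("tilt_deg must be finite")

    def validate(self, window: ValidationWindow = DEFAULT_WINDOW) -> "PelvicTilt":
        _check_range(self.tilt_deg, *window.tilt_deg, name="tilt_deg")
        return self


@dataclass(frozen=True)
class SpinopelvicProfile:
    """One patient's standing and sitting sagittal pelvic tilt."""

    standing_tilt: PelvicTilt
    sitting_tilt: PelvicTilt

    @classmethod
    def from_degrees(cls, standing: float, sitting: float) -> "SpinopelvicProfile":
        return cls(PelvicTilt(standing), PelvicTilt(sitting))

    @property
    def change_tilt_deg(self) -> float:
        return self.sitting_tilt.tilt_deg - self.standing_tilt.tilt_deg


@dataclass(frozen=True)
class FunctionalOrientation:
    """Functional anteversion standing / sitting, and their difference."""

    fa_standing_deg: float
    fa_sitting_deg: float
    fa_change_deg: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        change = self.fa_sitting_deg - self.fa_standing_deg
        if self.fa_change_deg is None:
            object.__setattr__(self, "fa_change_deg", change)
        elif self.fa_change_deg != change:
            raise ValidationError(
                "fa_change_deg must equal fa_sitting_deg - fa_standing_deg"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "fa_standing_deg": self.fa_standing_deg,
            "fa_sitting_deg": self.fa_sitting_deg,
            "fa_change_deg": self.fa_change_deg,
        }


# ---------------------------------------------------------------------------
# rotations


def _rot_x(angle_deg: float) -> np.ndarray:
    """Rotation about the lateral axis (sagittal-plane rotation)."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(angle_deg: float) -> np.ndarray:
    """Rotation about the anterior axis (coronal-plane rotation)."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(angle_deg: float) -> np.ndarray:
    """Rotation about the superior axis (axial-plane rotation)."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def cup_normal(plan: CupPlan, window: ValidationWindow = DEFAULT_WINDOW) -> Vector3:
    """Unit normal of the cup face after planned inclination then anteversion.

    The neutral normal ``(0, 0, -1)`` is rotated by ``I`` in the coronal plane
    (opening swings laterally) and then by ``A`` about the vertical axis
    (opening swings anteriorly), giving components
    ``(sin I cos A, sin I sin A, -cos I)``.
    """
    plan.validate(window)
    i = math.radians(plan.inclination_deg)
    a = math.radians(plan.anteversion_deg)
    v = Vector3(math.sin(i) * math.cos(a), math.sin(i) * math.sin(a), -math.cos(i))
    return v


def apply_pelvic_tilt(v: Vector3, tilt: PelvicTilt) -> Vector3:
    """Rotate a unit vector by sagittal pelvic tilt (about the lateral axis).

    Positive (posterior) tilt carries an inferiorly directed cup normal
    anteriorly, mirroring the pelvis rolling backwards into sitting.
    """
    if abs(v.norm - 1.0) > _UNIT_TOL:
        raise ContractError(f"apply_pelvic_tilt requires a unit vector, |v|={v.norm!r}")
    out = _rot_x(tilt.tilt_deg) @ v.as_array()
    return Vector3(*out)


def axial_anteversion(v: Vector3) -> float:
    """Signed transverse-plane anteversion of a cup normal, in degrees.

    Projects ``v`` onto the axial plane and returns the angle of the anterior
    component over the lateral component, in (-90, 90).  Requires the lateral
    component to be positive (cup opening faces laterally).
    """
    if v.x <= 0.0:
        raise DegenerateOrientationError(
            f"axial projection ({v.x:.4g}, {v.y:.4g}) has non-positive lateral "
            "component; anteversion is undefined for a medially or vertically "
            "facing cup"
        )
    return math.degrees(math.atan2(v.y, v.x))


def functional_anteversion(
    plan: CupPlan,
    tilt: PelvicTilt,
    window: ValidationWindow = DEFAULT_WINDOW,
) -> float:
    """FA of a planned cup in a posture with the given pelvic tilt, degrees.

    Equivalent closed form:
    ``atan2(sin I sin A cos PT + cos I sin PT, sin I cos A)``.
    """
    tilt.validate(window)
    return axial_anteversion(apply_pelvic_tilt(cup_normal(plan, window), tilt))


def closed_form_fa(inclination_deg: float, anteversion_deg: float, tilt_deg: float) -> float:
    """FA via the analytic composition of the three rotations (degrees).

    Identical to :func:`functional_anteversion` but skipping validation and
    vector construction; used as the fast engine for grid generation.
    """
    i = math.radians(inclination_deg)
    a = math.radians(anteversion_deg)
    t = math.radians(tilt_deg)
    lateral = math.sin(i) * math.cos(a)
    anterior = math.sin(i) * math.sin(a) * math.cos(t) + math.cos(i) * math.sin(t)
    if lateral <= 0.0:
        raise DegenerateOrientationError(
            "cup normal has non-positive lateral component"
        )
    return math.degrees(math.atan2(anterior, lateral))


def delta_fa(
    plan: CupPlan,
    tilt: PelvicTilt,
    window: ValidationWindow = DEFAULT_WINDOW,
) -> float:
    """Change in anteversion produced by pelvic tilt: FA minus planned A."""
    return functional_anteversion(plan, tilt, window) - plan.anteversion_deg


def profile_fa(
    plan: CupPlan,
    profile: SpinopelvicProfile,
    window: ValidationWindow = DEFAULT_WINDOW,
) -> FunctionalOrientation:
    """Standing and sitting FA for one patient, each taken from the neutral pose."""
    fa_stand = functional_anteversion(plan, profile.standing_tilt, window)
    fa_sit = functional_anteversion(plan, profile.sitting_tilt, window)
    return FunctionalOrientation(fa_standing_deg=fa_stand, fa_sitting_deg=fa_sit)
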