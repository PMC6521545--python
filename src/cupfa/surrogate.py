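"""Cubic response surface for the change in functional anteversion.

The geometric model gives ΔFA(I, A, PT) in closed form; this module provides
the polynomial surrogate of that surface used by the planning tool: a complete
third-degree polynomial in planned inclination ``I``, planned anteversion
``A`` and pelvic tilt ``PT`` (20 monomials including the constant), fitted by
ordinary least squares on a 1-degree grid over I 30–60, A 15–25, PT 0–30.

Two coefficient sets are available:

* :meth:`CubicDeltaFA.published` — the canonical coefficient set of the
  deployed planning tool, shipped verbatim;
* :func:`fit_surrogate` — a fresh least-squares fit on any sample table,
  reproducing the published set to within its own residual error.

The estimator follows the scikit-learn protocol (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) so it composes with
sklearn model-selection utilities.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import SingularDesignError, ValidationError
from .geometry import closed_form_fa

__all__ = [
    "GridSpec",
    "DEFAULT_GRID",
    "CubicDeltaFA",
    "PUBLISHED_EQ1_COEFFICIENTS",
    "monomial_exponents",
    "design_row",
    "design_matrix",
    "generate_grid",
    "fit_surrogate",
    "published_eq1",
    "eval_surrogate",
    "compare_surrogates",
]

logger = logging.getLogger(__name__)

VARIABLES = ("I", "A", "PT")


@dataclass(frozen=True)
class GridSpec:
    """Inclusive 3-D evaluation grid over (I, A, PT), degrees.

    Defaults are the iteration grid of the model: 1-degree increments over
    inclination 30–60, anteversion 15–25, pelvic tilt 0–30.
    """

    inclination: tuple[float, float] = (30.0, 60.0)
    anteversion: tuple[float, float] = (15.0, 25.0)
    tilt: tuple[float, float] = (0.0, 30.0)
    inclination_step: float = 1.0
    anteversion_step: float = 1.0
    tilt_step: float = 1.0

    def __post_init__(self) -> None:
        for name in ("inclination_step", "anteversion_step", "tilt_step"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("inclination", "anteversion", "tilt"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValidationError(f"{name} range is empty: ({lo}, {hi})")

    def axis(self, name: str) -> np.ndarray:
        lo, hi = getattr(self, name)
        step = getattr(self, f"{name}_step")
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    @property
    def n_points(self) -> int:
        return (
            self.axis("inclination").size
            * self.axis("anteversion").size
            * self.axis("tilt").size
        )

    def describe(self) -> str:
        return (
            f"I {self.inclination[0]:g}-{self.inclination[1]:g} by {self.inclination_step:g}, "
            f"A {self.anteversion[0]:g}-{self.anteversion[1]:g} by {self.anteversion_step:g}, "
            f"PT {self.tilt[0]:g}-{self.tilt[1]:g} by {self.tilt_step:g} "
            f"({self.n_points} points, inclusive)"
        )


DEFAULT_GRID = GridSpec()


def monomial_exponents(degree: int = 3) -> list[tuple[int, int, int]]:
    """Exponent triples (i, j, k) of I^i A^j PT^k with i+j+k <= degree.

    Canonical order: total degree descending, then lexicographic, so the
    constant term is last and serialised coefficient files are stable.
    """
    triples = [
        t
        for t in itertools.product(range(degree + 1), repeat=3)
        if sum(t) <= degree
    ]
    return sorted(triples, key=lambda t: (-sum(t), t))


def design_row(
    inclination: float, anteversion: float, tilt: float, degree: int = 3
) -> np.ndarray:
    """The monomial basis values at one (I, A, PT) point, canonical order."""
    return design_matrix(
        np.array([[inclination, anteversion, tilt]], dtype=float), degree
    )[0]


def design_matrix(X: np.ndarray, degree: int = 3) -> np.ndarray:
    """Complete-polynomial design matrix; columns follow monomial_exponents."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValidationError("X must have shape (n_samples, 3): columns I, A, PT")
    cols = [
        X[:, 0] ** i * X[:, 1] ** j * X[:, 2] ** k
        for i, j, k in monomial_exponents(degree)
    ]
    return np.column_stack(cols)


# Canonical coefficient set of the deployed planning tool: the complete cubic
# in (I, A, PT) for the change in functional anteversion, degrees.
PUBLISHED_EQ1_COEFFICIENTS: dict[tuple[int, int, int], float] = {
    (0, 0, 0): 0.69986,
    (0, 0, 1): 3.3245,
    (0, 0, 2): -0.029675,
    (0, 0, 3): 0.000041864,
    (0, 1, 0): 1.4579,
    (0, 1, 1): -0.028543,
    (0, 1, 2): -0.000039528,
    (0, 2, 0): -0.065747,
    (0, 2, 1): 0.000088289,
    (0, 3, 0): 0.00090945,
    (1, 0, 0): -0.62941,
    (1, 0, 1): -0.053399,
    (1, 0, 2): 0.00042065,
    (1, 1, 0): -0.0043096,
    (1, 1, 1): 0.0003293,
    (1, 2, 0): 0.00019878,
    (2, 0, 0): 0.012728,
    (2, 0, 1): 0.0001499,
    (2, 1, 0): -0.00004212,
    (3, 0, 0): -0.000070867,
}


class CubicDeltaFA(RegressorMixin, BaseEstimator):
    """Complete polynomial surrogate of ΔFA(I, A, PT), default degree 3.

    Parameters
    ----------
    degree : int
        Total polynomial degree of the complete basis (20 terms at degree 3).
    scale_columns : bool
        Standardise the non-constant design columns before the least-squares
        solve (conditioning only; reported coefficients are in raw units).

    Attributes
    ----------
    coefficients_ : dict[(i, j, k), float]
        Monomial coefficients of I^i A^j PT^k in degrees.
    provenance_ : str
        ``"fitted"`` or ``"published"``.
    r_squared_, mean_abs_error_deg_, max_abs_error_deg_ : float
        In-sample fit quality (fitted surrogates only).
    grid_description_ : str
        Human-readable description of the fitting samples.
    """

    def __init__(self, degree: int = 3, scale_columns: bool = True):
        self.degree = degree
        self.scale_columns = scale_columns

    # -- scikit-learn protocol ------------------------------------------------

    def fit(self, X, y, grid_description: str = "") -> "CubicDeltaFA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        exponents = monomial_exponents(self.degree)
        if X.shape[0] < len(exponents):
            raise SingularDesignError(
                f"need at least {len(exponents)} samples for a degree-{self.degree} "
                f"fit, got {X.shape[0]}"
            )
        for col, name in enumerate(VARIABLES):
            if np.unique(X[:, col]).size <= self.degree:
                raise SingularDesignError(
                    f"variable {name} takes too few distinct values "
                    f"({np.unique(X[:, col]).size}) for a degree-{self.degree} fit"
                )
        D = design_matrix(X, self.degree)

        if self.scale_columns:
            # standardise non-constant columns; fold the shift back into the
            # constant term afterwards so coefficients stay in raw units
            mean = D.mean(axis=0)
            scale = D.std(axis=0)
            const = scale < 1e-12
            scale[const] = 1.0
            mean[const] = 0.0
            Ds = (D - mean) / scale
            Ds[:, const] = D[:, const]
            beta_s, _, rank, _ = np.linalg.lstsq(Ds, y, rcond=None)
            if rank < len(exponents):
                raise SingularDesignError(
                    f"design matrix rank {rank} < {len(exponents)}"
                )
            beta = beta_s / scale
            const_idx = exponents.index((0, 0, 0))
            beta[const_idx] = beta_s[const_idx] - float(
                np.sum(beta_s[~const] * mean[~const] / scale[~const])
            )
        else:
            beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
            if rank < len(exponents):
                raise SingularDesignError(
                    f"design matrix rank {rank} < {len(exponents)}"
                )

        resid = y - D @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.coefficients_ = dict(zip(exponents, (float(b) for b in beta)))
        self.provenance_ = "fitted"
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.mean_abs_error_deg_ = float(np.mean(np.abs(resid)))
        self.max_abs_error_deg_ = float(np.max(np.abs(resid)))
        self.grid_description_ = grid_description or f"{X.shape[0]} samples"
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coefficients_"):
            raise ValidationError("surrogate is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        exponents = sorted(self.coefficients_, key=lambda t: (-sum(t), t))
        deg = max(sum(t) for t in exponents)
        D = design_matrix(X, deg)
        beta = np.array([self.coefficients_[t] for t in monomial_exponents(deg)])
        return D @ beta

    # -- alternate constructors / serialisation -------------------------------

    @classmethod
    def published(cls) -> "CubicDeltaFA":
        """The verbatim canonical coefficient set of the planning tool."""
        est = cls(degree=3)
        est.coefficients_ = dict(PUBLISHED_EQ1_COEFFICIENTS)
        est.provenance_ = "published"
        return est

    @classmethod
    def from_coefficients(
        cls,
        coefficients: Mapping[tuple[int, int, int], float],
        provenance: str = "fitted",
    ) -> "CubicDeltaFA":
        deg = max(sum(t) for t in coefficients)
        est = cls(degree=deg)
        est.coefficients_ = dict(coefficients)
        est.provenance_ = provenance
        return est

    def to_json(self) -> str:
        payload: dict = {
            "coefficients": {
                f"({i},{j},{k})": v for (i, j, k), v in sorted(
                    self.coefficients_.items(), key=lambda kv: (-sum(kv[0]), kv[0])
                )
            },
            "metadata": {"provenance": self.provenance_, "degree": self.degree},
        }
        for attr in ("r_squared_", "mean_abs_error_deg_", "max_abs_error_deg_",
                     "grid_description_"):
            if hasattr(self, attr):
                payload["metadata"][attr.rstrip("_")] = getattr(self, attr)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CubicDeltaFA":
        payload = json.loads(text)
        coeffs = {
            tuple(int(p) for p in key.strip("()").split(",")): float(v)
            for key, v in payload["coefficients"].items()
        }
        meta = payload.get("metadata", {})
        est = cls.from_coefficients(coeffs, provenance=meta.get("provenance", "fitted"))
        for attr in ("r_squared", "mean_abs_error_deg", "max_abs_error_deg",
                     "grid_description"):
            if attr in meta:
                setattr(est, attr + "_", meta[attr])
        return est


# ---------------------------------------------------------------------------
# module-level operations


def generate_grid(spec: GridSpec = DEFAULT_GRID) -> pd.DataFrame:
    """Evaluate geometric ΔFA on the Cartesian grid of a :class:`GridSpec`.

    Rows are ordered I outer, A middle, PT inner; columns ``I, A, PT,
    delta_fa`` (degrees).
    """
    rows = [
        (i, a, t, closed_form_fa(i, a, t) - a)
        for i in spec.axis("inclination")
        for a in spec.axis("anteversion")
        for t in spec.axis("tilt")
    ]
    return pd.DataFrame(rows, columns=["I", "A", "PT", "delta_fa"])


def fit_surrogate(samples: pd.DataFrame, degree: int = 3) -> CubicDeltaFA:
    """Least-squares complete-polynomial fit to a ΔFA sample table."""
    X = samples[["I", "A", "PT"]].to_numpy(dtype=float)
    y = samples["delta_fa"].to_numpy(dtype=float)
    return CubicDeltaFA(degree=degree).fit(
        X, y, grid_description=f"{len(samples)} samples"
    )


def published_eq1() -> CubicDeltaFA:
    """The published 20-coefficient cubic, verbatim."""
    return CubicDeltaFA.published()


def eval_surrogate(
    surrogate: CubicDeltaFA,
    inclination: float,
    anteversion: float,
    tilt: float,
    warn_extrapolation: bool = True,
) -> float:
    """ΔFA predicted by a surrogate at one point, degrees."""
    if warn_extrapolation:
        spec = DEFAULT_GRID
        inside = (
            spec.inclination[0] <= inclination <= spec.inclination[1]
            and spec.anteversion[0] <= anteversion <= spec.anteversion[1]
            and spec.tilt[0] <= tilt <= spec.tilt[1]
        )
        if not inside:
            logger.warning(
                "evaluating surrogate outside its fitting domain at "
                "I=%g, A=%g, PT=%g", inclination, anteversion, tilt,
            )
    return float(surrogate.predict([[inclination, anteversion, tilt]])[0])


def compare_surrogates(
    a: CubicDeltaFA, b: CubicDeltaFA, spec: GridSpec = DEFAULT_GRID
) -> float:
    """Maximum absolute prediction difference between two surrogates, degrees."""
    pts = np.array(
        [
            (i, av, t)
            for i in spec.axis("inclination")
            for av in spec.axis("anteversion")
            for t in spec.axis("tilt")
        ]
    )
    return float(np.max(np.abs(a.predict(pts) - b.predict(pts))))
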