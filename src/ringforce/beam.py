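"""Cantilever beam mechanics: deflection under a ring load and force calibration.

The tissue ring pulls each post toward the well centre at a height ``a``
above the base (the anchor height), while the camera observes the motion of
the post's top edge at height ``x`` (the tip by default).  For a prismatic
Euler-Bernoulli cantilever with a point load F at ``a``::

    delta(a)           = F a^3 / (3 E I)              (measured at the load)
    delta(x), x >= a   = F a^2 (3x - a) / (6 E I)     (measured above it)

The closed form ignores the tapered anchor tip; in practice that discrepancy
is absorbed by an empirical force-displacement calibration measured with a
micro-force transducer, which this module fits and inverts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ringforce.units import beam_deflection_um

__all__ = [
    "CantileverSpec",
    "LoadConfig",
    "CalibrationCurve",
    "CalibrationError",
    "ExtrapolationWarning",
    "second_moment",
    "theoretical_deflection",
    "stiffness_un_per_um",
    "fit_calibration",
    "force_from_deflection",
    "read_calibration_csv",
    "write_calibration_csv",
]


class CalibrationError(ValueError):
    """Raised for degenerate or insufficient calibration samples."""


class ExtrapolationWarning(UserWarning):
    """Displacement queried beyond twice the calibrated range."""


@dataclass(frozen=True)
class CantileverSpec:
    """Geometry and material of one elastomeric post.

    The cross-section is rectangular with the bending axis along
    ``thickness_mm`` (bending toward the well centre).  The anchor is the
    angled tip segment that keeps the tissue ring from slipping off; the
    ring therefore sits ``anchor_length_mm`` below the tip.

    Default numbers are synthetic placeholders for a soft elastomer post —
    the physical plates do not publish their dimensions, so any quantitative
    use should supply measured geometry or an empirical calibration.
    """

    length_mm: float = 3.0
    width_mm: float = 0.6
    thickness_mm: float = 0.6
    youngs_modulus_mpa: float = 1.5
    anchor_length_mm: float = 0.5
    anchor_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        for name in (
            "length_mm",
            "width_mm",
            "thickness_mm",
            "youngs_modulus_mpa",
            "anchor_length_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.anchor_length_mm < self.length_mm:
            raise ValueError("anchor_length_mm must be smaller than length_mm")
        if not 0 < self.anchor_angle_deg <= 90:
            raise ValueError("anchor_angle_deg must lie in (0, 90]")

    @property
    def second_moment_mm4(self) -> float:
        return second_moment(self)

    @property
    def default_load_height_mm(self) -> float:
        """Height at which the ring applies force: just below the anchor."""
        return self.length_mm - self.anchor_length_mm

    @classmethod
    def from_dict(cls, d: dict) -> "CantileverSpec":
        return cls(
            length_mm=d["length_mm"],
            width_mm=d["width_mm"],
            thickness_mm=d["thickness_mm"],
            youngs_modulus_mpa=d["youngs_modulus_mpa"],
            anchor_length_mm=d.get("anchor_length_mm", 0.5),
            anchor_angle_deg=d.get("anchor_angle_deg", 45.0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CantileverSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "length_mm": self.length_mm,
            "width_mm": self.width_mm,
            "thickness_mm": self.thickness_mm,
            "youngs_modulus_mpa": self.youngs_modulus_mpa,
            "anchor_length_mm": self.anchor_length_mm,
            "anchor_angle_deg": self.anchor_angle_deg,
        }


@dataclass(frozen=True)
class LoadConfig:
    """Where force is applied (``load_height_mm``) and motion observed.

    ``measure_height_mm=None`` means "at the tip", resolved against the
    cantilever length when the deflection is evaluated.
    """

    load_height_mm: float
    measure_height_mm: float | None = None

    def resolve(self, spec: CantileverSpec) -> tuple[float, float]:
        a = self.load_height_mm
        x = self.measure_height_mm if self.measure_height_mm is not None else spec.length_mm
        if not 0 < a <= spec.length_mm:
            raise ValueError(
                f"load_height_mm must lie in (0, {spec.length_mm}], got {a}"
            )
        if not a <= x <= spec.length_mm:
            raise ValueError(
                f"measure_height_mm must lie in [{a}, {spec.length_mm}], got {x}"
            )
        return a, x


def second_moment(spec: CantileverSpec) -> float:
    """Second moment of area of the rectangular section, I = w t^3 / 12 (mm^4)."""
    return spec.width_mm * spec.thickness_mm**3 / 12.0


def theoretical_deflection(
    force_un: float | np.ndarray,
    spec: CantileverSpec,
    load: LoadConfig | None = None,
) -> float | np.ndarray:
    """Small-deflection displacement (µm) at the observation height.

    Linear in force.  With ``load=None`` the ring is assumed to sit at the
    anchor (``length - anchor_length``) and the tip is observed.
    """
    if load is None:
        load = LoadConfig(load_height_mm=spec.default_load_height_mm)
    a, x = load.resolve(spec)
    force_un = np.asarray(force_un, dtype=float) if np.ndim(force_un) else float(force_un)
    if np.any(np.asarray(force_un) < 0):
        raise ValueError("force must be non-negative")
    geometry_mm3 = a * a * (3.0 * x - a) / 6.0
    return beam_deflection_um(
        force_un, geometry_mm3, spec.youngs_modulus_mpa, spec.second_moment_mm4
    )


def stiffness_un_per_um(spec: CantileverSpec, load: LoadConfig | None = None) -> float:
    """Effective stiffness k (µN per µm of observed deflection)."""
    return 1.0 / theoretical_deflection(1.0, spec, load)


@dataclass
class CalibrationCurve:
    """Fitted displacement→force map from transducer measurements.

    ``model_kind`` is ``"linear_through_origin"`` (single stiffness k, the
    small-deflection regime) or ``"cubic_polynomial"`` (full cubic with
    intercept, for large deflections).  Coefficients are stored in
    increasing-power order (µN per µm^p).
    """

    displacement_um: np.ndarray
    force_un: np.ndarray
    model_kind: str
    coefficients: np.ndarray
    load_height_mm: float | None = None
    residuals_un: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def stiffness_un_per_um(self) -> float:
        if self.model_kind != "linear_through_origin":
            raise ValueError("stiffness is only defined for the linear model")
        return float(self.coefficients[1])

    def predict(self, displacement_um: float | np.ndarray) -> np.ndarray:
        d = np.asarray(displacement_um, dtype=float)
        powers = np.arange(len(self.coefficients))
        return np.sum(self.coefficients * d[..., None] ** powers, axis=-1)


def fit_calibration(
    samples: Sequence[tuple[float, float]] | np.ndarray,
    model_kind: str = "linear_through_origin",
    load_height_mm: float | None = None,
) -> CalibrationCurve:
    """Least-squares fit of force (µN) against displacement (µm).

    Requires ≥ 2 samples for the linear model and ≥ 4 for the cubic;
    displacements must be strictly increasing and the fitted curve must be
    monotone non-decreasing over the sampled range.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CalibrationError("samples must be (displacement_um, force_un) pairs")
    d, f = arr[:, 0], arr[:, 1]
    if np.any(np.diff(d) <= 0):
        raise CalibrationError("displacements must be strictly increasing")
    if model_kind == "linear_through_origin":
        if len(d) < 2:
            raise CalibrationError("linear model needs at least 2 samples")
        k = float(np.dot(d, f) / np.dot(d, d))
        coeffs = np.array([0.0, k])
    elif model_kind == "cubic_polynomial":
        if len(d) < 4:
            raise CalibrationError("cubic model needs at least 4 samples")
        coeffs = np.polynomial.polynomial.polyfit(d, f, deg=3)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    powers = np.arange(len(coeffs))
    fitted = np.sum(coeffs * d[:, None] ** powers, axis=1)
    # monotonicity of the fitted map over the sampled range
    grid = np.linspace(d.min(), d.max(), 256)
    deriv_coeffs = coeffs[1:] * np.arange(1, len(coeffs))
    deriv = np.sum(deriv_coeffs * grid[:, None] ** np.arange(len(deriv_coeffs)), axis=1)
    if np.any(deriv < -1e-12 * max(1.0, np.abs(f).max())):
        raise CalibrationError("fitted force is not monotone over the sampled range")
    return CalibrationCurve(
        displacement_um=d,
        force_un=f,
        model_kind=model_kind,
        coefficients=coeffs,
        load_height_mm=load_height_mm,
        residuals_un=f - fitted,
    )


def force_from_deflection(
    displacement_um: float | np.ndarray, curve: CalibrationCurve
) -> float | np.ndarray:
    """Convert an observed deflection (µm) to contractile force (µN).

    Emits :class:`ExtrapolationWarning` when queried beyond twice the
    calibrated displacement range.
    """
    d = np.asarray(displacement_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("displacement must be non-negative")
    limit = 2.0 * curve.displacement_um.max()
    if np.any(d > limit):
        warnings.warn(
            f"displacement beyond 2x the calibrated range ({limit:.3g} µm); "
            "extrapolated force may be unreliable",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = curve.predict(d)
    return float(out) if np.ndim(displacement_um) == 0 else out


def read_calibration_csv(
    path: str | Path,
    model_kind: str = "linear_through_origin",
    load_height_mm: float | None = None,
) -> CalibrationCurve:
    """Read `displacement_um,force_uN` pairs and fit a calibration curve."""
    df = pd.read_csv(path)
    required = {"displacement_um", "force_uN"}
    if not required.issubset(df.columns):
        raise CalibrationError(f"calibration CSV must have columns {sorted(required)}")
    return fit_calibration(
        df[["displacement_um", "force_uN"]].to_numpy(),
        model_kind=model_kind,
        load_height_mm=load_height_mm,
    )


def write_calibration_csv(curve: CalibrationCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"displacement_um": curve.displacement_um, "force_uN": curve.force_un}
    ).to_csv(path, index=False)
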