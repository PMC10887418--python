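"""Core data model for AFM force curves and force volumes.

All quantities are stored in strict SI units (m, N, Pa, N/m); conversion to
display units (kPa, nm/V) happens only at I/O and reporting boundaries.

A force curve records cantilever deflection versus piezo position as the tip
is ramped toward (approach) or away from (retract) the sample.  The piezo
coordinate ``z_m`` increases toward the sample during an approach ramp, so
past the contact point the indentation is ``delta = (z - z0) - d`` with ``d``
the cantilever deflection in meters and force ``F = k * d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "TipKind",
    "ContactModelKind",
    "SampleClass",
    "DeflectionUnit",
    "Direction",
    "TipGeometry",
    "CantileverCalibration",
    "SampleClassSettings",
    "RawForceCurve",
    "ForceVolume",
    "validate_curve",
    "MIN_CURVE_SAMPLES",
]

MIN_CURVE_SAMPLES = 64

BOLTZMANN_J_PER_K = 1.380649e-23


class TipKind(str, Enum):
    PYRAMIDAL = "pyramidal"
    SPHERICAL = "spherical"


class ContactModelKind(str, Enum):
    SNEDDON = "sneddon"
    HERTZ = "hertz"


class SampleClass(str, Enum):
    CELL_2D = "cell_2d"
    HSR_WHOLE = "hsr_whole"
    CRYOSECTION = "cryosection"


class DeflectionUnit(str, Enum):
    VOLTS = "volts"
    METERS = "meters"


class Direction(str, Enum):
    APPROACH = "approach"
    RETRACT = "retract"


@dataclass(frozen=True)
class TipGeometry:
    """Indenter geometry: a pyramid (half-angle) or a sphere (radius).

    Exactly one of ``half_angle_deg`` / ``radius_m`` must be set, matching
    ``kind``.  ``nominal_apex_radius_m`` is manufacturer information only and
    plays no role in fitting.
    """

    kind: TipKind
    half_angle_deg: Optional[float] = None
    radius_m: Optional[float] = None
    nominal_apex_radius_m: Optional[float] = None

    def __post_init__(self) -> None:
        kind = TipKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is TipKind.PYRAMIDAL:
            if self.half_angle_deg is None or self.radius_m is not None:
                raise ValueError(
                    "pyramidal tip requires half_angle_deg and no radius_m"
                )
            if not 0.0 < self.half_angle_deg < 90.0:
                raise ValueError("half_angle_deg must lie in (0, 90)")
        else:
            if self.radius_m is None or self.half_angle_deg is not None:
                raise ValueError(
                    "spherical tip requires radius_m and no half_angle_deg"
                )
            if self.radius_m <= 0:
                raise ValueError("radius_m must be positive")


@dataclass(frozen=True)
class CantileverCalibration:
    """Spring constant and optical-lever sensitivity of one cantilever."""

    spring_constant_n_per_m: float
    deflection_sensitivity_m_per_v: Optional[float] = None
    method: str = "synthetic"

    def __post_init__(self) -> None:
        if self.spring_constant_n_per_m <= 0:
            raise ValueError("spring constant must be positive")
        if (
            self.deflection_sensitivity_m_per_v is not None
            and self.deflection_sensitivity_m_per_v <= 0
        ):
            raise ValueError("deflection sensitivity must be positive")


#: class-specific maximum indentation depths used for fitting
DEFAULT_MAX_INDENTATION_M = {
    SampleClass.CELL_2D: 2e-6,
    SampleClass.HSR_WHOLE: 5e-6,
    SampleClass.CRYOSECTION: 700e-9,
}

#: contact model conventionally paired with each sample class
DEFAULT_MODEL = {
    SampleClass.CELL_2D: ContactModelKind.SNEDDON,
    SampleClass.HSR_WHOLE: ContactModelKind.HERTZ,
    SampleClass.CRYOSECTION: ContactModelKind.SNEDDON,
}


@dataclass(frozen=True)
class SampleClassSettings:
    """Per-sample-class analysis settings.

    ``max_indentation_m`` defaults to the class convention (2 µm for 2D cell
    cultures, 5 µm for whole skin reconstructs, 700 nm for cryosections).
    ``thickness_m``, when known, enables the one-third depth rule check: a
    fit whose maximum indentation exceeds a third of the sample thickness is
    flagged as an apparent (Ea) rather than strict elastic modulus.
    """

    sample_class: SampleClass
    model: Optional[ContactModelKind] = None
    max_indentation_m: Optional[float] = None
    poisson_ratio: float = 0.3
    thickness_m: Optional[float] = None
    prefactor_two_pi: bool = False

    def __post_init__(self) -> None:
        sample_class = SampleClass(self.sample_class)
        object.__setattr__(self, "sample_class", sample_class)
        model = self.model
        if model is None:
            model = DEFAULT_MODEL[sample_class]
        object.__setattr__(self, "model", ContactModelKind(model))
        if self.max_indentation_m is None:
            object.__setattr__(
                self, "max_indentation_m", DEFAULT_MAX_INDENTATION_M[sample_class]
            )
        if self.max_indentation_m <= 0:
            raise ValueError("max_indentation_m must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.thickness_m is not None and self.thickness_m <= 0:
            raise ValueError("thickness_m must be positive")


@dataclass
class RawForceCurve:
    """One piezo-ramp/deflection trace with tip and calibration metadata.

    ``z_m`` must increase strictly on approach (piezo extending toward the
    sample) and decrease strictly on retract.  ``deflection`` is either in
    volts (a deflection sensitivity is then required to convert) or meters;
    the ``deflection_unit`` flag is mandatory — no unit guessing.
    """

    z_m: np.ndarray
    deflection: np.ndarray
    deflection_unit: DeflectionUnit
    direction: Direction
    tip: TipGeometry
    calibration: CantileverCalibration
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_m = np.asarray(self.z_m, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        self.deflection_unit = DeflectionUnit(self.deflection_unit)
        self.direction = Direction(self.direction)

    @property
    def n_samples(self) -> int:
        return self.z_m.size

    def deflection_m(self) -> np.ndarray:
        """Deflection in meters, converting from volts if needed."""
        if self.deflection_unit is DeflectionUnit.METERS:
            return self.deflection
        sens = self.calibration.deflection_sensitivity_m_per_v
        if sens is None:
            raise ValueError(
                "deflection is in volts but no deflection sensitivity is set"
            )
        return self.deflection * sens

    def with_deflection_m(self, deflection_m: np.ndarray) -> "RawForceCurve":
        """Copy of this curve with deflection replaced (in meters)."""
        return replace(
            self,
            deflection=np.asarray(deflection_m, dtype=float),
            deflection_unit=DeflectionUnit.METERS,
            labels=dict(self.labels),
        )


def validate_curve(curve: RawForceCurve) -> list[str]:
    """Check curve invariants; return human-readable violations (never raises)."""
    violations: list[str] = []
    z = np.asarray(curve.z_m, dtype=float)
    d = np.asarray(curve.deflection, dtype=float)
    if z.ndim != 1 or d.ndim != 1:
        violations.append("z and deflection must be one-dimensional")
        return violations
    if z.size != d.size:
        violations.append(
            f"length mismatch: {z.size} z samples vs {d.size} deflection samples"
        )
    if z.size < MIN_CURVE_SAMPLES:
        violations.append(
            f"too few samples: {z.size} < {MIN_CURVE_SAMPLES}"
        )
    dz = np.diff(z)
    if curve.direction is Direction.APPROACH and not np.all(dz > 0):
        violations.append("z not strictly monotone increasing on approach")
    if curve.direction is Direction.RETRACT and not np.all(dz < 0):
        violations.append("z not strictly monotone decreasing on retract")
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(d)):
        violations.append("non-finite values in z or deflection")
    if (
        curve.deflection_unit is DeflectionUnit.VOLTS
        and curve.calibration.deflection_sensitivity_m_per_v is None
    ):
        violations.append("deflection in volts without a deflection sensitivity")
    return violations


@dataclass
class ForceVolume:
    """A rectangular grid of force curves acquired over a scan area."""

    grid: list[list[RawForceCurve]]
    pixel_pitch_m: float
    scan_area_m2: Optional[float] = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grid or not self.grid[0]:
            raise ValueError("force volume grid must be non-empty")
        ncols = len(self.grid[0])
        if any(len(row) != ncols for row in self.grid):
            raise ValueError("force volume grid must be rectangular")
        first = self.grid[0][0]
        for row in self.grid:
            for c in row:
                if c.tip != first.tip or c.calibration != first.calibration:
                    raise ValueError(
                        "all curves in a force volume must share tip and calibration"
                    )
        if self.pixel_pitch_m <= 0:
            raise ValueError("pixel_pitch_m must be positive")
        if self.scan_area_m2 is None:
            self.scan_area_m2 = (
                self.rows * self.cols * self.pixel_pitch_m**2
            )

    @property
    def rows(self) -> int:
        return len(self.grid)

    @property
    def cols(self) -> int:
        return len(self.grid[0])

    @property
    def n_curves(self) -> int:
        return self.rows * self.cols

    def curves(self) -> list[RawForceCurve]:
        """Row-major flat list of all curves."""
        return [c for row in self.grid for c in row]
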