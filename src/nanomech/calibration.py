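"""Cantilever calibration: deflection sensitivity and thermal-tune spring constant.

The optical-lever sensitivity (meters of deflection per photodiode volt) is
measured by pressing the tip on an effectively rigid substrate (sapphire),
where every nanometer of piezo travel past contact becomes a nanometer of
deflection.  The spring constant comes from the thermal tune: by
equipartition a cantilever in thermal equilibrium fluctuates with
``(1/2) k <x^2> = (1/2) k_B T`` per mode, and the first-mode correction
factor beta = 0.971 accounts for the fraction of the total thermal variance
carried by the fundamental flexural mode of a rectangular lever, so

    k = beta * k_B * T / var(deflection)

Stiff levers shipped with a manufacturer-certified spring constant skip the
thermal tune; the pipeline accepts externally supplied constants for those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import BOLTZMANN_J_PER_K, RawForceCurve, DeflectionUnit

__all__ = [
    "ThermalTrace",
    "deflection_sensitivity_from_contact",
    "spring_constant_thermal",
    "CalibrationError",
    "FIRST_MODE_CORRECTION",
]

#: fundamental-mode fraction of thermal variance for a rectangular cantilever
FIRST_MODE_CORRECTION = 0.971

#: minimum R^2 for a contact-region line to count as linear
_CONTACT_R2 = 0.99
_MIN_WINDOW = 16


class CalibrationError(RuntimeError):
    """Raised when a calibration quantity cannot be extracted."""


@dataclass
class ThermalTrace:
    """Time series of thermal cantilever deflection, in meters."""

    deflection_m: np.ndarray
    sample_rate_hz: float
    temperature_k: float = 298.0

    def __post_init__(self) -> None:
        self.deflection_m = np.asarray(self.deflection_m, dtype=float)
        if self.deflection_m.size < 4096:
            raise ValueError("thermal trace requires at least 4096 samples")
        if not 250.0 < self.temperature_k < 350.0:
            raise ValueError("temperature outside the plausible (250, 350) K range")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")


def deflection_sensitivity_from_contact(curve: RawForceCurve) -> float:
    """Deflection sensitivity (m/V) from a contact curve on a rigid substrate.

    The deflection signal must be in volts.  Sliding windows anchored at the
    high-z (pressed-in) end of the ramp are fitted with straight lines; the
    longest window with R^2 >= 0.99 defines the contact slope (V/m), and the
    sensitivity is its inverse.  Deterministic — no per-curve tuning.
    """
    if curve.deflection_unit is not DeflectionUnit.VOLTS:
        raise CalibrationError("sensitivity calibration requires deflection in volts")
    z = np.asarray(curve.z_m, dtype=float)
    v = np.asarray(curve.deflection, dtype=float)
    n = z.size
    if n < 2 * _MIN_WINDOW:
        raise CalibrationError("curve too short for sensitivity calibration")

    best_len, best_slope = 0, None
    # grow the window down from the high-z end
    for length in range(_MIN_WINDOW, n + 1, _MIN_WINDOW // 2):
        zz, vv = z[n - length :], v[n - length :]
        slope, intercept = np.polyfit(zz, vv, 1)
        pred = intercept + slope * zz
        ss_tot = float(np.sum((vv - vv.mean()) ** 2))
        if ss_tot <= 0:
            continue
        r2 = 1.0 - float(np.sum((vv - pred) ** 2)) / ss_tot
        if r2 >= _CONTACT_R2 and length > best_len:
            best_len, best_slope = length, slope
    if best_slope is None or best_slope <= 0:
        raise CalibrationError(
            "no linear contact region found (best-segment R^2 < 0.99)"
        )
    # the longest admissible window may clip the kink at the contact point;
    # trim residual outliers so the slope comes from the pure contact line
    zz, vv = z[n - best_len :], v[n - best_len :]
    keep = np.ones(zz.size, dtype=bool)
    slope = best_slope
    for _ in range(12):
        slope, intercept = np.polyfit(zz[keep], vv[keep], 1)
        resid = vv - (intercept + slope * zz)
        sd = float(np.std(resid[keep]))
        if sd == 0:
            break
        new_keep = np.abs(resid) <= 3.0 * sd
        if new_keep.sum() < _MIN_WINDOW or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    if slope <= 0:
        raise CalibrationError("contact-line slope is not positive")
    return 1.0 / float(slope)


def spring_constant_thermal(trace: ThermalTrace) -> float:
    """Spring constant (N/m) from a thermal-noise trace via equipartition.

    The trace mean is removed internally; k = beta * k_B * T / var(d).
    """
    d = trace.deflection_m - trace.deflection_m.mean()
    var = float(np.mean(d**2))
    if var <= 0:
        raise CalibrationError("zero-variance trace: no thermal signal")
    k = FIRST_MODE_CORRECTION * BOLTZMANN_J_PER_K * trace.temperature_k / var
    if not np.isfinite(k) or k <= 0:
        raise CalibrationError("non-finite spring constant")
    return k
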