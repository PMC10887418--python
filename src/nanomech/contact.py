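"""Contact-mechanics modulus extraction from AFM force curves.

The pipeline converts a raw deflection-vs-piezo trace into force versus
indentation and fits one of two contact models to extract the Young's
modulus E:

* **Sneddon** (conical/pyramidal indenter, half-angle alpha)::

      F = (2/pi) * E / (1 - nu^2) * tan(alpha) * delta^2

* **Hertz** (spherical indenter, radius R)::

      F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

Both laws are linear in E, so for a fixed contact point the least-squares
modulus is available in closed form, E = sum(F*g) / sum(g^2) with g the
geometry term (F = E*g(delta)).  The only search dimension is the contact
index, located by a deterministic coarse-to-fine scan that minimises the
combined squared residual of a zero-force baseline before contact and the
contact model after contact.

Fitting is restricted to the class-specific indentation window (2 um for 2D
cells, 5 um for whole skin reconstructs, 700 nm for cryosections).  When the
sample thickness is known and the maximum indentation used exceeds one third
of it, the result is flagged as an apparent modulus (Ea) rather than a
strict elastic modulus; when the thickness is unknown the fit carries an
explicit note instead of a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .curves import (
    ContactModelKind,
    RawForceCurve,
    SampleClassSettings,
    TipGeometry,
    TipKind,
)

__all__ = [
    "sneddon_force",
    "hertz_force",
    "geometry_term",
    "solve_deflection",
    "correct_baseline",
    "find_contact_point",
    "build_indentation",
    "fit_modulus",
    "IndentationCurve",
    "ElasticFit",
    "IndentationModel",
    "IndentationResults",
    "PoorFitError",
]

#: minimum piecewise-fit R^2 below which contact detection reports failure
MIN_CONTACT_R2 = 0.8
#: minimum number of samples inside the indentation window
MIN_FIT_POINTS = 10
#: coarse contact-scan stride, refined exhaustively within +-stride
CONTACT_SCAN_STRIDE = 8


class PoorFitError(RuntimeError):
    """No contact point achieves an acceptable piecewise fit."""


def sneddon_force(
    modulus_pa: float,
    poisson_ratio: float,
    half_angle_deg: float,
    delta_m,
    *,
    prefactor_two_pi: bool = False,
):
    """Sneddon force law for a conical/pyramidal indenter.

    ``prefactor_two_pi`` switches the leading constant from the canonical
    2/pi to 2*pi, preserved as a sensitivity option.
    """
    delta = np.asarray(delta_m, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if modulus_pa <= 0:
        raise ValueError("modulus must be positive")
    pref = 2.0 * math.pi if prefactor_two_pi else 2.0 / math.pi
    out = (
        pref
        * modulus_pa
        / (1.0 - poisson_ratio**2)
        * math.tan(math.radians(half_angle_deg))
        * delta**2
    )
    return out if out.ndim else float(out)


def hertz_force(modulus_pa: float, poisson_ratio: float, radius_m: float, delta_m):
    """Hertz force law for a spherical indenter of radius R."""
    delta = np.asarray(delta_m, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if modulus_pa <= 0:
        raise ValueError("modulus must be positive")
    if radius_m <= 0:
        raise ValueError("tip radius must be positive")
    out = (
        (4.0 / 3.0)
        * modulus_pa
        / (1.0 - poisson_ratio**2)
        * math.sqrt(radius_m)
        * delta**1.5
    )
    return out if out.ndim else float(out)


def geometry_term(
    delta_m: np.ndarray, tip: TipGeometry, settings: SampleClassSettings
) -> np.ndarray:
    """g(delta) such that F = E * g(delta) for the configured contact model."""
    delta = np.asarray(delta_m, dtype=float)
    if settings.model is ContactModelKind.SNEDDON:
        if tip.kind is not TipKind.PYRAMIDAL:
            raise ValueError("Sneddon model requires a pyramidal tip")
        pref = 2.0 * math.pi if settings.prefactor_two_pi else 2.0 / math.pi
        return (
            pref
            / (1.0 - settings.poisson_ratio**2)
            * math.tan(math.radians(tip.half_angle_deg))
            * delta**2
        )
    if tip.kind is not TipKind.SPHERICAL:
        raise ValueError("Hertz model requires a spherical tip")
    return (
        (4.0 / 3.0)
        / (1.0 - settings.poisson_ratio**2)
        * math.sqrt(tip.radius_m)
        * delta**1.5
    )


def _model_power_and_const(
    tip: TipGeometry, settings: SampleClassSettings
) -> tuple[float, float]:
    """(p, C) with g(delta) = C * delta**p for the configured model."""
    p = 2.0 if settings.model is ContactModelKind.SNEDDON else 1.5
    return p, float(geometry_term(1.0, tip, settings))


def solve_deflection(
    z_past: np.ndarray,
    modulus_pa: float,
    tip: TipGeometry,
    settings: SampleClassSettings,
    spring_constant: float,
) -> np.ndarray:
    """Model deflection d solving k*d = E*g((z - z0) - d), z_past = z - z0 >= 0.

    Solved for the indentation delta via Newton iteration on the convex
    monotone residual E*C*delta**p + k*delta - k*z'; starting from
    delta = z' the iterates decrease monotonically to the root, reaching
    machine precision in a handful of steps.
    """
    zp = np.asarray(z_past, dtype=float)
    p, c = _model_power_and_const(tip, settings)
    ec = modulus_pa * c
    k = spring_constant
    delta = zp.copy()
    for _ in range(60):
        f = ec * delta**p + k * delta - k * zp
        fp = p * ec * delta ** (p - 1.0) + k
        step = f / fp
        new = np.clip(delta - step, 0.0, zp)
        if np.all(np.abs(new - delta) <= 1e-16 * (1.0 + np.abs(delta))):
            delta = new
            break
        delta = new
    return zp - delta


@dataclass
class IndentationCurve:
    """Force versus indentation past the contact point.

    ``delta_m`` starts at zero at the contact sample; ``baseline`` records
    the (intercept, slope) of the pre-contact force line that was removed.
    """

    delta_m: np.ndarray
    force_n: np.ndarray
    contact_index: int
    contact_z_m: float
    baseline: tuple[float, float] = (0.0, 0.0)


@dataclass
class ElasticFit:
    """Young's modulus and diagnostics for one curve."""

    modulus_pa: float
    contact_index: int
    rmse_n: float
    delta_max_m: float
    n_points_fit: int
    flags: set = field(default_factory=set)
    note: str = ""

    @property
    def valid(self) -> bool:
        return "poor_fit" not in self.flags and np.isfinite(self.modulus_pa)

    @property
    def modulus_kpa(self) -> float:
        return self.modulus_pa / 1e3


def correct_baseline(
    curve: RawForceCurve, precontact_fraction: float = 0.3
) -> RawForceCurve:
    """Remove the pre-contact deflection line (tilt plus offset).

    An ordinary least-squares line is fitted to the first
    ``precontact_fraction`` of samples (the off-contact end of an approach
    ramp) and subtracted from the whole trace, leaving the pre-contact
    deflection with zero mean and zero slope.  The removed line, expressed
    in force units, is recorded in the returned curve's labels.
    """
    if not 0.0 < precontact_fraction <= 1.0:
        raise ValueError("precontact_fraction must lie in (0, 1]")
    d = curve.deflection_m()
    z = curve.z_m
    n = max(2, int(round(precontact_fraction * d.size)))
    slope, intercept = np.polyfit(z[:n], d[:n], 1)
    corrected = d - (intercept + slope * z)
    out = curve.with_deflection_m(corrected)
    k = curve.calibration.spring_constant_n_per_m
    out.labels["baseline_intercept_n"] = float(intercept * k)
    out.labels["baseline_slope_n_per_m"] = float(slope * k)
    return out


def _contact_objective(
    force: np.ndarray,
    z: np.ndarray,
    d: np.ndarray,
    j: int,
    tip: TipGeometry,
    settings: SampleClassSettings,
) -> tuple[float, float]:
    """(total squared residual, closed-form E) for contact candidate j."""
    pre_ss = float(np.dot(force[:j], force[:j]))
    delta = (z[j:] - z[j]) - d[j:]
    mask = delta > 0
    if mask.sum() < 2:
        return pre_ss + float(np.dot(force[j:], force[j:])), np.nan
    g = geometry_term(delta[mask], tip, settings)
    f = force[j:][mask]
    denom = float(np.dot(g, g))
    if denom <= 0:
        return np.inf, np.nan
    e = float(np.dot(f, g)) / denom
    if not np.isfinite(e) or e <= 0:
        return pre_ss + float(np.dot(f, f)), np.nan
    resid = f - e * g
    return pre_ss + float(np.dot(resid, resid)), e


def find_contact_point(
    curve: RawForceCurve,
    tip: Optional[TipGeometry] = None,
    settings: Optional[SampleClassSettings] = None,
) -> int:
    """Locate the contact sample index on a baseline-corrected approach curve.

    Coarse scan every :data:`CONTACT_SCAN_STRIDE` samples, exhaustive
    refinement within one stride of the coarse optimum; ties break toward
    the smaller index, so the search is deterministic.  Raises
    :class:`PoorFitError` when no candidate achieves a piecewise fit
    R^2 >= 0.8.
    """
    if tip is None:
        tip = curve.tip
    if settings is None:
        raise ValueError("settings are required to choose the contact model")
    d = curve.deflection_m()
    z = curve.z_m
    k = curve.calibration.spring_constant_n_per_m
    force = k * d
    n = force.size

    lo, hi = 2, n - MIN_FIT_POINTS
    if hi <= lo:
        raise PoorFitError("curve too short for contact search")
    coarse = list(range(lo, hi, CONTACT_SCAN_STRIDE))
    best_j, best_ss, best_e = None, np.inf, np.nan
    for j in coarse:
        ss, e = _contact_objective(force, z, d, j, tip, settings)
        if ss < best_ss:
            best_j, best_ss, best_e = j, ss, e
    refine_lo = max(lo, best_j - CONTACT_SCAN_STRIDE)
    refine_hi = min(hi, best_j + CONTACT_SCAN_STRIDE + 1)
    for j in range(refine_lo, refine_hi):
        ss, e = _contact_objective(force, z, d, j, tip, settings)
        if ss < best_ss:
            best_j, best_ss, best_e = j, ss, e

    ss_tot = float(np.sum((force - force.mean()) ** 2))
    if ss_tot <= 0 or not np.isfinite(best_e):
        raise PoorFitError("no informative signal in curve")
    r2 = 1.0 - best_ss / ss_tot
    if r2 < MIN_CONTACT_R2:
        raise PoorFitError(
            f"best piecewise contact fit R^2 = {r2:.3f} < {MIN_CONTACT_R2}"
        )
    return int(best_j)


def build_indentation(
    curve: RawForceCurve, contact_index: int
) -> IndentationCurve:
    """Convert a (baseline-corrected) curve to force vs indentation.

    Uses the standard AFM relations F = k*d and delta = (z - z0) - d with d
    the deflection in meters; the indentation axis is shifted so that
    delta[0] = 0 exactly at the contact sample.
    """
    if not 0 <= contact_index < curve.n_samples:
        raise ValueError("contact_index out of range")
    d = curve.deflection_m()[contact_index:]
    z = curve.z_m[contact_index:]
    k = curve.calibration.spring_constant_n_per_m
    delta = (z - z[0]) - d
    delta = delta - delta[0]
    baseline = (
        curve.labels.get("baseline_intercept_n", 0.0),
        curve.labels.get("baseline_slope_n_per_m", 0.0),
    )
    return IndentationCurve(
        delta_m=delta,
        force_n=k * d,
        contact_index=int(contact_index),
        contact_z_m=float(z[0]),
        baseline=baseline,
    )


def _dspace_ssr(
    z: np.ndarray,
    d: np.ndarray,
    z0: float,
    modulus_pa: float,
    tip: TipGeometry,
    settings: SampleClassSettings,
    spring_constant: float,
) -> float:
    """Deflection-space residual: zero before contact, model after.

    The measurement noise lives in the deflection channel, so residuals in
    deflection units are homoscedastic across the whole trace — unlike the
    force-vs-indentation residual, whose variance is inflated by the factor
    (1 + E*g'/k)^2 wherever the contact stiffness exceeds the lever's.
    """
    if not np.isfinite(modulus_pa) or modulus_pa <= 0:
        return np.inf
    i = int(np.searchsorted(z, z0))
    ssr = float(np.dot(d[:i], d[:i]))
    if i < z.size:
        dm = solve_deflection(z[i:] - z0, modulus_pa, tip, settings, spring_constant)
        r = d[i:] - dm
        ssr += float(np.dot(r, r))
    return ssr


def _stiff_estimator(
    z: np.ndarray,
    d: np.ndarray,
    tip: TipGeometry,
    settings: SampleClassSettings,
    spring_constant: float,
) -> tuple[float, float]:
    """Closed-form (z0, E) from regressing z on deflection.

    Past contact z = z0 + d + delta(d) with delta(d) = (k*d/(C*E))**(1/p),
    so z - d is linear in [1, (k*d/C)**(1/p)] with coefficients
    (z0, E**(-1/p)).  Deflection noise is barely amplified when the contact
    stiffness exceeds the lever stiffness, making this the estimator of
    choice for stiff samples probed with a soft lever.  Samples are admitted
    once their deflection clears 8 robust SDs of the early-trace noise.
    """
    p, c = _model_power_and_const(tip, settings)
    n0 = max(16, d.size // 4)
    sigma = 1.4826 * float(np.median(np.abs(d[:n0] - np.median(d[:n0]))))
    mask = d > max(8.0 * sigma, 1e-15)
    if mask.sum() < MIN_FIT_POINTS:
        raise PoorFitError("too few clearly-in-contact samples")
    dd, zz = d[mask], z[mask]
    h = (spring_constant * dd / c) ** (1.0 / p)
    design = np.column_stack([np.ones_like(zz), h])
    coef, *_ = np.linalg.lstsq(design, zz - dd, rcond=None)
    z0, q = float(coef[0]), float(coef[1])
    if q <= 0:
        raise PoorFitError("non-physical geometry coefficient")
    return z0, q**-p


def fit_modulus(
    curve: RawForceCurve,
    settings: SampleClassSettings,
    precontact_fraction: float = 0.3,
) -> ElasticFit:
    """Extract the Young's modulus of one approach curve.

    Equivalent to ``IndentationModel(curve, settings).fit().elastic_fit``.
    """
    return IndentationModel(
        curve, settings, precontact_fraction=precontact_fraction
    ).fit().elastic_fit


class IndentationModel:
    """Contact-mechanics model bound to one raw force curve.

    Parameters
    ----------
    curve:
        Approach force curve (deflection in volts with a sensitivity, or
        meters).
    settings:
        Sample-class settings: contact model, indentation window, Poisson
        ratio, optional thickness.
    precontact_fraction:
        Fraction of the trace used for the first baseline pass; the baseline
        is re-fitted on the region up to 90% of the detected contact and the
        contact search repeated, so the result is insensitive to the initial
        guess as long as it overlaps the off-contact segment.
    """

    def __init__(
        self,
        curve: RawForceCurve,
        settings: SampleClassSettings,
        precontact_fraction: float = 0.3,
    ) -> None:
        if settings.model is ContactModelKind.SNEDDON:
            if curve.tip.kind is not TipKind.PYRAMIDAL:
                raise ValueError(
                    "Sneddon settings require a pyramidal tip "
                    f"(got {curve.tip.kind.value})"
                )
        elif curve.tip.kind is not TipKind.SPHERICAL:
            raise ValueError(
                f"Hertz settings require a spherical tip (got {curve.tip.kind.value})"
            )
        self.curve = curve
        self.settings = settings
        self.precontact_fraction = precontact_fraction

    def _joint_estimate(
        self, corrected: RawForceCurve
    ) -> Optional[tuple[float, float, float]]:
        """Best (z0, E, ssr) for one baseline-corrected curve, or None.

        Two complementary initialisations — the discrete closed-form contact
        search (accurate when the sample is softer than the lever) and the
        z-on-deflection regression (accurate when it is stiffer) — are
        scored by the deflection-space residual, and the winner is polished
        by a Nelder–Mead minimisation of that residual over continuous
        (z0, log E).  Exact fits (noiseless curves) short-circuit the
        polish, which keeps them exact to machine precision.
        """
        curve, settings = self.curve, self.settings
        k = curve.calibration.spring_constant_n_per_m
        z = corrected.z_m
        d = corrected.deflection_m()
        candidates: list[tuple[float, float]] = []
        try:
            j = find_contact_point(corrected, curve.tip, settings)
            delta = (z[j:] - z[j]) - d[j:]
            m = (delta > 0) & (delta <= settings.max_indentation_m)
            if m.sum() >= MIN_FIT_POINTS:
                g = geometry_term(delta[m], curve.tip, settings)
                f = k * d[j:][m]
                e0 = float(np.dot(f, g) / np.dot(g, g))
                if np.isfinite(e0) and e0 > 0:
                    candidates.append((float(z[j]), e0))
        except PoorFitError:
            pass
        try:
            candidates.append(_stiff_estimator(z, d, curve.tip, settings, k))
        except PoorFitError:
            pass
        candidates = [
            c for c in candidates if np.isfinite(c[1]) and c[1] > 0
        ]
        if not candidates:
            return None

        def ssr_of(z0: float, e: float) -> float:
            return _dspace_ssr(z, d, z0, e, curve.tip, settings, k)

        scored = sorted((ssr_of(z0, e), z0, e) for z0, e in candidates)
        ssr0, z0, e = scored[0]
        scale = float(np.dot(d, d))
        if scale > 0 and ssr0 / scale > 1e-26:
            from scipy.optimize import minimize

            dz = float(np.median(np.diff(z)))

            def objective(u):
                return ssr_of(u[0] * dz, 10.0 ** u[1])

            res = minimize(
                objective,
                [z0 / dz, np.log10(e)],
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-10 * ssr0, "maxiter": 300},
            )
            if np.isfinite(res.fun) and res.fun <= ssr0:
                z0, e, ssr0 = float(res.x[0] * dz), float(10.0 ** res.x[1]), float(res.fun)
        return z0, e, ssr0

    def _poor_fit(self, note: str, corrected: RawForceCurve) -> "IndentationResults":
        fit = ElasticFit(
            modulus_pa=float("nan"),
            contact_index=-1,
            rmse_n=float("nan"),
            delta_max_m=0.0,
            n_points_fit=0,
            flags={"poor_fit"},
            note=note,
        )
        return IndentationResults(self, fit, None, corrected)

    def fit(self) -> "IndentationResults":
        curve, settings = self.curve, self.settings
        k = curve.calibration.spring_constant_n_per_m
        corrected = correct_baseline(curve, self.precontact_fraction)
        est = self._joint_estimate(corrected)
        if est is not None:
            # re-fit the baseline on the actually-off-contact region when the
            # first window overlapped the detected contact
            i0 = int(np.searchsorted(curve.z_m, est[0]))
            frac = 0.9 * i0 / curve.n_samples
            if 0.02 < frac < self.precontact_fraction:
                corrected2 = correct_baseline(curve, frac)
                est2 = self._joint_estimate(corrected2)
                if est2 is not None:
                    corrected, est = corrected2, est2
        if est is None:
            return self._poor_fit("no viable contact-point candidate", corrected)
        z0, e, ssr = est

        z = corrected.z_m
        d = corrected.deflection_m()
        ss_tot = float(np.sum((d - d.mean()) ** 2))
        if ss_tot <= 0 or 1.0 - ssr / ss_tot < MIN_CONTACT_R2:
            return self._poor_fit(
                "deflection-space fit R^2 below threshold", corrected
            )

        contact_index = int(np.clip(np.searchsorted(z, z0), 0, z.size - 1))
        indent = build_indentation(corrected, contact_index)

        # diagnostics over the class indentation window, on the model axis
        i = int(np.searchsorted(z, z0))
        d_model = solve_deflection(z[i:] - z0, e, curve.tip, settings, k)
        delta_model = (z[i:] - z0) - d_model
        mask = (delta_model > 0) & (delta_model <= settings.max_indentation_m)
        flags: set = set()
        note = ""
        if mask.sum() < MIN_FIT_POINTS:
            return self._poor_fit(
                f"fewer than {MIN_FIT_POINTS} samples inside the indentation window",
                corrected,
            )
        resid_n = k * (d[i:][mask] - d_model[mask])
        rmse = float(np.sqrt(np.mean(resid_n**2)))
        delta_max = float(delta_model[mask].max())
        if delta_model[~mask].size and delta_model[~mask].max(initial=0.0) > 0:
            pass  # deeper samples exist but lie beyond the class window
        else:
            flags.add("depth_truncated")
        if settings.thickness_m is not None:
            if delta_max > settings.thickness_m / 3.0:
                flags.add("thickness_rule_violated")
                flags.add("apparent_modulus_Ea")
        else:
            note = "thickness unknown: one-third depth rule not checked"
        fit = ElasticFit(
            modulus_pa=e,
            contact_index=contact_index,
            rmse_n=rmse,
            delta_max_m=delta_max,
            n_points_fit=int(mask.sum()),
            flags=flags,
            note=note,
        )
        return IndentationResults(self, fit, indent, corrected)


class IndentationResults:
    """Fit results for one curve: modulus, contact point, diagnostics."""

    def __init__(
        self,
        model: IndentationModel,
        elastic_fit: ElasticFit,
        indentation: Optional[IndentationCurve],
        corrected_curve: RawForceCurve,
    ) -> None:
        self.model = model
        self.elastic_fit = elastic_fit
        self.indentation = indentation
        self.corrected_curve = corrected_curve

    @property
    def modulus_pa(self) -> float:
        return self.elastic_fit.modulus_pa

    @property
    def modulus_kpa(self) -> float:
        return self.elastic_fit.modulus_kpa

    @property
    def contact_index(self) -> int:
        return self.elastic_fit.contact_index

    @property
    def flags(self) -> set:
        return self.elastic_fit.flags

    def predicted_force(self) -> np.ndarray:
        """Model force over the fitted indentation range."""
        if self.indentation is None:
            raise ValueError("no indentation curve (poor fit)")
        g = geometry_term(
            np.clip(self.indentation.delta_m, 0, None),
            self.model.curve.tip,
            self.model.settings,
        )
        return self.elastic_fit.modulus_pa * g

    def summary(self) -> str:
        f = self.elastic_fit
        s = self.model.settings
        lines = [
            "Indentation fit summary",
            "=" * 40,
            f"model:             {s.model.value}",
            f"sample class:      {s.sample_class.value}",
            f"Young's modulus:   {f.modulus_kpa:.4g} kPa",
            f"contact index:     {f.contact_index}",
            f"max indentation:   {f.delta_max_m * 1e9:.1f} nm",
            f"points in fit:     {f.n_points_fit}",
            f"residual RMS:      {f.rmse_n:.3g} N",
            f"flags:             {sorted(f.flags) if f.flags else 'none'}",
        ]
        if f.note:
            lines.append(f"note:              {f.note}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Force-indentation data with the fitted model overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.indentation is not None:
            ax.plot(
                self.indentation.delta_m * 1e9,
                self.indentation.force_n * 1e9,
                ".",
                ms=2,
                label="data",
            )
            if self.elastic_fit.valid:
                ax.plot(
                    self.indentation.delta_m * 1e9,
                    self.predicted_force() * 1e9,
                    "-",
                    label=f"fit: {self.elastic_fit.modulus_kpa:.3g} kPa",
                )
        ax.set_xlabel("indentation (nm)")
        ax.set_ylabel("force (nN)")
        ax.legend()
        return ax
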