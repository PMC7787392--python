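"""Inverse dose prediction with propagated uncertainty.

Given a fitted calibration curve ΔE(dose; a, b) and a measured color change
ΔE, the unknown dose is predicted through the inverse fit function:

    first order:   dose(ΔE) = −b·ln(1 − ΔE/a)
    second order:  dose(ΔE) = ΔE / (½·a²·b − a·b·ΔE)

The standard uncertainty of the predicted dose combines the fit-parameter
covariance and the ΔE measurement noise by the delta method:

    u_dose² = (∂d/∂a)²·s_a² + (∂d/∂b)²·s_b² + (∂d/∂ΔE)²·s_ΔE²
              + 2·(∂d/∂a)·(∂d/∂b)·s_ab

with analytic partial derivatives of the inverse function.  Confidence
intervals use the Student-t quantile at the calibration fit's residual
degrees of freedom: CI = dose ± u_dose·t(1−α/2, ν).  The relative CI width
is the full width divided by the dose; "relative uncertainty" is half of
that, matching the convention in which a 12.1% relative CI width is quoted
as 6.05% relative uncertainty.

As ΔE approaches the curve's asymptote the partials diverge, so inversion
is refused above a configurable guard fraction of the asymptote and flagged
with a warning above a lower near-saturation fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .calibration import KineticCalibration

__all__ = [
    "DoseEstimate",
    "NormalizedDose",
    "SaturationError",
    "invert_dose",
    "inverse_partials",
    "dose_uncertainty",
    "confidence_interval",
    "equalize_replicates",
    "combine_uncertainty",
    "normalize_dose",
    "nongermicidal_fraction",
]


class SaturationError(ValueError):
    """ΔE is at or beyond the usable range of the calibration curve."""


@dataclass
class DoseEstimate:
    """A predicted dose with its propagated uncertainty and CI (mJ/cm²)."""

    dose: float
    u_dose: float
    ci_low: float
    ci_high: float
    alpha: float
    source_delta_e: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.u_dose < 0:
            raise ValueError("u_dose must be >= 0")
        if not (self.ci_low <= self.dose <= self.ci_high):
            raise ValueError("CI must bracket the dose estimate")

    @property
    def rel_ci_width(self) -> float:
        """Full CI width divided by the dose (dimensionless)."""
        if self.dose == 0:
            return math.nan
        return (self.ci_high - self.ci_low) / self.dose

    @property
    def rel_uncertainty(self) -> float:
        """Half the relative CI width."""
        return self.rel_ci_width / 2.0

    def scaled(self, factor: float) -> "DoseEstimate":
        """Multiply dose, CI bounds and standard uncertainty by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return DoseEstimate(
            dose=self.dose * factor,
            u_dose=self.u_dose * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            alpha=self.alpha,
            source_delta_e=self.source_delta_e,
            flags=self.flags,
        )


@dataclass
class NormalizedDose:
    """A dose ratio dose_meas/dose_ref with propagated uncertainty."""

    dose_norm: float
    u_norm: float
    u_total_meas: float
    u_total_ref: float

    def __post_init__(self) -> None:
        if self.u_norm < 0:
            raise ValueError("u_norm must be >= 0")


# --------------------------------------------------------------------------

def _check_invertible(model: KineticCalibration, delta_e: float,
                      guard: Optional[float]) -> None:
    if delta_e < 0:
        raise ValueError(f"delta_e must be >= 0, got {delta_e}")
    asym = model.asymptote_
    if delta_e >= asym:
        raise SaturationError(
            f"ΔE={delta_e:g} is at/above the calibration asymptote {asym:g} "
            f"({model.order}-order); the indicator is saturated"
        )
    g = model.saturation_guard if guard is None else guard
    if delta_e > g * asym:
        raise SaturationError(
            f"ΔE={delta_e:g} exceeds the saturation guard "
            f"{g:g}×asymptote = {g * asym:g} (asymptote {asym:g})"
        )


def invert_dose(model: KineticCalibration, delta_e: float,
                guard: Optional[float] = None) -> float:
    """Dose (mJ/cm²) whose predicted ΔE equals ``delta_e``.

    Exact algebraic inverse of the fitted calibration function.  Raises
    :class:`SaturationError` for ΔE at/above ``guard`` (default: the
    model's ``saturation_guard``) times the asymptote; pass ``guard=1.0``
    to allow inversion all the way to the asymptote.
    """
    model._check_fitted()
    _check_invertible(model, delta_e, guard)
    a, b = model.a_, model.b_
    if delta_e == 0:
        return 0.0
    if model.order == "first":
        return -b * math.log1p(-delta_e / a)
    return delta_e / (0.5 * a * a * b - a * b * delta_e)


def inverse_partials(model: KineticCalibration, delta_e: float) -> tuple[float, float, float]:
    """Partial derivatives (∂dose/∂a, ∂dose/∂b, ∂dose/∂ΔE) of the inverse
    fit function, evaluated at the fitted parameters and the given ΔE."""
    model._check_fitted()
    a, b = model.a_, model.b_
    de = delta_e
    if de >= model.asymptote_:
        raise SaturationError("partials diverge at/above the asymptote")
    if model.order == "first":
        d_da = -b * de / (a * a - a * de)
        d_db = -math.log1p(-de / a)
        d_dde = b / (a - de)
    else:
        denom = a - 2.0 * de
        d_da = 4.0 * de * (de - a) / (b * a * a * denom * denom)
        d_db = -2.0 * de / (a * b * b * denom)
        d_dde = 2.0 / (b * denom * denom)
    return d_da, d_db, d_dde


def dose_uncertainty(model: KineticCalibration, delta_e: float,
                     s_delta_e: Optional[float] = None) -> float:
    """Delta-method standard uncertainty of the inverse dose prediction.

    Combines the fit covariance over (a, b) with the ΔE measurement noise
    SD (``s_delta_e``, default: the model's).
    """
    s_de = model.s_delta_e if s_delta_e is None else s_delta_e
    d_da, d_db, d_dde = inverse_partials(model, delta_e)
    cov = model.covariance_
    var = (d_da * d_da * cov[0, 0]
           + d_db * d_db * cov[1, 1]
           + d_dde * d_dde * s_de * s_de
           + 2.0 * d_da * d_db * cov[0, 1])
    # parameter quadratic form is >= 0 under a PSD covariance; clip fp dust
    return math.sqrt(max(var, 0.0))


def confidence_interval(model: KineticCalibration, delta_e: float,
                        alpha: float = 0.05,
                        s_delta_e: Optional[float] = None) -> DoseEstimate:
    """Full inverse prediction: dose, u_dose, and the 1−α Student-t CI."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if model.nu_ < 1:
        raise ValueError("need nu >= 1 for a t-based confidence interval")
    dose = invert_dose(model, delta_e)
    u = dose_uncertainty(model, delta_e, s_delta_e=s_delta_e)
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, model.nu_))
    flags: tuple[str, ...] = ()
    if delta_e > model.warn_fraction * model.asymptote_:
        flags = ("near_saturation",)
    return DoseEstimate(
        dose=dose, u_dose=u,
        ci_low=dose - u * tq, ci_high=dose + u * tq,
        alpha=alpha, source_delta_e=delta_e, flags=flags,
    )


# --------------------------------------------------------------------------
# Replicate handling

def equalize_replicates(estimates: Sequence[DoseEstimate],
                        logged_doses: Sequence[float],
                        target_dose: float) -> list[DoseEstimate]:
    """Rescale replicate dose estimates to a common target exposure.

    Replicate exposures rarely deliver exactly the same dose; each estimate
    (dose, CI bounds and standard uncertainty alike) is multiplied by
    target_dose / logged_dose, where the logged dose comes from the
    radiometer record of that exposure.  Relative CI widths are unchanged.
    """
    if len(estimates) != len(logged_doses):
        raise ValueError("estimates and logged_doses must have equal length")
    if target_dose <= 0:
        raise ValueError("target_dose must be > 0")
    out = []
    for est, logged in zip(estimates, logged_doses):
        if logged <= 0:
            raise ValueError(f"logged dose must be > 0, got {logged}")
        out.append(est.scaled(target_dose / logged))
    return out


def combine_uncertainty(u_dose: float, replicate_doses: Sequence[float]) -> float:
    """Total uncertainty u_total = sqrt(u_dose² + u_rep²).

    ``u_rep`` is the sample standard deviation (ddof=1) of the replicate
    dose values; with fewer than two replicates u_rep = 0.
    """
    if u_dose < 0:
        raise ValueError("u_dose must be >= 0")
    reps = np.asarray(replicate_doses, dtype=float)
    u_rep = float(np.std(reps, ddof=1)) if reps.size >= 2 else 0.0
    return math.hypot(u_dose, u_rep)


def normalize_dose(dose_meas: float, u_total_meas: float,
                   dose_ref: float, u_total_ref: float) -> NormalizedDose:
    """Relative dose dose_meas/dose_ref with propagated uncertainty.

    u_norm = |dose_norm|·sqrt((u_meas/dose_meas)² + (u_ref/dose_ref)²).
    """
    if dose_meas <= 0 or dose_ref <= 0:
        raise ValueError("doses must be > 0 for normalization")
    ratio = dose_meas / dose_ref
    u = abs(ratio) * math.hypot(u_total_meas / dose_meas, u_total_ref / dose_ref)
    return NormalizedDose(dose_norm=ratio, u_norm=u,
                          u_total_meas=u_total_meas, u_total_ref=u_total_ref)


def nongermicidal_fraction(delta_e_filtered: float, delta_e_total: float) -> float:
    """Fraction of total color change caused by non-germicidal (>300 nm) light.

    Ratio of the ΔE behind a longpass filter to the ΔE from the unfiltered
    source; in [0, 1] for a well-behaved indicator.
    """
    if delta_e_filtered < 0 or delta_e_total <= 0:
        raise ValueError("ΔE inputs must be >= 0 with total > 0")
    if delta_e_filtered > delta_e_total:
        raise ValueError(
            f"filtered ΔE ({delta_e_filtered}) exceeds total ΔE ({delta_e_total})"
        )
    return delta_e_filtered / delta_e_total
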