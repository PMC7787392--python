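"""Optical attenuators as dose-scale transformations of calibration curves.

A neutral-density filter or UV-transmitting glass of transmittance T placed
over an indicator reduces the dose reaching it to T·d, so the filtered
dose-response is the unfiltered curve with a rescaled dose axis:
ΔE_filtered(d) = ΔE(T·d).  For the first-order form this maps b → b/T; for
the second-order form b → b·T.  A 1.3 OD filter (T ≈ 5%) therefore extends
the quantifiable dose range by roughly 20–30×, which is what makes
indicator-based in-process validation of ≥1 J/cm² treatments possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import KineticCalibration

__all__ = [
    "FilterSpec",
    "measure_transmittance",
    "filtered_model",
    "range_extension",
]


@dataclass(frozen=True)
class FilterSpec:
    """An optical attenuator characterized by its UV-C transmittance."""

    name: str
    transmittance: float
    source: str = "measured"

    def __post_init__(self) -> None:
        if not (0.0 < self.transmittance <= 1.0):
            raise ValueError(f"transmittance must be in (0, 1], got {self.transmittance}")
        if self.source not in ("measured", "nominal"):
            raise ValueError(f"source must be 'measured' or 'nominal', got {self.source!r}")

    @property
    def od(self) -> float:
        """Optical density, −log10(T)."""
        return -math.log10(self.transmittance)


def measure_transmittance(peak_filtered: float, peak_unfiltered: float,
                          name: str = "filter") -> FilterSpec:
    """Transmittance from paired radiometer peaks: through-filter / open."""
    if peak_unfiltered <= 0:
        raise ValueError("unfiltered peak irradiance must be > 0")
    if peak_filtered <= 0:
        raise ValueError("filtered peak irradiance must be > 0")
    t = peak_filtered / peak_unfiltered
    if t > 1.0:
        raise ValueError(f"filtered peak exceeds unfiltered peak (T={t:g} > 1)")
    return FilterSpec(name=name, transmittance=t, source="measured")


def filtered_model(model: KineticCalibration, filt: FilterSpec) -> KineticCalibration:
    """The calibration curve seen through an attenuator.

    Returns a fitted model satisfying predict(filtered, d) = predict(m, T·d)
    exactly: first-order b' = b/T, second-order b' = b·T, with ``a`` carried
    over and the covariance transformed consistently (var(b') scales by the
    Jacobian squared, the cross term linearly).
    """
    model._check_fitted()
    t = filt.transmittance
    jac = (1.0 / t) if model.order == "first" else t
    out = KineticCalibration(**model.get_params())
    out.a_ = model.a_
    out.b_ = model.b_ * jac
    cov = model.covariance_.copy()
    cov[0, 1] *= jac
    cov[1, 0] *= jac
    cov[1, 1] *= jac * jac
    out.covariance_ = cov
    out.nu_ = model.nu_
    out.sse_ = model.sse_
    out.r_squared_ = model.r_squared_
    out.n_points_ = model.n_points_
    out.dose_unit_ = model.dose_unit_
    out.metric_ = model.metric_
    out.device_id_ = model.device_id_
    out.pci_model_ = f"{model.pci_model_}+{filt.name}" if model.pci_model_ else filt.name
    return out


def _dose_scale(model: KineticCalibration) -> float:
    """Characteristic dose scale of a kinetic form: b (first order) or
    1/(a·b) (second order) — both in mJ/cm²."""
    return model.b_ if model.order == "first" else 1.0 / (model.a_ * model.b_)


def range_extension(unfiltered: KineticCalibration,
                    filtered: KineticCalibration,
                    unfiltered_limit: float | None = None,
                    ) -> tuple[float, float | None]:
    """Dynamic-range extension of a filtered over an unfiltered calibration.

    ``extension_factor`` is the ratio of characteristic dose scales
    (first order: b_filtered/b_unfiltered).  When ``unfiltered_limit`` is
    given (mJ/cm²), ``extended_limit`` is the ΔE-matched equivalent: the
    filtered dose whose predicted ΔE equals the unfiltered prediction at
    that limit (inf when the filtered curve never reaches that ΔE).
    """
    if unfiltered.order != filtered.order:
        raise ValueError(
            f"kinetic orders differ: {unfiltered.order!r} vs {filtered.order!r}"
        )
    factor = _dose_scale(filtered) / _dose_scale(unfiltered)

    extended = None
    if unfiltered_limit is not None:
        if unfiltered_limit < 0:
            raise ValueError("unfiltered_limit must be >= 0")
        de_limit = float(unfiltered.predict(unfiltered_limit))
        if de_limit >= filtered.asymptote_:
            extended = math.inf
        else:
            from .dose_inference import invert_dose
            extended = invert_dose(filtered, de_limit, guard=1.0)
    return factor, extended
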