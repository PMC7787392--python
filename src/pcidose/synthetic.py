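"""Synthetic fixtures with known ground truth for every input kind.

Every reader and pipeline in this package can be exercised without
instrument data: this module generates (1) kinetic ΔE-vs-dose calibration
tables with Gaussian color noise, (2) dose-dependent indicator swatch
images with a white patch and optional shadow mask, (3) lamp irradiance
logs with warm-up, output decay, noise and shutoff, and (4) spatial dose
fields with radial corner falloff.  All randomness flows through
``numpy.random.default_rng(seed)``; a fixed seed reproduces outputs
byte-identically.

Swatch colors are linear interpolations in CIELAB between an unexposed
(yellow) and a saturated (pink) endpoint.  Because CIEDE2000 is nonlinear,
the ΔE of an interpolated color only approximately follows the generating
kinetics; ``exact_delta_e=True`` instead solves the (monotone) path
position whose CIEDE2000 from the unexposed endpoint equals the kinetic
target exactly, which is the mode strict recovery tests should use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import CalibrationDataset
from .colorimetry import LabColor, _linear_to_srgb, ciede2000_lab
from .dose_inference import DoseEstimate
from .image_colorimetry import AnnotatedImage, Region
from .mapping import GRID_SPACING_MM, MapLocation, SpatialDoseMap
from .radiometry import IrradianceLog

__all__ = [
    "SyntheticSpec",
    "gen_calibration_dataset",
    "gen_swatch_image",
    "gen_irradiance_log",
    "gen_spatial_field",
]

# Unexposed yellow -> saturated pink, chosen so the full color swing has a
# CIEDE2000 magnitude comparable to a real indicator's ~45 ΔE span.
DEFAULT_UNEXPOSED = LabColor(85.0, 5.0, 60.0)
DEFAULT_SATURATED = LabColor(55.0, 45.0, 5.0)


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic indicator experiment.

    Defaults mirror the conditions of a typical first-order indicator
    calibration: amplitude 47.1 ΔE, dose scale 80.4 mJ/cm², ΔE noise SD
    0.273, and 8 doses spanning 0–250 mJ/cm² with 3 replicates each.
    """

    seed: int = 0
    kinetics: str = "first"
    a_true: float = 47.1
    b_true: float = 80.4
    noise_sd: float = 0.273
    doses: Sequence[float] = field(
        default_factory=lambda: tuple(np.linspace(0.0, 250.0, 8)))
    replicates: int = 3
    unexposed: LabColor = DEFAULT_UNEXPOSED
    saturated: LabColor = DEFAULT_SATURATED

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kinetics not in ("first", "second"):
            raise ValueError(f"kinetics must be 'first' or 'second', got {self.kinetics!r}")

    def true_delta_e(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        a, b = self.a_true, self.b_true
        if self.kinetics == "first":
            return a * (1.0 - np.exp(-dose / b))
        return 0.5 * a * a * b * dose / (1.0 + a * b * dose)

    def extent(self, dose) -> np.ndarray:
        """Reaction extent in [0, 1): the fraction of the color swing."""
        return np.asarray(self.true_delta_e(dose), dtype=float) / (
            self.a_true if self.kinetics == "first" else 0.5 * self.a_true)


# --------------------------------------------------------------------------

def gen_calibration_dataset(spec: SyntheticSpec) -> CalibrationDataset:
    """ΔE = kinetic_model(dose) + N(0, noise_sd), truncated at 0."""
    rng = np.random.default_rng(spec.seed)
    doses = np.repeat(np.asarray(spec.doses, dtype=float), spec.replicates)
    de = spec.true_delta_e(doses)
    if spec.noise_sd > 0:
        de = de + rng.normal(0.0, spec.noise_sd, size=de.shape)
    de = np.clip(de, 0.0, None)
    return CalibrationDataset(doses, de, s_delta_e=max(spec.noise_sd, 1e-12),
                              pci_model=f"synthetic-{spec.kinetics}")


# --------------------------------------------------------------------------
# Swatch images

def _path_lab(spec: SyntheticSpec, s) -> np.ndarray:
    """Lab color at path position s (s=0 unexposed, s=1 saturated;
    linear extrapolation beyond)."""
    s = np.asarray(s, dtype=float)[..., None]
    u = spec.unexposed.as_array()
    v = spec.saturated.as_array()
    return u + s * (v - u)


def _exact_extent(spec: SyntheticSpec, target_de: np.ndarray) -> np.ndarray:
    """Path position whose CIEDE2000 from the unexposed endpoint equals
    ``target_de``, via inverse interpolation of the monotone s→ΔE map."""
    grid = np.linspace(0.0, 1.6, 641)
    de_grid = ciede2000_lab(_path_lab(spec, grid), spec.unexposed.as_array())
    de_grid = np.maximum.accumulate(de_grid)  # guard tiny non-monotone dust
    if np.any(target_de > de_grid[-1]):
        raise ValueError(
            f"target ΔE {float(np.max(target_de)):.2f} exceeds the color path's "
            f"maximum {de_grid[-1]:.2f}; shrink a_true or widen the endpoints"
        )
    return np.interp(target_de, de_grid, grid)


def gen_swatch_image(
    dose: float,
    spec: SyntheticSpec,
    mask_dose: Optional[float] = None,
    size: int = 64,
    pixel_noise_sd: float = 0.002,
    channel_gains: tuple[float, float, float] = (1.0, 1.0, 1.0),
    exact_delta_e: bool = True,
    white_level: float = 0.9,
) -> AnnotatedImage:
    """A synthetic annotated swatch image at the given dose (mJ/cm²).

    Layout (size×size, linear RGB in [0, 1]): a white patch strip on top,
    the exposed swatch in the middle, and unexposed / saturated reference
    patches along the bottom.  ``mask_dose`` renders the right half of the
    exposed swatch at a second dose (a shadowed sub-region).
    ``channel_gains`` multiplies the whole frame to emulate a device color
    cast that white balancing must invert.  Gaussian pixel noise is added
    in linear RGB.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    rng = np.random.default_rng((spec.seed, int(round(dose * 1000)), 0x51))

    def swatch_rgb(d: float) -> np.ndarray:
        if exact_delta_e:
            s = _exact_extent(spec, np.atleast_1d(spec.true_delta_e(d)))[0]
        else:
            s = float(spec.extent(d))
        lab = _path_lab(spec, np.array(s))
        from skimage import color as _skc
        srgb = np.clip(_skc.lab2rgb(lab.reshape(1, 1, 3)), 0.0, 1.0)
        # stored frames are linear-light
        from .colorimetry import _srgb_to_linear
        return _srgb_to_linear(srgb[0, 0])

    h = w = int(size)
    strip = h // 4
    img = np.empty((h, w, 3), dtype=float)
    img[:] = white_level  # background = white card
    exposed_rgb = swatch_rgb(dose)
    img[strip:3 * strip, :, :] = exposed_rgb
    if mask_dose is not None:
        img[strip:3 * strip, w // 2:, :] = swatch_rgb(mask_dose)
    img[3 * strip:, : w // 2, :] = swatch_rgb(0.0)
    sat_dose = spec.b_true * 50.0 if spec.kinetics == "first" else None
    sat_rgb = (swatch_rgb(sat_dose) if sat_dose is not None
               else np.asarray(_srgb_linear_of_lab(spec.saturated)))
    img[3 * strip:, w // 2:, :] = sat_rgb

    gains = np.asarray(channel_gains, dtype=float)
    img = img * gains
    # emulate exposure control: keep every rendered patch below clipping
    peak = float(img.max())
    if peak > 1.0:
        img = img / peak
    if pixel_noise_sd > 0:
        img = img + rng.normal(0.0, pixel_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    regions = [
        Region("white", "white", 2, 2, w - 2, strip - 2),
        Region("exposed", "exposed", 2, strip + 2,
               (w // 2 - 2) if mask_dose is not None else w - 2, 3 * strip - 2),
        Region("unexposed", "unexposed", 2, 3 * strip + 2, w // 2 - 2, h - 2),
        Region("saturated", "saturated", w // 2 + 2, 3 * strip + 2, w - 2, h - 2),
    ]
    if mask_dose is not None:
        regions.append(Region("masked", "exposed", w // 2 + 2, strip + 2,
                              w - 2, 3 * strip - 2))
    return AnnotatedImage(pixels=img, regions=regions, device_id="synthetic",
                          bit_depth=32, encoding="linear", dose_mJ_cm2=dose)


def _srgb_linear_of_lab(lab: LabColor) -> np.ndarray:
    from skimage import color as _skc
    from .colorimetry import _srgb_to_linear
    srgb = np.clip(_skc.lab2rgb(lab.as_array().reshape(1, 1, 3)), 0.0, 1.0)
    return _srgb_to_linear(srgb[0, 0])


# --------------------------------------------------------------------------
# Irradiance logs

def gen_irradiance_log(
    i_max: float = 17.0,
    tau_rise: float = 30.0,
    decay_slope: float = -0.002,
    duration: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shutoff: bool = True,
) -> IrradianceLog:
    """A lamp output trace: exponential warm-up, linear decay, shutoff.

    I(t) = (i_max + decay_slope·t)·(1 − exp(−t/τ)) plus Gaussian noise,
    clipped at 0; ``shutoff`` appends near-zero samples after ``duration``.
    Defaults emulate a low-pressure lamp: ~17 mW/cm² plateau, ~30 s
    warm-up time constant, slow thermal decay, 1 Hz logging.
    """
    if i_max <= 0 or tau_rise <= 0 or duration <= 0 or dt <= 0:
        raise ValueError("i_max, tau_rise, duration and dt must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    irr = (i_max + decay_slope * t) * (1.0 - np.exp(-t / tau_rise))
    if noise_sd > 0:
        irr = irr + rng.normal(0.0, noise_sd, size=irr.shape)
    irr = np.clip(irr, 0.0, None)
    if shutoff:
        tail_t = t[-1] + dt * np.arange(1, 4)
        tail_i = np.full(3, 0.01 * i_max)
        t = np.concatenate([t, tail_t])
        irr = np.concatenate([irr, tail_i])
    return IrradianceLog(t, irr, {"synthetic": True, "i_max": i_max,
                                  "tau_rise": tau_rise, "decay_slope": decay_slope})


# --------------------------------------------------------------------------
# Spatial fields

def gen_spatial_field(
    center_dose: float = 1000.0,
    corner_fraction: float = 0.4,
    grid: tuple[int, int] = (7, 5),
    spacing_mm: float = GRID_SPACING_MM,
    n_replicates: int = 3,
    rel_noise: float = 0.0,
    rel_u_dose: float = 0.02,
    seed: int = 0,
) -> SpatialDoseMap:
    """A treatment-plane dose field with radial falloff toward the corners.

    dose(r) = center_dose·(1 − (1 − corner_fraction)·(r/r_corner)²), so the
    exact corner-to-center ratio equals ``corner_fraction``.  Each location
    carries ``n_replicates`` dose estimates with multiplicative Gaussian
    noise of SD ``rel_noise`` and a per-estimate standard uncertainty of
    ``rel_u_dose``·dose.  The reference label is the center location.
    """
    if center_dose <= 0:
        raise ValueError("center_dose must be > 0")
    if not (0.0 < corner_fraction <= 1.0):
        raise ValueError("corner_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    nx, ny = grid
    xs = np.arange(nx) * spacing_mm
    ys = np.arange(ny) * spacing_mm
    cx, cy = xs.mean(), ys.mean()
    r_corner = math.hypot(xs[-1] - cx, ys[-1] - cy)

    locations = []
    ref_label = None
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            r = math.hypot(x - cx, y - cy)
            frac = (r / r_corner) ** 2 if r_corner > 0 else 0.0
            true_dose = center_dose * (1.0 - (1.0 - corner_fraction) * frac)
            label = f"r{j}c{i}"
            if r == 0 or (ref_label is None and abs(x - cx) < 1e-9 and abs(y - cy) < 1e-9):
                ref_label = label
            estimates = []
            for _ in range(n_replicates):
                d = true_dose * (1.0 + (rng.normal(0.0, rel_noise) if rel_noise > 0 else 0.0))
                d = max(d, 1e-9)
                estimates.append(DoseEstimate(
                    dose=d, u_dose=rel_u_dose * d, ci_low=d, ci_high=d,
                    alpha=0.05, source_delta_e=math.nan,
                ))
            locations.append(MapLocation(label=label, x_mm=float(x), y_mm=float(y),
                                         surface="plane", estimates=estimates))
    if ref_label is None:
        # even grid: no exact center sample; use the location nearest the centroid
        dists = [math.hypot(l.x_mm - cx, l.y_mm - cy) for l in locations]
        ref_label = locations[int(np.argmin(dists))].label
    return SpatialDoseMap(locations, reference_label=ref_label)
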