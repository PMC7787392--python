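"""Color representations and color-difference metrics for photochromic indicators.

Photochromic UV-C indicators (PCIs) report accumulated dose through a color
change.  Quantification always compares an exposed indicator against an
unexposed reference measured under the same conditions, so the primitives here
are *differences* between colors rather than absolute colors: the CIEDE2000
ΔE (the industry-standard perceptual difference with lightness/chroma/hue
weighting and a rotation term), the CIELAB 1976 Euclidean ΔC, the Euclidean
RGB ΔC, the signed component differences ΔR/ΔG/ΔB and ΔL*/ΔC*/ΔH*, and the
per-channel colorimetric absorbance −γ·log10(I/I0).

CIEDE2000 is implemented in full here (it is the quantity every calibration
in this package is built on); Lab↔sRGB conversion is delegated to
scikit-image.  Instrument Lab readings carry an illuminant/observer tag
(e.g. ``"D65/10"``) and differences between mismatched tags are refused
rather than silently adapted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "LabColor",
    "RGBColor",
    "Metric",
    "ColorDifference",
    "PCIMeasurement",
    "ciede2000",
    "ciede2000_lab",
    "cielab_dc",
    "rgb_dc",
    "component_diffs",
    "colorimetric_absorbance",
    "lab_to_rgb",
    "rgb_to_lab",
    "read_color_table",
    "write_color_table",
]


class TagMismatchError(ValueError):
    """Raised when colors with different illuminant/observer tags are compared."""


class Metric(str, Enum):
    CIEDE2000 = "CIEDE2000"
    CIELAB_dC = "CIELAB_dC"
    RGB_dC = "RGB_dC"
    dR = "dR"
    dG = "dG"
    dB = "dB"
    dL = "dL"
    dC = "dC"
    dH = "dH"
    Abs_R = "Abs_R"
    Abs_G = "Abs_G"
    Abs_B = "Abs_B"


@dataclass(frozen=True)
class LabColor:
    """A CIELAB color with its illuminant/observer tag.

    L is lightness in [0, 100]; a and b are the green–red and blue–yellow
    opponent coordinates.  The tag records the measurement condition (the
    RM200QC spectrocolorimeter reports D65/10°); colors are only comparable
    when their tags match.
    """

    L: float
    a: float
    b: float
    illuminant_observer: str = "D65/10"

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"L must be in [0, 100], got {self.L}")
        if not self.illuminant_observer:
            raise ValueError("illuminant_observer tag must be non-empty")

    @property
    def chroma(self) -> float:
        """C* = sqrt(a*^2 + b*^2)."""
        return float(np.hypot(self.a, self.b))

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class RGBColor:
    """An RGB color with channels in [0, 1] and an encoding tag.

    ``encoding`` is ``"gamma"`` for sRGB-encoded values (what cameras and
    ``lab_to_rgb`` produce) or ``"linear"`` for linear-light intensities.
    ``clipped`` marks colors that were gamut-clipped during conversion.
    """

    R: float
    G: float
    B: float
    encoding: str = "gamma"
    clipped: bool = False

    def __post_init__(self) -> None:
        for name, v in (("R", self.R), ("G", self.G), ("B", self.B)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"channel {name} must be in [0, 1], got {v}")
        if self.encoding not in ("linear", "gamma"):
            raise ValueError(f"encoding must be 'linear' or 'gamma', got {self.encoding!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.G, self.B], dtype=float)


@dataclass(frozen=True)
class ColorDifference:
    """A single color-difference value under a named metric.

    CIEDE2000 and the Euclidean metrics are nonnegative; component metrics
    (ΔR…, ΔL*, ΔC*, ΔH*) are signed.
    """

    metric: Metric
    value: float

    _NONNEGATIVE = (Metric.CIEDE2000, Metric.CIELAB_dC, Metric.RGB_dC)

    def __post_init__(self) -> None:
        if self.metric in self._NONNEGATIVE and self.value < -1e-12:
            raise ValueError(f"{self.metric.value} must be >= 0, got {self.value}")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class PCIMeasurement:
    """One exposed-PCI reading paired with its unexposed reference."""

    exposed: LabColor
    reference_unexposed: LabColor
    saturated: Optional[LabColor] = None
    device_id: str = ""
    pci_model: str = ""
    timestamp: Optional[str] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        _check_tags(self.exposed, self.reference_unexposed)

    def delta_e(self) -> ColorDifference:
        """CIEDE2000 ΔE between the exposed PCI and its unexposed reference."""
        return ciede2000(self.exposed, self.reference_unexposed)


def _check_tags(x: LabColor, y: LabColor) -> None:
    if x.illuminant_observer != y.illuminant_observer:
        raise TagMismatchError(
            f"illuminant/observer tags differ: {x.illuminant_observer!r} vs "
            f"{y.illuminant_observer!r}; re-measure or adapt before comparing"
        )


# --------------------------------------------------------------------------
# CIEDE2000

def ciede2000_lab(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 ΔE between Lab triples, vectorized over leading axes.

    Full formula with the lightness/chroma/hue weighting functions and the
    blue-region rotation term; parametric factors default to kL=kC=kH=1.
    Accepts arrays of shape (..., 3) and broadcasts.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = np.moveaxis(lab1, -1, 0)
    L2, a2, b2 = np.moveaxis(lab2, -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((b1 == 0) & (a1p == 0), 0.0, h1p)
    h2p = np.where((b2 == 0) & (a2p == 0), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dhp = h2p - h1p
    dhp = np.where(dhp > 180.0, dhp - 360.0, dhp)
    dhp = np.where(dhp < -180.0, dhp + 360.0, dhp)
    dhp = np.where(C1p * C2p == 0.0, 0.0, dhp)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum,
                   np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    T = (1.0
         - 0.17 * np.cos(np.radians(hbp - 30.0))
         + 0.24 * np.cos(np.radians(2.0 * hbp))
         + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
         - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0)))

    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp**7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)


def ciede2000(sample: LabColor, reference: LabColor) -> ColorDifference:
    """CIEDE2000 ΔE between two tagged Lab colors (symmetric, nonnegative)."""
    _check_tags(sample, reference)
    value = float(ciede2000_lab(sample.as_array(), reference.as_array()))
    return ColorDifference(Metric.CIEDE2000, value)


# --------------------------------------------------------------------------
# Euclidean and component differences

def cielab_dc(sample: LabColor, reference: LabColor) -> ColorDifference:
    """CIELAB 1976 color difference: Euclidean distance over (ΔL*, Δa*, Δb*)."""
    _check_tags(sample, reference)
    d = sample.as_array() - reference.as_array()
    return ColorDifference(Metric.CIELAB_dC, float(np.linalg.norm(d)))


def rgb_dc(sample: RGBColor, reference: RGBColor) -> ColorDifference:
    """Euclidean RGB color difference over (ΔR, ΔG, ΔB)."""
    d = sample.as_array() - reference.as_array()
    return ColorDifference(Metric.RGB_dC, float(np.linalg.norm(d)))


def component_diffs(sample: LabColor, reference: LabColor) -> dict[Metric, ColorDifference]:
    """Signed component differences between exposed (sample) and reference.

    Returns ΔL* = L*_E − L*_R, ΔC* = C*_E − C*_R, the CIE 1976 metric hue
    difference ΔH* = s·sqrt(2(C*_E·C*_R − a*_E·a*_R − b*_E·b*_R)) with sign
    s = +1 if a*_R·b*_E > a*_E·b*_R else −1, and ΔR/ΔG/ΔB computed after
    Lab→sRGB conversion.  The ΔH* radicand is clamped at zero to absorb
    floating-point negatives.  The decomposition satisfies
    ΔL*² + ΔC*² + ΔH*² = (CIELAB ΔC)².
    """
    _check_tags(sample, reference)
    dL = sample.L - reference.L
    CE, CR = sample.chroma, reference.chroma
    dC = CE - CR
    # algebraically 2(C_E·C_R − a_E·a_R − b_E·b_R); this form is exact at
    # identical colors instead of leaving sqrt-of-rounding residue
    da = sample.a - reference.a
    db = sample.b - reference.b
    radicand = da * da + db * db - dC * dC
    s = 1.0 if reference.a * sample.b > sample.a * reference.b else -1.0
    dH = s * np.sqrt(max(0.0, radicand))

    rgb_e = lab_to_rgb(sample)
    rgb_r = lab_to_rgb(reference)
    return {
        Metric.dL: ColorDifference(Metric.dL, dL),
        Metric.dC: ColorDifference(Metric.dC, dC),
        Metric.dH: ColorDifference(Metric.dH, float(dH)),
        Metric.dR: ColorDifference(Metric.dR, rgb_e.R - rgb_r.R),
        Metric.dG: ColorDifference(Metric.dG, rgb_e.G - rgb_r.G),
        Metric.dB: ColorDifference(Metric.dB, rgb_e.B - rgb_r.B),
    }


def colorimetric_absorbance(
    sample: RGBColor, reference: RGBColor, gamma: float = 1.0
) -> dict[Metric, ColorDifference]:
    """Per-channel colorimetric absorbance Abs = −γ·log10(I / I0).

    ``sample`` is the exposed indicator, ``reference`` the unexposed one
    (I0).  Reference channels must be positive; a zero sample channel is a
    saturated reading (infinite absorbance) and is rejected.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    i0 = reference.as_array()
    i = sample.as_array()
    if np.any(i0 <= 0):
        raise ValueError("reference channels must be > 0 for absorbance")
    if np.any(i <= 0):
        raise ValueError("sample channel is 0: saturated/invalid (infinite absorbance)")
    vals = -gamma * np.log10(i / i0)
    keys = (Metric.Abs_R, Metric.Abs_G, Metric.Abs_B)
    return {k: ColorDifference(k, float(v)) for k, v in zip(keys, vals)}


# --------------------------------------------------------------------------
# Lab <-> sRGB conversion (scikit-image backend)

def _split_tag(tag: str) -> tuple[str, str]:
    if "/" in tag:
        ill, obs = tag.split("/", 1)
        return ill, obs.rstrip("°")
    return tag, "2"


_SRGB_THRESHOLD = 0.0031308


def _linear_to_srgb(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return np.where(x <= _SRGB_THRESHOLD, 12.92 * x, 1.055 * x ** (1 / 2.4) - 0.055)


def _srgb_to_linear(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return np.where(x <= 12.92 * _SRGB_THRESHOLD, x / 12.92, ((x + 0.055) / 1.055) ** 2.4)


def lab_to_rgb(color: LabColor) -> RGBColor:
    """Convert a tagged Lab color to sRGB (gamma-encoded, D65).

    Out-of-gamut results are clipped to [0, 1] and flagged via
    ``RGBColor.clipped``.
    """
    ill, obs = _split_tag(color.illuminant_observer)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rgb = _skcolor.lab2rgb(color.as_array(), illuminant=ill, observer=obs)
    clipped = any("gamut" in str(w.message).lower() or "clip" in str(w.message).lower()
                  for w in caught)
    rgb = np.clip(rgb, 0.0, 1.0)
    return RGBColor(float(rgb[0]), float(rgb[1]), float(rgb[2]),
                    encoding="gamma", clipped=clipped)


def rgb_to_lab(color: RGBColor, illuminant_observer: str = "D65/2") -> LabColor:
    """Convert an RGB color to CIELAB under the given illuminant/observer.

    Linear-encoded input is first passed through the sRGB transfer function.
    """
    rgb = color.as_array()
    if color.encoding == "linear":
        rgb = _linear_to_srgb(rgb)
    ill, obs = _split_tag(illuminant_observer)
    lab = _skcolor.rgb2lab(rgb, illuminant=ill, observer=obs)
    return LabColor(float(np.clip(lab[0], 0.0, 100.0)), float(lab[1]), float(lab[2]),
                    illuminant_observer=illuminant_observer)


# --------------------------------------------------------------------------
# Color-table I/O

_COLOR_COLUMNS = ["sample_id", "role", "L", "a", "b",
                  "dose_mJ_cm2", "device_id", "pci_model"]


def read_color_table(path, illuminant_observer: str = "D65/10"):
    """Read a color-reading CSV into a pandas DataFrame.

    Expected columns: ``sample_id, role{exposed|unexposed|saturated}, L, a, b``
    plus optional ``dose_mJ_cm2, device_id, pci_model``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"sample_id", "role", "L", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"color table {path} missing columns: {sorted(missing)}")
    bad = set(df["role"].unique()) - {"exposed", "unexposed", "saturated"}
    if bad:
        raise ValueError(f"unknown roles in color table: {sorted(bad)}")
    df.attrs["illuminant_observer"] = illuminant_observer
    return df


def write_color_table(df, path) -> None:
    cols = [c for c in _COLOR_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format="%.6g")


def measurements_from_table(df, illuminant_observer: str = "D65/10") -> list[PCIMeasurement]:
    """Pair each exposed row with the unexposed (and saturated) reference.

    A single unexposed row acts as the shared reference for every exposed
    row (the scanner dialect); per-device references are matched on
    ``device_id`` when present.
    """
    def _lab(row):
        return LabColor(row["L"], row["a"], row["b"], illuminant_observer)

    refs = df[df["role"] == "unexposed"]
    sats = df[df["role"] == "saturated"]
    if refs.empty:
        raise ValueError("color table has no unexposed reference")
    out = []
    for _, row in df[df["role"] == "exposed"].iterrows():
        dev = row.get("device_id", "")
        r = refs[refs.get("device_id", "") == dev] if "device_id" in df.columns else refs
        if r.empty:
            r = refs
        sat = None
        if not sats.empty:
            sat = _lab(sats.iloc[0])
        out.append(PCIMeasurement(
            exposed=_lab(row),
            reference_unexposed=_lab(r.iloc[0]),
            saturated=sat,
            device_id=str(dev) if dev == dev else "",
            pci_model=str(row.get("pci_model", "")),
            sample_id=str(row["sample_id"]),
        ))
    return out
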