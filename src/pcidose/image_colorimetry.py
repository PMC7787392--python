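"""Extract indicator colors and per-pixel dose maps from device images.

Flatbed scanners, DSLRs and phone cameras can replace a spectrocolorimeter
for indicator readout once images are white-balance/exposure corrected
against a white reference region in the frame.  The contract here is
file-based for reproducibility: images arrive as already-converted linear
or sRGB-encoded TIFF/PNG arrays, and regions of interest (exposed PCI,
unexposed PCI, saturated PCI, white patch, Pantone match) are axis-aligned
rectangles in 0-based pixel coordinates with half-open bounds
[x0, x1) × [y0, y1), supplied via an annotation CSV.

Two acquisition dialects are supported when building a dose-response
dataset: per-image references (camera workflow: every image carries its own
unexposed/saturated/white regions) and shared references (scanner workflow:
one white/unexposed/saturated region serves all exposed swatches in a
single scan).

Pantone-match regions are read and carried but never used in computation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage import color as _skcolor

from .calibration import CalibrationDataset, KineticCalibration
from .colorimetry import (LabColor, RGBColor, _linear_to_srgb, _srgb_to_linear,
                          ciede2000, ciede2000_lab, rgb_to_lab)

__all__ = [
    "Region",
    "AnnotatedImage",
    "white_balance",
    "region_color",
    "region_lab",
    "device_dose_response",
    "dose_image",
    "read_image",
    "read_annotations",
    "write_dose_map",
]

ROLES = ("exposed", "unexposed", "saturated", "white", "pantone")


@dataclass(frozen=True)
class Region:
    """A named rectangular region: [x0, x1) × [y0, y1), 0-based pixels."""

    name: str
    role: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"empty region {self.name!r}: [{self.x0},{self.x1})x[{self.y0},{self.y1})")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class AnnotatedImage:
    """An H×W×3 image in [0, 1] with named regions and acquisition metadata.

    ``encoding`` declares whether pixel values are linear-light or
    sRGB-encoded; gamma-encoded pixels are linearized before any averaging.
    """

    pixels: np.ndarray
    regions: list[Region] = field(default_factory=list)
    device_id: str = ""
    bit_depth: int = 16
    encoding: str = "linear"
    dose_mJ_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.encoding not in ("linear", "gamma"):
            raise ValueError(f"encoding must be 'linear' or 'gamma', got {self.encoding!r}")
        h, w, _ = self.pixels.shape
        for r in self.regions:
            if r.x1 > w or r.y1 > h:
                raise ValueError(f"region {r.name!r} exceeds image bounds {w}x{h}")

    def find(self, role: str, name: Optional[str] = None) -> Region:
        for r in self.regions:
            if r.role == role and (name is None or r.name == name):
                return r
        raise KeyError(f"no region with role {role!r}" + (f" named {name!r}" if name else ""))

    def linear_pixels(self) -> np.ndarray:
        if self.encoding == "linear":
            return self.pixels
        return _srgb_to_linear(self.pixels)


# --------------------------------------------------------------------------

def white_balance(image: AnnotatedImage, target: float = 0.9) -> AnnotatedImage:
    """White-balance and exposure-correct against the white region.

    Each channel (in linear light) is divided by the white-region channel
    mean and rescaled so the white region maps to the neutral gray
    (target, target, target).  Output is clipped to [0, 1]; the clipped
    pixel fraction is recorded and a warning is emitted if it is nonzero.
    Applying the correction twice equals applying it once.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("white target must be in (0, 1]")
    white = image.find("white")
    lin = image.linear_pixels()
    ys, xs = white.slices()
    means = lin[ys, xs].reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("white region has a zero-mean channel; cannot balance")
    corrected = lin * (target / means)
    clip_fraction = float(np.mean(corrected > 1.0))
    if clip_fraction > 0:
        warnings.warn(f"white balance clipped {clip_fraction:.1%} of pixels",
                      stacklevel=2)
    corrected = np.clip(corrected, 0.0, 1.0)
    return AnnotatedImage(
        pixels=corrected, regions=list(image.regions), device_id=image.device_id,
        bit_depth=image.bit_depth, encoding="linear", dose_mJ_cm2=image.dose_mJ_cm2,
    )


def region_color(image: AnnotatedImage, region: Region | str) -> RGBColor:
    """Arithmetic per-channel mean over a region (linear light)."""
    if isinstance(region, str):
        region = image.find("exposed", region) if region not in ROLES \
            else image.find(region)
    ys, xs = region.slices()
    mean = image.linear_pixels()[ys, xs].reshape(-1, 3).mean(axis=0)
    mean = np.clip(mean, 0.0, 1.0)
    return RGBColor(float(mean[0]), float(mean[1]), float(mean[2]), encoding="linear")


def region_lab(image: AnnotatedImage, region: Region | str,
               illuminant_observer: str = "D65/2") -> LabColor:
    """Region mean converted to CIELAB."""
    return rgb_to_lab(region_color(image, region), illuminant_observer)


# --------------------------------------------------------------------------

def device_dose_response(
    images: Sequence[AnnotatedImage],
    s_delta_e: float = 0.273,
    shared_references: Optional[AnnotatedImage] = None,
    balance: bool = True,
    white_target: float = 0.9,
) -> CalibrationDataset:
    """Assemble a ΔE-vs-dose dataset from annotated, dose-labelled images.

    Camera dialect: each image carries its own ``unexposed`` (and
    ``white``) regions.  Scanner dialect: pass ``shared_references`` (or
    include the reference regions on one of the images) and every exposed
    region in every image is compared against that shared unexposed
    reference.  Images are white-balanced before averaging when
    ``balance`` is set.
    """
    points: list[tuple[float, float]] = []
    device = images[0].device_id if images else ""
    shared_lab: Optional[LabColor] = None
    if shared_references is not None:
        ref_img = white_balance(shared_references, white_target) if balance else shared_references
        shared_lab = region_lab(ref_img, ref_img.find("unexposed"))

    for img in images:
        if img.dose_mJ_cm2 is None:
            raise ValueError("every image needs a dose label (dose_mJ_cm2)")
        work = white_balance(img, white_target) if balance else img
        try:
            ref_lab = region_lab(work, work.find("unexposed"))
        except KeyError:
            if shared_lab is None:
                raise ValueError(
                    "image has no unexposed reference region and no shared "
                    "references were supplied"
                )
            ref_lab = shared_lab
        for region in work.regions:
            if region.role != "exposed":
                continue
            de = ciede2000(region_lab(work, region), ref_lab).value
            points.append((img.dose_mJ_cm2, de))
    if len(points) < 4:
        raise ValueError(f"need >= 4 exposed measurements, got {len(points)}")
    doses, des = map(np.array, zip(*points))
    return CalibrationDataset(doses, des, s_delta_e=s_delta_e, device_id=device)


def dose_image(
    image: AnnotatedImage,
    model: KineticCalibration,
    reference: LabColor,
    balance: bool = True,
    white_target: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dose map through the inverse calibration function.

    Every pixel's CIEDE2000 ΔE against the unexposed reference color is
    mapped through the inverse fit function.  Returns ``(doses, saturated)``
    where ``doses`` is an H×W float array (mJ/cm²; NaN where saturated) and
    ``saturated`` is the boolean mask of pixels at/above the saturation
    guard — flagged, not silently clipped.
    """
    model._check_fitted()
    work = white_balance(image, white_target) if balance else image
    srgb = _linear_to_srgb(work.linear_pixels())
    lab = _skcolor.rgb2lab(srgb)
    de = ciede2000_lab(lab, reference.as_array())

    a, b = model.a_, model.b_
    asym = model.asymptote_
    saturated = de >= model.saturation_guard * asym
    de_safe = np.where(saturated, 0.0, de)
    if model.order == "first":
        doses = -b * np.log1p(-de_safe / a)
    else:
        doses = de_safe / (0.5 * a * a * b - a * b * de_safe)
    doses = np.where(saturated, np.nan, doses)
    return doses, saturated


# --------------------------------------------------------------------------
# I/O

def read_image(path, encoding: str = "linear", device_id: str = "",
               dose_mJ_cm2: Optional[float] = None) -> AnnotatedImage:
    """Read a TIFF/PNG into an AnnotatedImage, scaling integers by bit depth."""
    import tifffile
    from imageio import v3 as iio

    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(p)
    else:
        arr = iio.imread(p)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        bit_depth = int(arr.dtype.itemsize * 8)
        arr = arr.astype(float) / (2**bit_depth - 1)
    else:
        bit_depth = 32
        arr = arr.astype(float)
    return AnnotatedImage(pixels=arr, device_id=device_id, bit_depth=bit_depth,
                          encoding=encoding, dose_mJ_cm2=dose_mJ_cm2)


def read_annotations(path) -> dict[str, list[Region]]:
    """Read a region-annotation CSV: `image, region_name, role, x0, y0, x1, y1`.

    Returns a mapping from image filename to its region list.
    """
    import pandas as pd

    df = pd.read_csv(path)
    need = {"image", "region_name", "role", "x0", "y0", "x1", "y1"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {sorted(missing)}")
    out: dict[str, list[Region]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image"]), []).append(Region(
            name=str(row["region_name"]), role=str(row["role"]),
            x0=int(row["x0"]), y0=int(row["y0"]),
            x1=int(row["x1"]), y1=int(row["y1"]),
        ))
    return out


def write_dose_map(doses: np.ndarray, path, csv_path=None) -> None:
    """Write a per-pixel dose map as 32-bit float TIFF (+ optional CSV summary)."""
    import tifffile

    tifffile.imwrite(str(path), doses.astype(np.float32))
    if csv_path is not None:
        finite = doses[np.isfinite(doses)]
        import pandas as pd

        pd.DataFrame([{
            "n_pixels": doses.size,
            "n_saturated": int(np.sum(~np.isfinite(doses))),
            "dose_mean": float(finite.mean()) if finite.size else math.nan,
            "dose_min": float(finite.min()) if finite.size else math.nan,
            "dose_max": float(finite.max()) if finite.size else math.nan,
        }]).to_csv(csv_path, index=False)
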