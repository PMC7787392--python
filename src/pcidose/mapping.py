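"""Spatial dose maps: treatment-plane grids and on-respirator locations.

Point dose measurements (with replicates) are assembled into a
:class:`SpatialDoseMap`, replicates are averaged into per-location means
with a replicate-scatter uncertainty u_rep, per-location radiometer
correction factors are applied multiplicatively, and doses are expressed
relative to a reference location (e.g. the apex of the central respirator)
with propagated uncertainty.  Uniformity summaries (min/max ratio,
corner-to-center ratio, histograms) characterize the treatment plane, where
irradiance typically falls off toward the corners.

Coordinates are millimetres with the origin at the treatment-plane lower
left; on-respirator locations are identified by label (apex, side, ...)
rather than coordinates.  Missing locations are representable as locations
with no replicates and are excluded from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_inference import DoseEstimate, NormalizedDose, combine_uncertainty, normalize_dose

__all__ = [
    "MapLocation",
    "SpatialDoseMap",
    "aggregate_replicates",
    "apply_correction",
    "relative_map",
    "uniformity_summary",
    "read_map_csv",
    "write_map_csv",
    "render_heatmap",
]

GRID_SPACING_MM = 63.5  # default treatment-plane grid pitch

_SURFACES = ("plane", "n95_exterior", "n95_interior")


@dataclass
class MapLocation:
    """One measurement site with its replicate dose estimates."""

    label: str
    x_mm: float
    y_mm: float
    surface: str = "plane"
    estimates: list[DoseEstimate] = field(default_factory=list)
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.surface not in _SURFACES:
            raise ValueError(f"surface must be one of {_SURFACES}, got {self.surface!r}")
        if self.correction_factor <= 0:
            raise ValueError("correction factor must be > 0")

    @property
    def measured(self) -> bool:
        return len(self.estimates) > 0


@dataclass
class SpatialDoseMap:
    """A set of labelled measurement locations with replicate structure."""

    locations: list[MapLocation]
    reference_label: Optional[str] = None

    def __post_init__(self) -> None:
        labels = [loc.label for loc in self.locations]
        if len(set(labels)) != len(labels):
            raise ValueError("location labels must be unique")
        if self.reference_label is not None:
            self[self.reference_label]  # existence check

    def __getitem__(self, label: str) -> MapLocation:
        for loc in self.locations:
            if loc.label == label:
                return loc
        raise KeyError(f"no location labelled {label!r}")

    def measured_locations(self) -> list[MapLocation]:
        return [loc for loc in self.locations if loc.measured]


def aggregate_replicates(dose_map: SpatialDoseMap) -> pd.DataFrame:
    """Per-location replicate mean, u_rep (sample SD), and u_total.

    u_total combines the mean of the calibration-propagated u_dose with the
    replicate scatter by root sum of squares.
    """
    rows = []
    for loc in dose_map.measured_locations():
        doses = np.array([e.dose for e in loc.estimates])
        u_doses = np.array([e.u_dose for e in loc.estimates])
        u_rep = float(np.std(doses, ddof=1)) if doses.size >= 2 else 0.0
        u_dose = float(np.mean(u_doses))
        rows.append({
            "label": loc.label, "x_mm": loc.x_mm, "y_mm": loc.y_mm,
            "surface": loc.surface, "n_replicates": doses.size,
            "dose_mJ_cm2": float(np.mean(doses)),
            "u_rep": u_rep, "u_dose": u_dose,
            "u_total": combine_uncertainty(u_dose, doses),
        })
    return pd.DataFrame(rows)


def apply_correction(dose_map: SpatialDoseMap) -> SpatialDoseMap:
    """Multiply each location's doses (and uncertainties) by its
    radiometer correction factor; the factors are reset to 1 afterwards so
    correction is applied at most once."""
    out_locs = []
    for loc in dose_map.locations:
        f = loc.correction_factor
        out_locs.append(MapLocation(
            label=loc.label, x_mm=loc.x_mm, y_mm=loc.y_mm, surface=loc.surface,
            estimates=[e.scaled(f) for e in loc.estimates],
            correction_factor=1.0,
        ))
    return SpatialDoseMap(out_locs, reference_label=dose_map.reference_label)


def relative_map(dose_map: SpatialDoseMap,
                 reference_label: Optional[str] = None) -> pd.DataFrame:
    """Doses normalized to the reference location, with u_norm per location.

    The reference row is exactly 1 with u_norm = sqrt(2)·(u_total/dose)
    (the self-ratio of two equally uncertain measurements).
    """
    ref_label = reference_label or dose_map.reference_label
    if ref_label is None:
        raise ValueError("a reference_label is required for a relative map")
    agg = aggregate_replicates(dose_map)
    ref_rows = agg[agg["label"] == ref_label]
    if ref_rows.empty:
        raise KeyError(f"reference location {ref_label!r} has no measurements")
    ref = ref_rows.iloc[0]

    norms: list[NormalizedDose] = [
        normalize_dose(row["dose_mJ_cm2"], row["u_total"],
                       ref["dose_mJ_cm2"], ref["u_total"])
        for _, row in agg.iterrows()
    ]
    agg = agg.copy()
    agg["dose_norm"] = [n.dose_norm for n in norms]
    agg["u_norm"] = [n.u_norm for n in norms]
    agg["is_reference"] = agg["label"] == ref_label
    return agg


def uniformity_summary(dose_map: SpatialDoseMap, bins: int = 10) -> dict:
    """Uniformity metrics of a plane map: min/max ratio, corner-to-center
    ratio, and a dose histogram.

    The "center" is the measured location nearest the centroid of all
    measured plane locations; "corners" are the locations nearest the four
    bounding-box corners (their mean dose is used).  Invariant under global
    dose rescaling.  A single-location map yields a degenerate summary with
    a warning flag.
    """
    agg = aggregate_replicates(dose_map)
    agg = agg[agg["surface"] == "plane"]
    if agg.empty:
        raise ValueError("no measured plane locations to summarize")
    doses = agg["dose_mJ_cm2"].to_numpy()
    out: dict = {"n_locations": int(len(agg)), "warnings": []}
    counts, edges = np.histogram(doses, bins=bins)
    out["histogram_counts"] = counts.tolist()
    out["histogram_edges"] = edges.tolist()
    if len(agg) < 2:
        out["warnings"].append("single-location map: ratios degenerate")
        out["min_max_ratio"] = 1.0
        out["corner_to_center_ratio"] = 1.0
        return out
    out["min_max_ratio"] = float(doses.min() / doses.max())

    xy = agg[["x_mm", "y_mm"]].to_numpy()
    centroid = xy.mean(axis=0)
    center_idx = int(np.argmin(np.linalg.norm(xy - centroid, axis=1)))
    center_dose = doses[center_idx]
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    corner_doses = []
    for corner in ((x0, y0), (x0, y1), (x1, y0), (x1, y1)):
        idx = int(np.argmin(np.linalg.norm(xy - np.array(corner), axis=1)))
        corner_doses.append(doses[idx])
    out["corner_to_center_ratio"] = float(np.mean(corner_doses) / center_dose)
    return out


# --------------------------------------------------------------------------
# I/O

_MAP_COLUMNS = ["label", "x_mm", "y_mm", "surface", "replicate",
                "dose_mJ_cm2", "u_dose"]


def read_map_csv(path, reference_label: Optional[str] = None,
                 alpha: float = 0.05) -> SpatialDoseMap:
    """Read a long-format map CSV (one row per replicate measurement).

    Columns: ``label, x_mm, y_mm, surface, replicate, dose_mJ_cm2, u_dose``;
    an optional ``correction_factor`` column is honored.  Rows with a blank
    dose mark unmeasured locations.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"map CSV {path} missing columns: {sorted(missing)}")
    locs: dict[str, MapLocation] = {}
    for _, row in df.iterrows():
        label = str(row["label"])
        if label not in locs:
            cf = float(row["correction_factor"]) if "correction_factor" in df.columns else 1.0
            locs[label] = MapLocation(
                label=label, x_mm=float(row["x_mm"]), y_mm=float(row["y_mm"]),
                surface=str(row["surface"]), correction_factor=cf,
            )
        if pd.notna(row["dose_mJ_cm2"]):
            dose = float(row["dose_mJ_cm2"])
            u = float(row["u_dose"]) if pd.notna(row["u_dose"]) else 0.0
            locs[label].estimates.append(DoseEstimate(
                dose=dose, u_dose=u, ci_low=dose, ci_high=dose,
                alpha=alpha, source_delta_e=math.nan,
            ))
    return SpatialDoseMap(list(locs.values()), reference_label=reference_label)


def write_map_csv(dose_map: SpatialDoseMap, path) -> None:
    """Write the long-format map CSV (lossless value round trip)."""
    rows = []
    for loc in dose_map.locations:
        if not loc.estimates:
            rows.append({"label": loc.label, "x_mm": loc.x_mm, "y_mm": loc.y_mm,
                         "surface": loc.surface, "replicate": "",
                         "dose_mJ_cm2": "", "u_dose": "",
                         "correction_factor": loc.correction_factor})
        for i, e in enumerate(loc.estimates, start=1):
            rows.append({"label": loc.label, "x_mm": loc.x_mm, "y_mm": loc.y_mm,
                         "surface": loc.surface, "replicate": i,
                         "dose_mJ_cm2": repr(e.dose), "u_dose": repr(e.u_dose),
                         "correction_factor": loc.correction_factor})
    pd.DataFrame(rows).to_csv(path, index=False)


def render_heatmap(dose_map: SpatialDoseMap, path, column: str = "dose_mJ_cm2",
                   cmap: str = "inferno") -> None:
    """Render a scatter heatmap of per-location mean doses to a PNG.

    Rendering is cosmetic; the CSV values are the contract.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = aggregate_replicates(dose_map)
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(agg["x_mm"], agg["y_mm"], c=agg[column], cmap=cmap,
                    s=200, marker="s")
    fig.colorbar(sc, ax=ax, label=column)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
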