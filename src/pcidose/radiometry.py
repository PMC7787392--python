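"""Radiometer irradiance-log analysis: dose integration and lamp stability.

UV-C dose (fluence) is irradiance integrated over exposure time,
dose = Σ I·Δt, so a 1 mW/cm² output held for 1 s delivers 1 mJ/cm².
Low-pressure mercury/amalgam lamps are not temporally stable: they warm up
over minutes and their output degrades during long exposures, which is why
single "snap-shot" irradiance readings extrapolate poorly to treatment
times.  This module parses time-stamped irradiance logs and derives:

* integrated dose over the exposure (left-Riemann by default),
* the lamp shutoff sample (a large drop from the previous reading); plots
  and analysis windows conventionally stop two samples before it,
* the 10–90% warm-up rise time (linear interpolation at the crossings of
  10% and 90% of the maximum recorded irradiance),
* the output degradation slope from a linear least-squares fit,
* snapshot exposure-time estimates: target dose divided by the mean
  irradiance in a start window (iterations 10–20) or an end window (the
  last 11 iterations before shutoff).  Window indices are 1-based
  "iterations" at the user interface, matching data-logger conventions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "IrradianceLog",
    "StabilityReport",
    "integrate_dose",
    "detect_shutoff",
    "rise_time_10_90",
    "degradation_slope",
    "estimate_time_to_dose",
    "stability_report",
    "read_log_tsv",
    "write_log_tsv",
]


@dataclass
class IrradianceLog:
    """A time-stamped irradiance series (times in s, irradiance in mW/cm²)."""

    times: np.ndarray
    irradiances: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.irradiances = np.asarray(self.irradiances, dtype=float)
        if self.times.shape != self.irradiances.shape or self.times.ndim != 1:
            raise ValueError("times and irradiances must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise ValueError("log must have >= 3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.irradiances < 0):
            raise ValueError("irradiances must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, start: int, stop: int) -> "IrradianceLog":
        """Sub-log over 0-based sample indices [start, stop)."""
        if stop - start < 3:
            raise ValueError("window must keep >= 3 samples")
        return IrradianceLog(self.times[start:stop], self.irradiances[start:stop],
                             dict(self.meta))


@dataclass
class StabilityReport:
    """Derived lamp-stability metrics for one exposure log."""

    i_end: int                      # 1-based iteration of detected shutoff (len+1 if none)
    shutoff_detected: bool
    dose_mJ_cm2: float
    rise_time_10_90_s: float
    degradation_slope_mW_cm2_per_s: float
    degradation_slope_stderr: float
    t_est_start_s: Optional[float]
    t_est_end_s: Optional[float]
    target_dose_mJ_cm2: Optional[float]
    warnings: tuple[str, ...] = ()

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["warnings"] = list(self.warnings)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# --------------------------------------------------------------------------

def integrate_dose(log: IrradianceLog, window: Optional[tuple[int, int]] = None,
                   method: str = "left") -> float:
    """Integrated dose Σ I·Δt in mJ/cm² over 0-based sample window [i0, i1).

    ``method="left"`` (default) is a left-Riemann sum over the logged
    intervals, extending the final interval with the mean sampling step;
    ``method="trapezoid"`` integrates trapezoidally over the same span.
    """
    t, irr = log.times, log.irradiances
    if window is not None:
        i0, i1 = window
        t, irr = t[i0:i1], irr[i0:i1]
    if len(t) == 0:
        import warnings as _w
        _w.warn("empty integration window; dose = 0", stacklevel=2)
        return 0.0
    if len(t) == 1:
        return 0.0
    if method == "left":
        dt = np.diff(t)
        dose = float(np.sum(irr[:-1] * dt)) + float(irr[-1]) * float(np.mean(dt))
        return dose
    if method == "trapezoid":
        return float(np.trapezoid(irr, t))
    raise ValueError(f"unknown integration method {method!r}")


def detect_shutoff(log: IrradianceLog, drop_fraction: float = 0.5) -> int:
    """Index of the sample at which lamp shutoff occurred (0-based).

    Shutoff is the first sample whose irradiance falls below the previous
    sample by more than ``drop_fraction`` of the maximum recorded
    irradiance (the analysis is post-hoc, so the full log is available;
    referencing the global maximum keeps noisy near-zero warm-up samples
    from mimicking a shutoff).  Returns ``len(log)`` when no such drop
    exists (log treated as ongoing).
    """
    if not (0.0 < drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in (0, 1)")
    irr = log.irradiances
    drops = irr[:-1] - irr[1:]
    hits = np.nonzero(drops > drop_fraction * float(irr.max()))[0]
    if hits.size == 0:
        return len(log)
    return int(hits[0]) + 1


def rise_time_10_90(log: IrradianceLog) -> float:
    """Warm-up rise time: seconds from 10% to 90% of the maximum recorded
    irradiance, with linear interpolation between bracketing samples.

    A log that starts above 10% (or is constant) yields 0 with a
    degeneracy warning.
    """
    t, irr = log.times, log.irradiances
    peak = float(np.max(irr))
    if peak <= 0:
        raise ValueError("log has no positive irradiance")

    def _crossing(level: float) -> float:
        above = irr >= level
        if above[0]:
            return float(t[0])
        idx = int(np.argmax(above))  # first True
        t0, t1 = t[idx - 1], t[idx]
        y0, y1 = irr[idx - 1], irr[idx]
        if y1 == y0:
            return float(t1)
        return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))

    t10 = _crossing(0.10 * peak)
    t90 = _crossing(0.90 * peak)
    rise = max(0.0, t90 - t10)
    if irr[0] >= 0.90 * peak:
        import warnings as _w
        _w.warn("log starts at/above 90% of peak; rise time degenerate", stacklevel=2)
    return rise


def degradation_slope(log: IrradianceLog,
                      window: Optional[tuple[int, int]] = None) -> tuple[float, float]:
    """Linear least-squares irradiance slope (mW/cm² per s) and its SE."""
    sub = log if window is None else log.window(*window)
    res = stats.linregress(sub.times, sub.irradiances)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr


def _iter_to_index(iteration: int) -> int:
    """1-based logger iteration -> 0-based array index."""
    return iteration - 1


def estimate_time_to_dose(log: IrradianceLog, target: float,
                          start_window: tuple[int, int] = (10, 20),
                          end_count: int = 11,
                          drop_fraction: float = 0.5,
                          ) -> tuple[Optional[float], Optional[float]]:
    """Snapshot exposure-time estimates: target dose / mean irradiance.

    ``start_window`` is in 1-based logger iterations, inclusive (default
    the 10th–20th samples); the end window is the last ``end_count``
    iterations before the detected shutoff.  For a temporally stable lamp
    the two estimates agree; their discrepancy quantifies the error of
    extrapolating a single snapshot.  Returns None for a window that is
    unavailable or has zero mean irradiance.
    """
    if target <= 0:
        raise ValueError("target dose must be > 0")
    i_end = detect_shutoff(log, drop_fraction)
    irr = log.irradiances

    lo = _iter_to_index(start_window[0])
    hi = _iter_to_index(start_window[1]) + 1
    t_start = None
    if 0 <= lo < hi <= i_end:
        m = float(np.mean(irr[lo:hi]))
        if m > 0:
            t_start = target / m

    t_end = None
    lo_e = i_end - end_count
    if lo_e >= 0 and i_end > lo_e:
        m = float(np.mean(irr[lo_e:i_end]))
        if m > 0:
            t_end = target / m
    return t_start, t_end


def stability_report(log: IrradianceLog, target: Optional[float] = None,
                     drop_fraction: float = 0.5) -> StabilityReport:
    """Full lamp characterization of one exposure log.

    The dose integral and degradation fit stop two samples before the
    detected shutoff (the i_end − 2 trim), excluding the shutoff transient.
    """
    n = len(log)
    i_end = detect_shutoff(log, drop_fraction)
    detected = i_end < n
    trim = max(3, i_end - 2) if detected else n
    warnings_: list[str] = []
    if detected and i_end - 2 < 3:
        warnings_.append("shutoff too early for a trimmed analysis window")

    analysis = log.window(0, trim)
    dose = integrate_dose(analysis)
    try:
        rise = rise_time_10_90(analysis)
    except ValueError:
        rise = 0.0
        warnings_.append("degenerate rise time (no positive irradiance)")
    # slope over the second half of the trimmed log: past warm-up, the
    # remaining trend is the lamp's thermal output degradation
    half = len(analysis) // 2
    slope, stderr = degradation_slope(analysis, window=(half, len(analysis)))

    t_start = t_end = None
    if target is not None:
        t_start, t_end = estimate_time_to_dose(log, target, drop_fraction=drop_fraction)
        if t_start is None:
            warnings_.append("start window unavailable for time-to-dose estimate")
        if t_end is None:
            warnings_.append("end window unavailable for time-to-dose estimate")

    return StabilityReport(
        i_end=i_end + 1,  # report as a 1-based iteration
        shutoff_detected=detected,
        dose_mJ_cm2=dose,
        rise_time_10_90_s=rise,
        degradation_slope_mW_cm2_per_s=slope,
        degradation_slope_stderr=stderr,
        t_est_start_s=t_start,
        t_est_end_s=t_end,
        target_dose_mJ_cm2=target,
        warnings=tuple(warnings_),
    )


# --------------------------------------------------------------------------
# I/O: canonical two-column TSV, with a hook for vendor formats

def read_log_tsv(path, line_parser=None) -> IrradianceLog:
    """Read a `time_s<TAB>irradiance_mW_cm2` TSV (header optional).

    ``line_parser(line) -> (time_s, irradiance) | None`` may be supplied to
    consume vendor-specific export formats; None skips the line.
    """
    times, irrs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line_parser is not None:
                parsed = line_parser(line)
                if parsed is None:
                    continue
                t, i = parsed
            else:
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: malformed line {line!r}")
                try:
                    t, i = float(parts[0]), float(parts[1])
                except ValueError:
                    continue  # header line
            times.append(t)
            irrs.append(i)
    return IrradianceLog(np.array(times), np.array(irrs), {"source": str(path)})


def write_log_tsv(log: IrradianceLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tirradiance_mW_cm2\n")
        for t, i in zip(log.times, log.irradiances):
            fh.write(f"{t:.6g}\t{i:.6g}\n")
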