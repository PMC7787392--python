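"""Reaction-kinetics calibration of ΔE vs UV-C dose.

The color change of a photochromic indicator saturates with accumulated
dose.  Two empirical calibration forms are supported, motivated by first-
and second-order reaction kinetics of the color-forming chemistry:

    first order:   ΔE(dose) = a·(1 − exp(−dose/b))          asymptote a
    second order:  ΔE(dose) = ½·a²·b·dose / (1 + a·b·dose)   asymptote a/2

with amplitude ``a`` (ΔE units) and dose-scale parameter ``b``.  Doses are
mJ/cm² internally.  The fit is unweighted nonlinear least squares; the
parameter covariance from the fit Jacobian, the residual degrees of freedom
ν = n − 2, and the ΔE measurement noise s_ΔE together drive the inverse
dose prediction and its delta-method uncertainty (see
:mod:`pcidose.dose_inference`).

`KineticCalibration` follows the scikit-learn estimator contract (``fit``,
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationDataset",
    "KineticCalibration",
    "FitError",
    "fit_calibration",
    "predict_delta_e",
    "model_selection_sse",
    "read_calibration_csv",
]

MJ_PER_J = 1000.0


class FitError(RuntimeError):
    """Calibration fit failed to converge or the data are degenerate."""


@dataclass
class CalibrationDataset:
    """ΔE-vs-dose calibration points for one device / PCI model.

    ``s_delta_e`` is the measurement noise SD of the color metric (same
    units as ``delta_e``), determined from replicate readings of unexposed
    indicators; it enters the inverse-prediction uncertainty, not the fit.
    """

    doses: np.ndarray
    delta_e: np.ndarray
    metric: str = "CIEDE2000"
    s_delta_e: float = 0.273
    device_id: str = ""
    pci_model: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        if self.doses.shape != self.delta_e.shape or self.doses.ndim != 1:
            raise ValueError("doses and delta_e must be 1-D arrays of equal length")
        if len(self.doses) < 4:
            raise ValueError(f"need >= 4 calibration points, got {len(self.doses)}")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if len(np.unique(self.doses)) < 3:
            raise ValueError("need >= 3 distinct doses")
        if not self.s_delta_e > 0:
            raise ValueError("s_delta_e must be > 0")

    def __len__(self) -> int:
        return len(self.doses)


def _first_order(dose, a, b):
    return a * (1.0 - np.exp(-dose / b))


def _second_order(dose, a, b):
    return 0.5 * a * a * b * dose / (1.0 + a * b * dose)


_FORMS = {"first": _first_order, "second": _second_order}


class KineticCalibration(RegressorMixin, BaseEstimator):
    """Kinetic dose-response calibration curve as a sklearn regressor.

    Parameters
    ----------
    order : {"first", "second"}
        Kinetic form of the calibration function.
    s_delta_e : float
        Measurement noise SD of the color metric, used by inverse dose
        prediction (not by the fit itself).
    saturation_guard : float
        Fraction of the asymptote above which inverse prediction is
        refused (default 0.98): the inverse partials diverge there.
    warn_fraction : float
        Fraction of the asymptote above which inverse predictions carry a
        near-saturation warning flag.
    xtol : float
        Convergence tolerance on relative parameter change.
    max_iter : int
        Maximum function evaluations for the optimizer.

    Attributes
    ----------
    a_, b_ : float
        Fitted amplitude and dose-scale parameter (both > 0).
    covariance_ : (2, 2) ndarray
        Parameter covariance over (a, b) from the fit Jacobian.
    nu_ : int
        Residual degrees of freedom, n − 2.
    sse_ : float
        Squared sum of residuals (observed − predicted ΔE).
    r_squared_ : float
        1 − SSE/SST.
    """

    def __init__(
        self,
        order: str = "first",
        s_delta_e: float = 0.273,
        saturation_guard: float = 0.98,
        warn_fraction: float = 0.90,
        xtol: float = 1e-10,
        max_iter: int = 10_000,
    ):
        self.order = order
        self.s_delta_e = s_delta_e
        self.saturation_guard = saturation_guard
        self.warn_fraction = warn_fraction
        self.xtol = xtol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    def _initial_guess(self, dose: np.ndarray, de: np.ndarray) -> tuple[float, float]:
        """Deterministic, scale-aware start: amplitude from the observed max,
        dose scale from the dose nearest half-amplitude."""
        de_max = float(np.max(de))
        if de_max <= 0:
            raise FitError("all ΔE observations are <= 0: degenerate calibration data")
        if self.order == "first":
            a0 = de_max
            half = 0.5 * a0
        else:
            a0 = 2.0 * de_max
            half = 0.25 * a0  # half of the a/2 asymptote
        pos = dose > 0
        if not np.any(pos):
            raise FitError("no positive doses in calibration data")
        idx = np.argmin(np.abs(de[pos] - half))
        dose_half = float(dose[pos][idx])
        if dose_half <= 0:
            dose_half = float(np.median(dose[pos]))
        if self.order == "first":
            b0 = dose_half / np.log(2.0)
        else:
            b0 = 1.0 / (a0 * dose_half)
        return a0, b0

    def fit(self, X, y=None):
        """Fit the calibration curve.

        ``X`` may be a :class:`CalibrationDataset` (y omitted), or an
        array of doses (mJ/cm², shape (n,) or (n, 1)) with ``y`` the
        observed ΔE values.
        """
        if isinstance(X, CalibrationDataset):
            data = X
            self.s_delta_e = data.s_delta_e
        else:
            dose = np.asarray(X, dtype=float)
            if dose.ndim == 2 and dose.shape[1] == 1:
                dose = dose[:, 0]
            data = CalibrationDataset(dose, np.asarray(y, dtype=float),
                                      s_delta_e=self.s_delta_e)
        if self.order not in _FORMS:
            raise ValueError(f"order must be 'first' or 'second', got {self.order!r}")

        dose, de = data.doses, data.delta_e
        fn = _FORMS[self.order]
        p0 = self._initial_guess(dose, de)
        try:
            popt, pcov = curve_fit(
                fn, dose, de, p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=self.xtol, maxfev=self.max_iter, method="trf",
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"calibration fit did not converge: {exc}") from exc
        if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(pcov)):
            raise FitError(
                "calibration fit degenerate: non-finite parameters or covariance "
                f"(a={popt[0]!r}, b={popt[1]!r})"
            )
        if popt[0] <= 0 or popt[1] <= 0:
            raise FitError(f"fitted parameters must be positive, got a={popt[0]}, b={popt[1]}")

        resid = de - fn(dose, *popt)
        sse = float(np.dot(resid, resid))
        sst = float(np.sum((de - de.mean()) ** 2))
        self.a_ = float(popt[0])
        self.b_ = float(popt[1])
        self.covariance_ = np.asarray(pcov, dtype=float)
        self.nu_ = len(dose) - 2
        self.sse_ = sse
        self.r_squared_ = 1.0 - sse / sst if sst > 0 else float("nan")
        self.n_points_ = len(dose)
        self.dose_unit_ = "mJ/cm2"
        self.metric_ = data.metric
        self.device_id_ = data.device_id
        self.pci_model_ = data.pci_model
        return self

    # -- prediction --------------------------------------------------------

    @property
    def asymptote_(self) -> float:
        """Limiting ΔE as dose → ∞: a (first order) or a/2 (second order)."""
        self._check_fitted()
        return self.a_ if self.order == "first" else 0.5 * self.a_

    def _check_fitted(self) -> None:
        if not hasattr(self, "a_"):
            raise FitError("calibration is not fitted; call fit() first")

    def predict(self, X):
        """Predicted ΔE at the given doses (mJ/cm²; scalar, (n,) or (n, 1))."""
        self._check_fitted()
        dose = np.asarray(X, dtype=float)
        if dose.ndim == 2 and dose.shape[1] == 1:
            dose = dose[:, 0]
        if np.any(dose < 0):
            raise ValueError("dose must be >= 0")
        return _FORMS[self.order](dose, self.a_, self.b_)

    def predict_dose(self, delta_e, alpha: float = 0.05):
        """Inverse prediction: dose estimate(s) with uncertainty and CI.

        Thin delegation to :func:`pcidose.dose_inference.confidence_interval`.
        """
        from . import dose_inference

        if np.ndim(delta_e) == 0:
            return dose_inference.confidence_interval(self, float(delta_e), alpha=alpha)
        return [dose_inference.confidence_interval(self, float(d), alpha=alpha)
                for d in np.asarray(delta_e, dtype=float).ravel()]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "order": self.order,
            "a": self.a_,
            "b": self.b_,
            "covariance": self.covariance_.tolist(),
            "nu": self.nu_,
            "s_delta_e": self.s_delta_e,
            "r_squared": self.r_squared_,
            "sse": self.sse_,
            "n_points": self.n_points_,
            "dose_unit": self.dose_unit_,
            "metric": self.metric_,
            "device_id": self.device_id_,
            "pci_model": self.pci_model_,
            "saturation_guard": self.saturation_guard,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "KineticCalibration":
        model = cls(order=d["order"], s_delta_e=d["s_delta_e"],
                    saturation_guard=d.get("saturation_guard", 0.98))
        model.a_ = float(d["a"])
        model.b_ = float(d["b"])
        model.covariance_ = np.asarray(d["covariance"], dtype=float)
        model.nu_ = int(d["nu"])
        model.sse_ = float(d["sse"])
        model.r_squared_ = float(d["r_squared"])
        model.n_points_ = int(d.get("n_points", d["nu"] + 2))
        model.dose_unit_ = d.get("dose_unit", "mJ/cm2")
        model.metric_ = d.get("metric", "CIEDE2000")
        model.device_id_ = d.get("device_id", "")
        model.pci_model_ = d.get("pci_model", "")
        return model

    @classmethod
    def from_json(cls, path) -> "KineticCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# Functional wrappers

def fit_calibration(data: CalibrationDataset, order: str = "first",
                    **kwargs) -> KineticCalibration:
    """Fit a :class:`KineticCalibration` to a dataset and return it."""
    return KineticCalibration(order=order, **kwargs).fit(data)


def predict_delta_e(model: KineticCalibration, dose):
    """ΔE predicted by a fitted model at the given dose (mJ/cm²)."""
    return model.predict(dose)


def model_selection_sse(fits: Sequence[KineticCalibration]):
    """Rank candidate calibration fits by SSE, ascending.

    Ties keep declaration order (stable sort).  Returns the sorted list.
    """
    return sorted(fits, key=lambda m: m.sse_)


def read_calibration_csv(path, s_delta_e: float = 0.273, dose_unit: str = "mJ_cm2",
                         **kwargs) -> CalibrationDataset:
    """Read a `dose_mJ_cm2, delta_e` CSV into a CalibrationDataset.

    ``dose_unit="J_cm2"`` declares the dose column is in J/cm²; values are
    converted to mJ/cm² on read.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "delta_e" not in df.columns:
        raise ValueError(f"{path}: missing 'delta_e' column")
    if "dose_mJ_cm2" in df.columns:
        doses = df["dose_mJ_cm2"].to_numpy(dtype=float)
        if dose_unit == "J_cm2":
            raise ValueError("column is dose_mJ_cm2 but dose_unit says J_cm2")
    elif "dose_J_cm2" in df.columns or dose_unit == "J_cm2":
        col = "dose_J_cm2" if "dose_J_cm2" in df.columns else "dose"
        doses = df[col].to_numpy(dtype=float) * MJ_PER_J
    else:
        raise ValueError(f"{path}: missing dose column")
    return CalibrationDataset(doses, df["delta_e"].to_numpy(dtype=float),
                              s_delta_e=s_delta_e, **kwargs)
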