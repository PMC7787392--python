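"""Inverse dose prediction, uncertainty propagation, and dose arithmetic."""

import math

import numpy as np
import pytest
from scipy import stats

from pcidose.dose_inference import (DoseEstimate, SaturationError,
                                    combine_uncertainty, confidence_interval,
                                    dose_uncertainty, equalize_replicates,
                                    inverse_partials, invert_dose,
                                    nongermicidal_fraction, normalize_dose)

from conftest import make_model


class TestInversion:
    @pytest.mark.parametrize("order,a,b", [("first", 47.1, 80.4),
                                           ("second", 47.7, 0.00060)])
    def test_round_trip_identity(self, order, a, b):
        m = make_model(a, b, order=order)
        rng = np.random.default_rng(1)
        # doses within the guard band of the asymptote
        top = invert_dose(m, 0.97 * m.asymptote_, guard=0.99)
        for dose in rng.uniform(0.01, top, 100):
            de = float(m.predict(dose))
            assert invert_dose(m, de) == pytest.approx(dose, rel=1e-9)

    def test_zero_delta_e(self, pci1_model):
        assert invert_dose(pci1_model, 0.0) == 0.0

    def test_above_asymptote_is_saturation(self, pci1_model):
        with pytest.raises(SaturationError, match="47.1"):
            invert_dose(pci1_model, 47.2)

    def test_guard_band_refusal(self, pci1_model):
        # beyond 0.98*asymptote but below it: refused by the default guard,
        # allowed when the guard is lifted
        de = 0.99 * pci1_model.asymptote_
        with pytest.raises(SaturationError, match="guard"):
            invert_dose(pci1_model, de)
        assert invert_dose(pci1_model, de, guard=1.0) > 0

    def test_negative_delta_e_rejected(self, pci1_model):
        with pytest.raises(ValueError):
            invert_dose(pci1_model, -0.1)


class TestPartials:
    @pytest.mark.parametrize("order", ["first", "second"])
    def test_against_central_finite_differences(self, order):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = rng.uniform(20, 60)
            b = rng.uniform(50, 150) if order == "first" else rng.uniform(1e-4, 1e-2)
            asym = a if order == "first" else a / 2
            de = rng.uniform(0.05, 0.9) * asym

            def inv(a_, b_, de_):
                m_ = make_model(a_, b_, order=order)
                return invert_dose(m_, de_, guard=1.0)

            m = make_model(a, b, order=order)
            d_da, d_db, d_dde = inverse_partials(m, de)
            for got, idx, x in ((d_da, 0, a), (d_db, 1, b), (d_dde, 2, de)):
                h = 1e-6 * abs(x)
                args = [a, b, de]
                hi, lo = list(args), list(args)
                hi[idx] += h
                lo[idx] -= h
                fd = (inv(*hi) - inv(*lo)) / (2 * h)
                assert got == pytest.approx(fd, rel=1e-6)


class TestDoseUncertainty:
    def test_collapses_to_measurement_term(self, pci1_model):
        # zero covariance: only the ΔE noise term survives
        de = 20.0
        _, _, d_dde = inverse_partials(pci1_model, de)
        assert dose_uncertainty(pci1_model, de) == pytest.approx(
            abs(d_dde) * pci1_model.s_delta_e, rel=1e-12)

    def test_monotone_toward_saturation(self, fitted_pci1):
        asym = fitted_pci1.asymptote_
        des = np.linspace(0.3, 0.95, 30) * asym
        us = [dose_uncertainty(fitted_pci1, float(d)) for d in des]
        assert np.all(np.diff(us) > 0)

    def test_agrees_with_monte_carlo(self, fitted_pci1):
        de = 25.0
        u_delta = dose_uncertainty(fitted_pci1, de)
        rng = np.random.default_rng(123)
        n = 100_000
        ab = rng.multivariate_normal([fitted_pci1.a_, fitted_pci1.b_],
                                     fitted_pci1.covariance_, size=n)
        de_s = de + rng.normal(0, fitted_pci1.s_delta_e, size=n)
        ok = (de_s > 0) & (de_s < 0.999 * ab[:, 0])
        doses = -ab[ok, 1] * np.log1p(-de_s[ok] / ab[ok, 0])
        assert u_delta == pytest.approx(float(np.std(doses)), rel=0.05)


class TestConfidenceInterval:
    def test_zero_uncertainty_zero_width(self, pci1_model):
        m = make_model(47.1, 80.4, s_delta_e=1e-300)
        est = confidence_interval(m, 20.0)
        assert est.ci_low == pytest.approx(est.dose)
        assert est.ci_high == pytest.approx(est.dose)

    def test_large_nu_approaches_normal_quantile(self):
        m = make_model(47.1, 80.4, nu=10_000_000)
        est = confidence_interval(m, 20.0)
        half = (est.ci_high - est.ci_low) / 2
        assert half / est.u_dose == pytest.approx(1.95996, abs=1e-4)

    def test_relative_uncertainty_is_half_ci_width(self, fitted_pci1):
        est = confidence_interval(fitted_pci1, 25.0)
        assert est.rel_uncertainty == pytest.approx(est.rel_ci_width / 2)
        assert est.ci_low <= est.dose <= est.ci_high

    def test_near_saturation_flagged(self, fitted_pci1):
        de = 0.95 * fitted_pci1.asymptote_
        est = confidence_interval(fitted_pci1, float(de))
        assert "near_saturation" in est.flags


class TestReplicateArithmetic:
    def _est(self, dose=100.0, u=5.0):
        return DoseEstimate(dose=dose, u_dose=u, ci_low=dose - 2 * u,
                            ci_high=dose + 2 * u, alpha=0.05, source_delta_e=20.0)

    def test_equalize_identity_and_scaling(self):
        est = self._est()
        same = equalize_replicates([est], [500.0], 500.0)[0]
        assert same.dose == est.dose and same.u_dose == est.u_dose
        double = equalize_replicates([est], [250.0], 500.0)[0]
        assert double.dose == pytest.approx(200.0)
        assert double.u_dose == pytest.approx(10.0)
        assert double.rel_ci_width == pytest.approx(est.rel_ci_width)

    def test_equalize_rejects_bad_logged_dose(self):
        with pytest.raises(ValueError):
            equalize_replicates([self._est()], [0.0], 500.0)

    def test_combine_uncertainty(self):
        assert combine_uncertainty(3.0, [100.0]) == pytest.approx(3.0)
        # replicates 96,100,104 have SD 4: the 3-4-5 triangle
        assert combine_uncertainty(3.0, [96.0, 100.0, 104.0]) == pytest.approx(5.0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            u = rng.uniform(0, 10)
            reps = rng.uniform(50, 150, 5)
            expected = math.sqrt(u**2 + np.std(reps, ddof=1) ** 2)
            assert combine_uncertainty(u, reps) == pytest.approx(expected, rel=1e-12)

    def test_normalize_dose(self):
        n = normalize_dose(100.0, 5.0, 100.0, 5.0)
        assert n.dose_norm == pytest.approx(1.0)
        assert n.u_norm == pytest.approx(math.sqrt(2) * 5.0 / 100.0)
        n2 = normalize_dose(100.0, 5.0, 200.0, 0.0)
        assert n2.u_norm == pytest.approx(5.0 / 200.0)
        rng = np.random.default_rng(5)
        for _ in range(20):
            dm, dr = rng.uniform(10, 500, 2)
            um, ur = rng.uniform(0, 20, 2)
            got = normalize_dose(dm, um, dr, ur)
            expected = (dm / dr) * math.sqrt((um / dm) ** 2 + (ur / dr) ** 2)
            assert got.u_norm == pytest.approx(expected, rel=1e-12)


class TestNongermicidalFraction:
    def test_edge_and_worked_values(self):
        assert nongermicidal_fraction(0.0, 25.0) == 0.0
        assert nongermicidal_fraction(25.0, 25.0) == 1.0
        assert nongermicidal_fraction(4.75, 25.0) == pytest.approx(0.19)

    def test_filtered_above_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            nongermicidal_fraction(26.0, 25.0)


class TestCoverage:
    def test_ci_coverage_near_nominal(self):
        """A 95% CI on an unknown dose covers the true dose at ~95% over
        seeded synthetic calibrations (PCI1-like truth, ΔE noise SD 0.273)."""
        from pcidose.calibration import KineticCalibration
        from pcidose.synthetic import SyntheticSpec, gen_calibration_dataset

        rng = np.random.default_rng(77)
        n, hits = 200, 0
        for k in range(n):
            data = gen_calibration_dataset(SyntheticSpec(seed=90_000 + k))
            m = KineticCalibration("first", s_delta_e=0.273).fit(data)
            de_obs = 47.1 * (1 - math.exp(-100.0 / 80.4)) + rng.normal(0, 0.273)
            est = confidence_interval(m, float(de_obs))
            hits += est.ci_low <= 100.0 <= est.ci_high
        assert 0.90 <= hits / n <= 0.99
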