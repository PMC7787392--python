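import numpy as np
import pytest

from pcidose.calibration import KineticCalibration


def make_model(a, b, order="first", cov=None, nu=22, s_delta_e=0.273,
               **kwargs) -> KineticCalibration:
    """Assemble a fitted calibration model directly from parameters."""
    m = KineticCalibration(order=order, s_delta_e=s_delta_e, **kwargs)
    m.a_ = float(a)
    m.b_ = float(b)
    m.covariance_ = np.zeros((2, 2)) if cov is None else np.asarray(cov, dtype=float)
    m.nu_ = nu
    m.sse_ = 0.0
    m.r_squared_ = 1.0
    m.n_points_ = nu + 2
    m.dose_unit_ = "mJ/cm2"
    m.metric_ = "CIEDE2000"
    m.device_id_ = ""
    m.pci_model_ = ""
    return m


@pytest.fixture(scope="session")
def pci1_model():
    """First-order model at the PCI1-like parameters, zero fit covariance."""
    return make_model(47.1, 80.4, order="first")


@pytest.fixture(scope="session")
def pci2_model():
    """Second-order model at the PCI2-like parameters."""
    return make_model(47.7, 0.00060, order="second", s_delta_e=0.083)


@pytest.fixture(scope="session")
def fitted_pci1():
    """A model actually fitted to noisy PCI1-like synthetic data, so the
    covariance is a real fit covariance."""
    from pcidose.synthetic import SyntheticSpec, gen_calibration_dataset

    data = gen_calibration_dataset(SyntheticSpec(seed=42))
    return KineticCalibration(order="first", s_delta_e=0.273).fit(data)
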