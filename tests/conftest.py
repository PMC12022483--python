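import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vesikin import BindingConditions, KineticParams
from vesikin.io import load_atdgd2_kobs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_params() -> KineticParams:
    """Parameters close to the atDGD2/LUV fit (accessible-lipid basis)."""
    return KineticParams(k_on=2.06, k_off=0.37, c1=1 / 47.0)


@pytest.fixture(scope="session")
def study_lipid_totals() -> tuple:
    return (45.5, 91.0, 136.5, 182.0, 227.5, 273.0)


@pytest.fixture()
def study_conditions() -> BindingConditions:
    return BindingConditions(protein_conc=0.78, lipid_total=45.5, leaflet_factor=0.5)


@pytest.fixture(scope="session")
def published_points():
    """The bundled six-point stopped-flow k_obs table (accessible basis)."""
    return load_atdgd2_kobs()


def exact_bimolecular_solution(params, e0, s0, t):
    """Closed-form x(t) of dx/dt = k_on(E0−x)(S0−x) − k_off·x, x(0)=0.

    Independent oracle for the ODE integrator: with x1 < x2 the roots of
    the quadratic rate law, x(t) = x1 x2 (1−e^{−λt}) / (x2 − x1 e^{−λt})
    and λ = k_on (x2 − x1).
    """
    t = np.asarray(t, dtype=float)
    kon, koff = params.k_on, params.k_off
    b = kon * (e0 + s0) + koff
    lam = np.sqrt(b * b - 4 * kon * kon * e0 * s0)
    x1 = (b - lam) / (2 * kon)
    x2 = (b + lam) / (2 * kon)
    ex = np.exp(-lam * t)
    return x1 * x2 * (1 - ex) / (x2 - x1 * ex)
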