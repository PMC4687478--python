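import warnings

import pytest
from hypothesis import HealthCheck, settings

import protonvib as pv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crystal_curve() -> pv.PotentialCurve:
    return pv.make_pyp_crystal_fixture()


@pytest.fixture(scope="session")
def equilibrium_curve() -> pv.PotentialCurve:
    return pv.make_pyp_equilibrium_fixture()


def _solve_quiet(curve, mass, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pv.BoundaryLeakageWarning)
        return pv.solve_states(curve, mass, **kw)


@pytest.fixture(scope="session")
def crystal_proton(crystal_curve) -> pv.VibrationalSpectrum:
    return _solve_quiet(crystal_curve, pv.ParticleMass.proton())


@pytest.fixture(scope="session")
def crystal_deuteron(crystal_curve) -> pv.VibrationalSpectrum:
    return _solve_quiet(crystal_curve, pv.ParticleMass.deuteron())


@pytest.fixture(scope="session")
def equilibrium_proton(equilibrium_curve) -> pv.VibrationalSpectrum:
    return _solve_quiet(equilibrium_curve, pv.ParticleMass.proton())
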