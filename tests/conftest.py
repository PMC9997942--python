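import pytest

from vitriflow.materials import (MaterialProperties, MaterialSet,
                                 PropertyPolynomial, ViscosityModel,
                                 default_materials)
from vitriflow.simulate import (SimulationConfig, ThermalProtocol,
                                run_tf_simulation)

TEST_ELEMENTS = 1500  # desk-scale mesh used by the simulation-level tests


@pytest.fixture(scope="session")
def mats():
    return default_materials()


@pytest.fixture(scope="session")
def constant_mats():
    """Constant-property materials for analytic benchmarks."""
    def poly(name, c):
        return PropertyPolynomial((c,), name=name)

    cpa = MaterialProperties(
        density=poly("rho", 1090.0),
        conductivity=poly("k", 0.356),
        specific_heat=poly("cp", 2804.0),
        thermal_expansion=1.1e-5,
        viscosity=ViscosityModel(),
    )
    return MaterialSet(cpa=cpa, cuvette=cpa)


@pytest.fixture(scope="session")
def tf_run():
    """Session-cached TF runs keyed by (rate, T_final, elements, extras)."""
    cache = {}

    def run(rate=20.0, tfinal=-125.0, elements=TEST_ELEMENTS, **kwargs):
        key = (rate, tfinal, elements, tuple(sorted(kwargs.items())))
        if key not in cache:
            cfg = SimulationConfig(
                protocol=ThermalProtocol(cooling_rate=rate, T_final=tfinal),
                target_elements=elements, **kwargs)
            cache[key] = run_tf_simulation(cfg)
        return cache[key]

    return run
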