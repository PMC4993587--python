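import pytest

from kvflux import IonConditions, PhysEnv, SimScenario, simulate_current_family


@pytest.fixture(scope="session")
def env23():
    """Room-temperature thermodynamic context (23 C)."""
    return PhysEnv.from_celsius(23.0)


@pytest.fixture(scope="session")
def cond_phys():
    """Physiological K+ gradient: 3 mM out / 140 mM in."""
    return IonConditions.from_mm(3.0, 140.0)


@pytest.fixture(scope="session")
def default_scenario():
    return SimScenario()


@pytest.fixture(scope="session")
def default_family(default_scenario):
    """One simulated family under the default recording conditions
    (N = 3120, 15 pS, P_o = 0.014, 5 pA noise, seed 0)."""
    return simulate_current_family(default_scenario)


@pytest.fixture(scope="session")
def noiseless_family():
    import dataclasses

    s = dataclasses.replace(SimScenario(), noise_sd=0.0)
    return simulate_current_family(s)
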