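import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ctx_298():
    from idpdyn.hydro import HydroContext

    return HydroContext(temperature=298.0, isotope="D2O")


@pytest.fixture(scope="session")
def noiseless_spectrum():
    """Default-condition synthetic spectrum with no noise, plus its truth."""
    from idpdyn.synthetic import SpectrumTruth, generate_spectrum

    truth = SpectrumTruth(D_apparent=17.0, noise_scale=0.0)
    return truth, generate_spectrum(truth)


@pytest.fixture(scope="session")
def fixed_solvent_policy():
    from idpdyn.qens import SolventPolicy

    return SolventPolicy(mode="fixed", width=50.0)


@pytest.fixture(scope="session")
def brownian_replicates():
    """Five seeded Brownian replicates of ten chains each, unwrapped."""
    from idpdyn.synthetic import BrownianSystemTruth, generate_brownian_chains
    from idpdyn.trajectory import unwrap

    return [unwrap(generate_brownian_chains(BrownianSystemTruth(seed=s)))
            for s in range(5)]
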