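import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import secrgrid as sg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid10():
    """The full study design: 10x10 lattice at 9.43 m."""
    return sg.build_grid(10, 10, 9.43)


@pytest.fixture(scope="session")
def mask50(grid10):
    """Default habitat mask: 50 m buffer, 5 m spacing."""
    return sg.build_mask(grid10, 50.0, 5.0)


@pytest.fixture(scope="session")
def sex_spec():
    return sg.ModelSpec("EX", frozenset({"sex"}), frozenset({"sex"}))


@pytest.fixture(scope="session")
def study_truth():
    """Generator truth at the emulator defaults, D = 30/ha."""
    d = sg.STUDY_DEFAULTS
    return sg.SessionTruth(
        "sim", 30.0, d["g0_F"], d["g0_M"], d["sigma_F"], d["sigma_M"], d["pmix"]
    )


@pytest.fixture(scope="session")
def sim_session(grid10, mask50, study_truth):
    """One simulated full-design session at the study defaults."""
    rng = np.random.default_rng(202)
    pop = sg.simulate_population(study_truth.D, mask50, study_truth.pmix, rng)
    ch = sg.simulate_capthist(
        pop, grid10, 4, study_truth.params("EX"), seed=rng, session_label="sim"
    )
    return ch


@pytest.fixture(scope="session")
def sim_fit(sim_session, grid10, mask50, sex_spec):
    """Sex-mixture EX fit of the shared simulated session."""
    return sg.fit_secr(sim_session, grid10, mask50, sex_spec)
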