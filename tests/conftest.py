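import numpy as np
import pytest

import recordage as ra


@pytest.fixture(scope="session")
def default_proc() -> ra.RecordAgeProcess:
    """Packaged reference calibration (entry age 0, b = 0.09)."""
    return ra.default_process()


@pytest.fixture(scope="session")
def toy_hom() -> ra.HomogeneousModel:
    """Small-population homogeneous model, cheap to simulate."""
    return ra.HomogeneousModel(lam=20.0, law=ra.LifespanLaw(a=0.02, b=0.2, gamma=0.3), x_max=80.0)


@pytest.fixture(scope="session")
def realistic_hom() -> ra.HomogeneousModel:
    """Homogeneous model with record ages near 90, for residual oracles."""
    return ra.HomogeneousModel(lam=1000.0, law=ra.LifespanLaw(a=1e-4, b=0.11, gamma=0.12))


@pytest.fixture(scope="session")
def exp_hom() -> ra.HomogeneousModel:
    """Unit-rate exponential lifespans at unit birth rate: the atom at 0
    is large (e^-1), exercising every point-mass term."""
    return ra.HomogeneousModel(lam=1.0, law=ra.LifespanLaw(a=1.0, b=0.09, gamma=0.09), x_max=60.0)


@pytest.fixture(scope="session")
def synthetic_frame():
    """One synthetic titleholder table under the packaged study conditions."""
    return ra.make_synthetic_titleholders(seed=1)


@pytest.fixture(scope="session")
def synthetic_records(synthetic_frame):
    return [
        ra.TitleholderRecord(r.date_death, r.age_death_years, r.successor_age_years)
        for r in synthetic_frame.itertuples()
    ]


@pytest.fixture(scope="session")
def toy_run(toy_hom):
    """Long homogeneous simulation shared by the distributional tests."""
    lam, law = toy_hom.lam, toy_hom.law
    pop = ra.simulate_population(
        lambda t: np.full(np.shape(t), lam), law, window=(0.0, 3000.0), seed=42
    )
    traj = ra.extract_record_trajectory(pop)
    return pop, traj
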