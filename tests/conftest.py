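import pytest

from vitalcentiles import synthetic
from vitalcentiles.cleaning import clean_encounters
from vitalcentiles.distributions import BCPE, BCT, FamilyParams

#: the 11 published centile levels
LEVELS = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0, 97.5, 99.0)


@pytest.fixture(scope="session")
def reference_params():
    """Per-age FamilyParams inverted from the packaged reference tables."""
    return synthetic.build_reference_params()


@pytest.fixture(scope="session")
def hr_table():
    return synthetic.load_reference_table("hr")


@pytest.fixture(scope="session")
def rr_table():
    return synthetic.load_reference_table("rr")


@pytest.fixture(scope="session")
def small_cohort():
    """A 20k-encounter synthetic cohort (raw encounter/measurement frames)."""
    cfg = synthetic.GeneratorConfig(n_encounters=20_000)
    return synthetic.simulate_encounters(cfg, seed=42)


@pytest.fixture(scope="session")
def small_clean(small_cohort):
    enc, meas = small_cohort
    clean, log = clean_encounters(enc, meas)
    return clean, log


@pytest.fixture(scope="session")
def hr_model(small_clean):
    """HR model fitted on the small cohort at a fixed zeta."""
    from vitalcentiles.gamlss import FitConfig
    from vitalcentiles.pipeline import fit_vital
    clean, _ = small_clean
    cfg = FitConfig(edf={"mu": 12.0, "sigma": 8.0, "nu": 5.0, "tau": 5.0})
    return fit_vital(clean, "hr", config=cfg, zeta=0.3)


@pytest.fixture(scope="session")
def rr_model(small_clean):
    from vitalcentiles.gamlss import FitConfig
    from vitalcentiles.pipeline import fit_vital
    clean, _ = small_clean
    cfg = FitConfig(edf={"mu": 12.0, "sigma": 8.0, "nu": 5.0, "tau": 5.0})
    return fit_vital(clean, "rr", seed=5, config=cfg, zeta=0.3)


@pytest.fixture
def normal_params():
    """BCPE with nu=1, tau=2: exactly Normal(mu, mu*sigma)."""
    return FamilyParams(BCPE, mu=100.0, sigma=0.1, nu=1.0, tau=2.0)


@pytest.fixture
def bct_params():
    return FamilyParams(BCT, mu=30.0, sigma=0.2, nu=0.0, tau=10.0)
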