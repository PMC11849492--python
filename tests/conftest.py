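import pytest

from dermalink import simulate


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic cohort (positive planted driver-SIP correlation)."""
    return simulate.generate_cohort(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def driver_study():
    """Cohort with a planted negative driver-SIP correlation, the scenario
    where removing the driver should raise the module's median SCC."""
    cfg = simulate.SimConfig(
        seed=3,
        driver_spec=simulate.DriverSpec(target_sip="pore", target_correlation=-0.4),
    )
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def ages_of():
    def _ages(study):
        return study.metadata.set_index("sample_id").loc[study.phenome.index, "age"]

    return _ages
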