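import pytest

from chamberflux import (
    InstrumentModel,
    SiteForcing,
    TrueFluxModel,
    default_chamber_meta,
    simulate_campaign,
)


@pytest.fixture(scope="session")
def meta3():
    return default_chamber_meta(3)


@pytest.fixture(scope="session")
def small_campaign():
    """Three chambers, three days, default (noisy) instrument."""
    return simulate_campaign(
        SiteForcing(),
        TrueFluxModel(),
        InstrumentModel(n_chambers=3),
        "2009-06-01",
        "2009-06-04",
        seed=42,
        warming_start="2009-06-02",
    )


@pytest.fixture(scope="session")
def clean_campaign():
    """Noise-free campaign: no dead band, no spikes, no flow noise."""
    inst = InstrumentModel(
        n_chambers=3, co2_noise_sd=0.0, dead_band_records=0,
        spike_rate=0.0, flow_noise_sd=0.0,
    )
    return simulate_campaign(
        SiteForcing(), TrueFluxModel(), inst,
        "2009-03-01", "2009-03-03", seed=7, warming_start="2009-03-01",
    )
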