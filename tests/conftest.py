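import logging

import pytest

import traitpart as tp

logging.getLogger("traitpart").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design():
    return tp.generate_design(2, 4, seed=11)


@pytest.fixture(scope="session")
def one_site_design():
    return tp.generate_design(1, 4, seed=11)


@pytest.fixture(scope="session")
def community(design):
    """Default synthetic bundle: (cover, traits, biomass, truth)."""
    params = tp.SimulationParams(seed=11)
    return tp.generate_community(design, params)


@pytest.fixture(scope="session")
def cwm_tables(design, community):
    """Specific / fixed / ITV CWM long table for the default bundle."""
    import pandas as pd

    cover, traits, _, _ = community
    cover_dom = tp.filter_dominant(cover)
    spec = tp.bootstrap_cwm(traits, cover_dom, seed=21)
    refs = tp.reference_species_means(traits, design)
    fixed = tp.fixed_cwm(refs, cover_dom, design, seed=21)
    itv = tp.itv_component(spec, fixed)
    return pd.concat([spec, fixed, itv], ignore_index=True)
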