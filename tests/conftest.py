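"""Shared fixtures: one default synthetic genome pair per session, plus the
derived expression/motif data and the full five-method conservation run."""

import pytest

from lncsynt import conservation as cons
from lncsynt import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_cfg():
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def fixture(sim_cfg):
    return sd.generate_genome_pair(sim_cfg)


@pytest.fixture(scope="session")
def expression_data(sim_cfg, fixture):
    return sd.generate_expression(sim_cfg, fixture)


@pytest.fixture(scope="session")
def motif_data(sim_cfg, fixture):
    return sd.generate_motif_data(sim_cfg, fixture)


@pytest.fixture(scope="session")
def lnc_sequences(fixture):
    return fixture.lnc_sequences("human"), fixture.lnc_sequences("mouse")


@pytest.fixture(scope="session")
def method_pairs(fixture, lnc_sequences):
    """All five conservation methods run on the default fixture."""
    seqs_h, seqs_m = lnc_sequences
    lnc_h, lnc_m = fixture.lnc("human"), fixture.lnc("mouse")
    return {
        "symbol": cons.classify_by_symbol(
            lnc_h, lnc_m, fixture.truth.symbol_whitelist
        ),
        "global": cons.classify_global(
            lnc_h, lnc_m, fixture.chains_h2m, fixture.chains_m2h
        ),
        "local": cons.classify_local(
            lnc_h, lnc_m, fixture.coding("human"), fixture.coding("mouse"),
            fixture.orthologs, seqs_h, seqs_m,
        ),
        "sequence": cons.classify_sequence(
            lnc_h, lnc_m, seqs_h, seqs_m, fixture.track_h, fixture.track_m
        ),
        "promoter": cons.classify_promoter(
            lnc_h, lnc_m, fixture.genome_h, fixture.genome_m
        ),
    }
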