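import numpy as np
import pytest

from mixscreen import (
    ProcessingProtocol,
    RelativeAffinityModel,
)
from mixscreen.synthetic import (
    PMFSSpec,
    generate_scenario,
    make_pcs_single_mixture,
    table_fixtures,
)


@pytest.fixture(scope="session")
def single_fixtures():
    """Published single-candidate calibrations (BCHA/BMPL/BDETA/BME)."""
    return table_fixtures("single")


@pytest.fixture(scope="session")
def multi_fixtures():
    """Five-ligand calibrations around the BPDEDA reference."""
    return table_fixtures("multi")


@pytest.fixture
def protocol():
    """Standard single-candidate protocol: 2.0 mL system, 40 uL extract,
    5 uL injections, 40 uL PMFS."""
    return ProcessingProtocol()


def single_candidate_table(
    candidate,
    total_conc,
    fixtures,
    true_ratio=None,
    reference_conc=1.0e-6,
    noise_cv=0.0,
    seed=0,
    duplicates=1,
):
    """Noise-controlled single-candidate scenario -> (system, truth, table)."""
    mixture = make_pcs_single_mixture(candidate, content=0.5)
    spec = PMFSSpec(
        mixture=mixture,
        reference_id="BMPL",
        total_candidate_conc=total_conc,
        reference_conc_system=reference_conc,
    )
    truths = {candidate: true_ratio} if true_ratio is not None else None
    return generate_scenario(
        spec,
        seed=seed,
        truth_ratios=truths,
        fixtures=fixtures,
        noise_cv=noise_cv,
        duplicates=duplicates,
    )


def single_candidate_model(table, fixtures, candidate):
    return RelativeAffinityModel(
        table,
        fixtures.responses,
        fixtures.recovery,
        "BMPL",
        candidate_ids=[candidate],
    )


@pytest.fixture
def bcha_scenario(single_fixtures):
    """Noiseless BCHA scenario at an optimized composition (2.0 uM candidate,
    1.0 uM reference), truth 3.68."""
    system, truth, table = single_candidate_table("BCHA", 2.0e-6, single_fixtures)
    model = single_candidate_model(table, single_fixtures, "BCHA")
    return system, truth, table, model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210505)
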