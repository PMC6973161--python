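"""Shared fixtures: small hand-built objects plus session-scoped synthetic populations."""

import numpy as np
import pytest

from invcross.io import HET, MISSING, REC, GenotypeMatrix, MarkerMap
from invcross.simulate import (
    default_marker_map,
    generate_bc1,
    inversion_partition,
    preset,
)


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    """Ten markers on two chromosomes."""
    records = [
        ("M1-1", "1", 100_000), ("M1-2", "1", 900_000), ("M1-3", "1", 1_700_000),
        ("M1-4", "1", 2_400_000), ("M1-5", "1", 3_100_000), ("M1-6", "1", 4_000_000),
        ("M2-1", "2", 200_000), ("M2-2", "2", 1_000_000),
        ("M2-3", "2", 1_900_000), ("M2-4", "2", 2_600_000),
    ]
    return MarkerMap.from_records(records)


@pytest.fixture()
def toy_genotypes(small_map) -> GenotypeMatrix:
    calls = np.array(
        [
            [REC, REC, HET, HET, HET, HET, REC, REC, REC, REC],
            [HET, HET, HET, HET, HET, HET, HET, HET, HET, HET],
            [REC, MISSING, HET, HET, MISSING, HET, REC, HET, MISSING, HET],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["ind1", "ind2", "ind3"], calls, small_map, "toy")


@pytest.fixture(scope="session")
def study_map() -> MarkerMap:
    return default_marker_map()


@pytest.fixture(scope="session")
def partition(study_map):
    return inversion_partition(study_map)


@pytest.fixture(scope="session")
def control_population(study_map):
    """Control-male synthetic population (clean: no missing calls)."""
    scenario = preset("control_male", n=300, seed=11, missing_rate=0.0)
    genotypes, truth = generate_bc1(scenario)
    return genotypes, truth


@pytest.fixture(scope="session")
def mutant_population(study_map):
    """Mutant-male synthetic population carrying the inversion."""
    scenario = preset("mutant_male", n=418, seed=13, missing_rate=0.0)
    genotypes, truth = generate_bc1(scenario)
    return genotypes, truth
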