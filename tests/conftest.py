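import numpy as np
import pytest

from turnoverms.isotope_model import (
    EnrichmentModel,
    PeptideSpec,
    labeled_pattern,
    natural_isotope_pattern,
)


@pytest.fixture(scope="session")
def enrichment() -> EnrichmentModel:
    return EnrichmentModel(pW=0.046)


@pytest.fixture(scope="session")
def peptide() -> PeptideSpec:
    return PeptideSpec(sequence="FANTMGLVIER", charge=2)


@pytest.fixture(scope="session")
def natural(peptide) -> np.ndarray:
    return natural_isotope_pattern(peptide)


@pytest.fixture(scope="session")
def labeled(peptide, natural, enrichment) -> np.ndarray:
    return labeled_pattern(natural, peptide.neh, enrichment.excess_fraction)


@pytest.fixture(scope="session")
def schedule() -> np.ndarray:
    return np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 14.0, 21.0])
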