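import numpy as np
import pytest

from cepmap.coseg_search import (
    IndividualPanel,
    LocusPatterns,
    SegregationPattern,
    default_panel,
)
from cepmap.datasets import CROSS_COUNTS, CROSSES, MARKER_PATTERNS


@pytest.fixture(scope="session")
def panel() -> IndividualPanel:
    return default_panel()


@pytest.fixture(scope="session")
def marker_loci() -> list[LocusPatterns]:
    """The eleven assayed marker loci as observed pattern rows."""
    return [
        LocusPatterns(
            locus_id=marker,
            alleles=[
                (allele, SegregationPattern.from_string(pattern))
                for allele, pattern in rows
            ],
        )
        for marker, rows in MARKER_PATTERNS.items()
    ]


@pytest.fixture(scope="session")
def crosses():
    return CROSSES


@pytest.fixture(scope="session")
def cross_counts():
    return CROSS_COUNTS


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
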