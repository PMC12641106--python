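import numpy as np
import pandas as pd
import pytest
from hypothesis import strategies as st

from taxdist import OccurrenceMatrix, TaxonomyTable
from taxdist.simulate import paper_like_fixture


@pytest.fixture(scope="session")
def toy_tax() -> TaxonomyTable:
    """Four-species mixed taxonomy: 2 congeners + 1 confamilial + 1 other order."""
    return TaxonomyTable.from_records(
        [
            ("Hydrina alpha", "Hydrina", "Serpentidae", "Squamosa", "Reptilia"),
            ("Hydrina beta", "Hydrina", "Serpentidae", "Squamosa", "Reptilia"),
            ("Laticola gamma", "Laticola", "Serpentidae", "Squamosa", "Reptilia"),
            ("Chelonia delta", "Chelonia", "Testudidae", "Testudina", "Reptilia"),
        ]
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    return paper_like_fixture()


@pytest.fixture()
def tiny_occ(toy_tax) -> OccurrenceMatrix:
    df = pd.DataFrame(
        {
            "EastSea": [1, 1, 1, 1],
            "WestSea": [1, 1, 0, 0],
            "LoneRock": [0, 0, 1, 0],
        },
        index=toy_tax.species,
    )
    return OccurrenceMatrix(df)


# ---------------------------------------------------------------------------
# hypothesis strategies


@st.composite
def small_taxonomies(draw, max_species: int = 8):
    """Random rank-consistent taxonomy of 2..max_species species.

    Hierarchy consistency holds by construction: a child label embeds its
    full ancestor path.
    """
    n = draw(st.integers(2, max_species))
    records = []
    for i in range(n):
        c = draw(st.integers(0, 1))
        o = draw(st.integers(0, 1))
        f = draw(st.integers(0, 1))
        g = draw(st.integers(0, 2))
        records.append(
            (
                f"Sp{i}",
                f"G{c}.{o}.{f}.{g}",
                f"F{c}.{o}.{f}",
                f"O{c}.{o}",
                f"C{c}",
            )
        )
    return TaxonomyTable.from_records(records)


@st.composite
def taxonomy_with_assemblage(draw, max_species: int = 8):
    tax = draw(small_taxonomies(max_species))
    n = len(tax)
    size = draw(st.integers(2, n))
    idx = draw(st.permutations(range(n)))
    return tax, [tax.species[i] for i in idx[:size]]
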