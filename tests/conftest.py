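import numpy as np
import pytest

from covselect.demo import demo_condition, demo_design
from covselect.library import (
    CodonBook,
    KineticParams,
    LibraryDesign,
    LibraryMember,
    TagSchema,
)


@pytest.fixture(scope="session")
def tiny_schema() -> TagSchema:
    return TagSchema(
        upstream_constant="ACGTACGT",
        cycle_codon_lengths=(4, 4),
        downstream_constant="TTGGCCAA",
        umi_length=6,
    )


@pytest.fixture(scope="session")
def tiny_design(tiny_schema) -> LibraryDesign:
    """3×3 codon space (min Hamming 3), 8 members (one tuple left unused)."""
    books = [
        CodonBook(0, ("AAAA", "CCCC", "GGGG"), min_hamming=3),
        CodonBook(1, ("ACAC", "CGCG", "GTGT"), min_hamming=3),
    ]
    members = []
    mid = 0
    for i in range(3):
        for j in range(3):
            if (i, j) == (2, 2):
                continue  # valid codons, nonexistent combination
            members.append(
                LibraryMember(member_id=mid, codon_indices=(i, j), input_molecules=100)
            )
            mid += 1
    return LibraryDesign(schema=tiny_schema, codon_books=books, members=members)


@pytest.fixture(scope="session")
def small_design() -> LibraryDesign:
    """100-member demo-style library with one covalent spike-in tag."""
    return demo_design(
        n_members=100,
        member_input=1_000,
        spike_compounds=("A",),
        spike_inputs=(1_000,),
        seed=7,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20181101)


@pytest.fixture
def resin_2uM():
    def make(**kw):
        return demo_condition("resin", 2.0, **kw)

    return make
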