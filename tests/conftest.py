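import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from chemoscan.genomeforge import FamilySpec, forge_genome  # noqa: E402
from chemoscan.seqs import CODON_TABLE  # noqa: E402
from chemoscan.sixframe import ScoringScheme  # noqa: E402

CODONS_BY_AA: dict[str, list[str]] = {}
for c, a in sorted(CODON_TABLE.items()):
    CODONS_BY_AA.setdefault(a, []).append(c)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(CODONS_BY_AA[a][rng.integers(len(CODONS_BY_AA[a]))] for a in protein)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_forge():
    """A small forged genome shared by integration-level unit tests."""
    spec = FamilySpec(
        family_name="OR",
        n_genes=8,
        n_pseudo_stop=1,
        n_pseudo_frameshift=1,
        n_partial=1,
        tandem_cluster_sizes=(),
        scaffold_count=2,
        scaffold_length=100_000,
        rng_seed=42,
    )
    genome, truth, refs = forge_genome(spec)
    return spec, genome, truth, refs
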