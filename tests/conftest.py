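import random

import pytest

from orthocat.simulate import SimConfig, generate_contigs, generate_reference


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A compact mixed-defect scenario used by several integration tests."""
    return SimConfig(
        n_genes=20,
        seed=7,
        paralog_families=1,
        seleno_count=2,
        fragmented_genes=3,
        fused_pairs=2,
        intron_retained_genes=1,
        vector_inserted_genes=1,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(references, ortholog table, contigs, truth, vector db) for small_cfg."""
    references, table = generate_reference(small_cfg)
    contigs, truth, vector_db = generate_contigs(references, small_cfg)
    return references, table, contigs, truth, vector_db


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(1234)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)
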