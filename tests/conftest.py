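from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from proktf import DomainHit, load_default_registry, make_genome

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def planted():
    return make_genome(
        {"TR": 2, "OCS": 1, "RR": 1, "SF-ECF": 1, "ODP": 1},
        n_mispredicted=1,
        n_pseudogenes=1,
        seed=7,
    )


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_domain_hit(
    pid="P1",
    accession="HTH_TetR",
    evalue=1e-10,
    start=1,
    end=50,
    coverage=0.9,
    role="DBD",
    bitscore=100.0,
) -> DomainHit:
    return DomainHit(
        protein_id=pid,
        accession=accession,
        evalue=evalue,
        query_start=start,
        query_end=end,
        coverage=coverage,
        role=role,
        bitscore=bitscore,
    )
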