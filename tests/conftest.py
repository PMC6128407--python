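from pathlib import Path

import numpy as np
import pytest

from editmir import MiRNA, read_mirna_fasta

DATA_DIR = Path(__file__).parent / "data"


def random_mirna_catalog(n: int = 12, seed: int = 0, length: int = 22) -> list[MiRNA]:
    """Deterministic catalog of random mature miRNAs."""
    rng = np.random.default_rng(seed)
    catalog = []
    for i in range(n):
        mature = "".join(rng.choice(list("ACGU"), size=length))
        catalog.append(MiRNA(name=f"mir-{i:02d}", accession=f"MIMAT{i:07d}", mature=mature))
    return catalog


@pytest.fixture(scope="session")
def catalog():
    return random_mirna_catalog()


@pytest.fixture(scope="session")
def table1_catalog():
    """The 20 miRNAs of the published top-10 created/destroyed tables.

    Mature sequences are synthetic stand-ins constrained to the published
    seed regions (see the fixture file); only hsa-miR-140-3p carries its
    verbatim miRBase mature sequence.
    """
    return read_mirna_fasta(DATA_DIR / "table1_mirnas.synthetic.fa")
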