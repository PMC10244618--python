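import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

_STOP_FIX = {"TAA": "TAC", "TAG": "TAT", "TGA": "TGC"}


def random_cds(n_codons: int, seed: int = 1) -> str:
    """Deterministic stop-free toy ORF."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + ["".join(rng.choice(list("ACGT"), 3))
                        for _ in range(n_codons - 1)]
    return "".join(_STOP_FIX.get(c, c) for c in codons)


@pytest.fixture(scope="session")
def toy_cds() -> str:
    return random_cds(50)


@pytest.fixture(scope="session")
def toy_catalog(toy_cds):
    from nf2scan.catalog import design_catalog

    return design_catalog(toy_cds)


@pytest.fixture(scope="session")
def nf2_cds() -> str:
    from importlib import resources
    from io import StringIO

    from Bio import SeqIO

    text = resources.files("nf2scan.data").joinpath(
        "nf2_iso7_synthetic_cds.fasta").read_text()
    return str(next(SeqIO.parse(StringIO(text), "fasta")).seq)
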