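import numpy as np
import pytest

from earminer import SequenceRecord, simulate_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_proteome():
    """40 proteins, all carrying one implanted EAR window (divergence 0.1)."""
    records, truth = simulate_proteome(
        n=40, n_implant=40, length_mean=150, divergence_rate=0.1, seed=1234
    )
    return records, truth


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.faa"
    path.write_text(">p1 first\nDLNYYP\n>p2\nLLLALGGG\nAAA\n")
    return path
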