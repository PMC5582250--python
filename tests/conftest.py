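import numpy as np
import pytest

from mirhunt.io_formats import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write


def random_rna(rng, n, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def mature_record(rng):
    return SequenceRecord("ath-miR9001a", "test mature", random_rna(rng, 21))
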