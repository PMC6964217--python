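import numpy as np
import pytest

from pgnet import DiseaseCatalog, SyntheticConfig, generate

ASSOC_HEADER = "ncrna_id\tncrna_class\tdisease\tbiomarker\tdirection\tpmid\tsample_note\n"


@pytest.fixture(scope="session")
def catalog():
    return DiseaseCatalog.default()


@pytest.fixture
def assoc_file(tmp_path):
    """Factory: write association rows to a TSV and return its path."""

    def _write(rows, name="assoc.tsv"):
        path = tmp_path / name
        body = "".join("\t".join(str(x) for x in r) + "\n" for r in rows)
        path.write_text(ASSOC_HEADER + body)
        return path

    return _write


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset, shared across tests."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2020)
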