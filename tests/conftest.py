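import numpy as np
import pytest

from pharmnet.chemio_features import MoleculeRecord, ensure_conformer
from pharmnet.pharmacophore import packaged_model


@pytest.fixture(scope="session")
def igf1r_model():
    return packaged_model()


@pytest.fixture(scope="session")
def model_coords(igf1r_model):
    return igf1r_model.embed()


def make_record(smiles, name, embed=True):
    rec = MoleculeRecord(id=name, smiles=smiles)
    if embed:
        ensure_conformer(rec)
    return rec


@pytest.fixture
def smi_file(tmp_path):
    def _write(lines, name="lib.smi"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180522)
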