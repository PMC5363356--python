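import pytest

from isoforge.energy import EnergyModel
from isoforge.synthetic_data import focal_seed_pairs


@pytest.fixture(scope="session")
def energy_model():
    return EnergyModel.default()


@pytest.fixture(scope="session")
def mir34b_seeds():
    """(canonical, 5'-isomiR) seed specs for the miR-34b mimic sequence."""
    return focal_seed_pairs()["miR-34b"]


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="seqs.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
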