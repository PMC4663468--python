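import numpy as np
import pytest

from genefam.simulate import SimulationConfig, emit_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One emitted synthetic dataset shared across tests (seed 1)."""
    out = tmp_path_factory.mktemp("dataset") / "ds"
    config = SimulationConfig()
    truth = emit_dataset(config, out, seed=1, force=True)
    return {"dir": out, "truth": truth, "config": config}


@pytest.fixture(scope="session")
def annotation(small_dataset):
    from genefam.formats_io import read_gff3_fasta

    d = small_dataset["dir"]
    return read_gff3_fasta(d / "annotation.gff3", d / "genome.fasta",
                           cds_fasta=d / "cds.fasta",
                           protein_fasta=d / "proteins.fasta")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
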