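import numpy as np
import pytest

import ppiddg as pg
from ppiddg.model import ModelConfig, train
from ppiddg.pipeline import FeaturePipeline


TOY_PDB = """\
ATOM      1  N   LEU A  45      10.000  10.000  10.000  1.00 20.00           N
ATOM      2  CA  LEU A  45      11.400  10.200  10.100  1.00 20.00           C
ATOM      3  C   LEU A  45      12.100  10.100  11.400  1.00 20.00           C
ATOM      4  O   LEU A  45      11.600  10.600  12.400  1.00 20.00           O
ATOM      5  CB  LEU A  45      11.900  11.500   9.500  1.00 20.00           C
ATOM      6  CG  LEU A  45      11.600  11.700   8.000  1.00 20.00           C
ATOM      7  CD1 LEU A  45      12.200  13.000   7.500  1.00 20.00           C
ATOM      8  CD2 LEU A  45      12.100  10.500   7.200  1.00 20.00           C
ATOM      9  N   ALA A  46      13.200   9.400  11.500  1.00 20.00           N
ATOM     10  CA  ALA A  46      14.000   9.300  12.700  1.00 20.00           C
ATOM     11  C   ALA A  46      15.300   8.600  12.400  1.00 20.00           C
ATOM     12  O   ALA A  46      15.500   8.000  11.300  1.00 20.00           O
ATOM     13  CB  ALA A  46      13.300   8.500  13.800  1.00 20.00           C
ATOM     14  N   GLY B  12      12.900  13.800   5.800  1.00 20.00           N
ATOM     15  CA  GLY B  12      13.500  15.000   5.300  1.00 20.00           C
ATOM     16  C   GLY B  12      14.900  14.800   4.800  1.00 20.00           C
ATOM     17  O   GLY B  12      15.400  13.700   4.700  1.00 20.00           O
ATOM     18  N   SER B  13      15.600  15.900   4.500  1.00 20.00           N
ATOM     19  CA  SER B  13      17.000  15.800   4.100  1.00 20.00           C
ATOM     20  C   SER B  13      17.800  15.100   5.200  1.00 20.00           C
ATOM     21  O   SER B  13      17.400  15.100   6.400  1.00 20.00           O
ATOM     22  CB  SER B  13      17.600  17.200   3.900  1.00 20.00           C
ATOM     23  OG  SER B  13      17.000  17.900   2.800  1.00 20.00           O
HETATM   24  O   HOH A 201       5.000   5.000   5.000  1.00 30.00           O
END
"""


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture
def toy_structure():
    return pg.read_structure(TOY_PDB)


@pytest.fixture
def synthetic_complex():
    return pg.generate_synthetic_complex(10, seed=3, contact_pairs=4)


@pytest.fixture(scope="session")
def small_data():
    """A small featurized synthetic dataset shared across model tests."""
    records, structures = pg.generate_synthetic_dataset(
        60, pg.SyntheticGroundTruth(seed=11))
    pipeline = FeaturePipeline(provider=pg.stub_embedding_provider(16, seed=0))
    dataset = pipeline.featurize_dataset(records, structures)
    return records, structures, pipeline, dataset


@pytest.fixture(scope="session")
def quick_state(small_data):
    """A briefly trained model, good enough for driver/diagnostic contracts."""
    _, _, _, dataset = small_data
    return train(ModelConfig(seed=0, epochs=8), dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
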