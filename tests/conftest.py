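from pathlib import Path

import numpy as np
import pytest

from ck1switch import synthetic as syn

#: directory where locally supplied copies of deposited PDB entries live
ACCESSION_DIR = Path(__file__).parent / "data" / "accessions"


@pytest.fixture
def toy_up():
    return syn.make_toy_kinase(seed=0, state="up")


@pytest.fixture
def toy_down():
    return syn.make_toy_kinase(seed=0, state="down")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
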