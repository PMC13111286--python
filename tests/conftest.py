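import numpy as np
import pytest

from qhandpd import synthetic as syn
from qhandpd.io import read_exam_directory


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """Small synthetic exam directory shared across tests (5+5 subjects)."""
    root = tmp_path_factory.mktemp("exams")
    syn.generate_dataset(5, 5, draws_per_subject=2, seed=11, out_dir=root,
                         canvas_size=256, n_turns=2)
    return root


@pytest.fixture(scope="session")
def tiny_manifest(tiny_dataset_dir):
    return read_exam_directory(tiny_dataset_dir)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
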