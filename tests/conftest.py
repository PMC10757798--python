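import warnings

import numpy as np
import pandas as pd
import pytest

from dualica import DualICA, synthetic
from dualica.data import LFCMatrix

warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3x2 labeled LFC matrix for I/O round trips."""
    return LFCMatrix(
        values=np.array([[1.0, -2.5], [0.25, 6.75], [-3.0, 0.0]]),
        gene_ids=["gA", "gB", "gC"],
        condition_ids=["c1", "c2"],
    )


@pytest.fixture
def write_matrix(tmp_path):
    def _write(text, name="m.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def planted_fit():
    """One fitted pipeline on a small planted-module matrix, shared
    across tests that only inspect fitted attributes."""
    specs = [
        synthetic.ModuleSpec(40, 7, 4.0),
        synthetic.ModuleSpec(40, 7, -4.0),
        synthetic.ModuleSpec(40, 7, 4.0),
    ]
    M, truth = synthetic.generate(600, 50, specs, sigma=1.0, seed=7)
    est = DualICA(n_condition_ics=4, n_gene_ics=4, random_state=7).fit(M)
    return M, truth, est
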