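import numpy as np
import pandas as pd
import pytest

import nucblur as nb


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at default settings, shared across tests."""
    return nb.simulate_study(nb.SimConfig(), seed=0)


@pytest.fixture(scope="session")
def small_genome():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    return nb.GenomeSequence({"chr1": seq})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sites(rows) -> pd.DataFrame:
    """Helper: site table from (tf, chrom, start, end, strand, chip_p)."""
    return pd.DataFrame(
        rows, columns=["tf", "chrom", "start", "end", "strand", "chip_p"]
    )
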