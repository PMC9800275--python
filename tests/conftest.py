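import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from icbtox import SimConfig, aggregate_clones, gen_bcr_repertoire, gen_repertoire

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=7, n_patients=60, clone_count=200, depth=4000)


@pytest.fixture(scope="session")
def tcr_clones(small_cfg):
    return aggregate_clones(gen_repertoire(small_cfg, sample_id="S1"), key="cdr3_vj")


@pytest.fixture(scope="session")
def bcr_clones(small_cfg):
    return aggregate_clones(gen_bcr_repertoire(small_cfg, carrier=False, sample_id="B1"))


def make_clone_table(reads, chain="TRB", freqs=None):
    """Minimal clone table from a vector of read counts."""
    reads = np.asarray(reads, dtype=int)
    total = reads.sum()
    return pd.DataFrame(
        {
            "sample_id": "S1",
            "chain": chain,
            "cdr3_nt": [f"{'ACGT' * 4}{i:04d}".replace("0", "A").replace("1", "C")
                        .replace("2", "G").replace("3", "T").replace("4", "A")
                        .replace("5", "C").replace("6", "G").replace("7", "T")
                        .replace("8", "A").replace("9", "C") for i in range(len(reads))],
            "c_call": "",
            "total_reads": reads,
            "n_subs": 0,
            "n_ins": 0,
            "n_del": 0,
            "aligned_length": 300,
            "frequency": reads / total if freqs is None else np.asarray(freqs),
        }
    )
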