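import pandas as pd
import pytest

from codon_sda import reference as ref
from codon_sda.quant import ReferenceIndex
from codon_sda.simulate import SimulationConfig, write_fixtures


@pytest.fixture(scope="session")
def sim_config():
    # error-free reads with two planted misincorporation sites and both
    # contamination channels active, so filtering and calling are exercised
    return SimulationConfig(
        seed=11,
        read_depth=20_000,
        error_rate=0.0,
        planted_modifications=[("GAA", 34, 0.3), ("AGG", 58, 0.4)],
        premature_fraction=0.05,
        background_fraction=0.05,
    )


@pytest.fixture(scope="session")
def sim_paths(sim_config, tmp_path_factory):
    return write_fixtures(sim_config, tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def sim_clusters(sim_paths):
    return ref.read_mature_library(sim_paths["refdir"])


@pytest.fixture(scope="session")
def sim_library(sim_clusters):
    return {c.cluster_id: c.mature_seq for c in sim_clusters}


@pytest.fixture(scope="session")
def sim_index(sim_paths):
    return ReferenceIndex.from_refdir(sim_paths["refdir"])


@pytest.fixture(scope="session")
def read_truth(sim_paths):
    return pd.read_csv(sim_paths["read_truth"], sep="\t", keep_default_na=False)


@pytest.fixture()
def toy_genome():
    # 200 nt chromosome with a 72 nt tRNA-like gene at 60-132 (+ strand)
    import numpy as np

    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), 200))
    return {"chr1": seq}
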