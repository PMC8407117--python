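import numpy as np
import pytest
from hypothesis import settings

from rhizokmer import SimConfig, simulate_study

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 0)."""
    cfg = SimConfig(seed=0)
    genomes, annotations, truth, pheno, counts = simulate_study(cfg)
    return {"cfg": cfg, "genomes": genomes, "annotations": annotations,
            "truth": truth, "pheno": pheno, "counts": counts}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
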