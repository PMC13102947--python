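import pytest

import isletid as ii
from isletid.preprocess import QCParams

# the synthetic panel has ~200 genes, so the feature window is scaled down
# proportionally from the tissue-scale defaults; the mito bound is unchanged
SMALL_QC = QCParams(min_features=20, max_features=1000, max_mito_fraction=0.10)


@pytest.fixture(scope="session")
def small_sim():
    """Default small two-condition simulation, seed fixed."""
    cfg = ii.default_config("small")
    cfg.seed = 1
    adata, truth = ii.simulate_dataset(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full pipeline results on the small simulation."""
    cfg, adata, truth = small_sim
    res = ii.run_pipeline(
        adata, panel=cfg.panel, programs=cfg.programs, qc=SMALL_QC, seed=1
    )
    return cfg, res, truth
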