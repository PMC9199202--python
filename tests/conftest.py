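import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import damline as dl
from damline.pipeline import run_scenario

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_panel(genotypes, lines, ids=None, cm=None, chrom=None, lengths=None):
    """Build a GenotypePanel from a plain genotype matrix."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    ids = np.array([f"an{i}" for i in range(n)], object) if ids is None else np.asarray(ids, object)
    cm = np.arange(m, dtype=float) if cm is None else np.asarray(cm, float)
    chrom = ["1"] * m if chrom is None else list(chrom)
    table = pd.DataFrame({"chrom": chrom, "snp": [f"s{j}" for j in range(m)],
                          "cm": cm, "bp": (cm * 1e4).astype(int) + 1,
                          "a1": "A", "a2": "B"})
    markers = dl.MarkerMap(table, lengths=lengths)
    return dl.GenotypePanel(ids, np.asarray(lines, object), genotypes, markers)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_panel():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(5, 10))
    return make_panel(g, ["A", "A", "B", "C", "ABC"])


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down 'unrelated' scenario used across unit tests."""
    cfg = dl.preset_config("unrelated", n_purebred=200, n_crossbred=80,
                           snps_per_chrom=(600, 120), seed=5)
    return dl.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def unrelated_run():
    """Full-scale 'unrelated' replicate with every estimator applied."""
    cfg = dl.preset_config("unrelated", seed=7)
    result, estimates, truth = run_scenario(cfg)
    return result, estimates, truth


@pytest.fixture(scope="session")
def close_run():
    """Full-scale 'close' replicate with every estimator applied."""
    cfg = dl.preset_config("close", seed=7)
    result, estimates, truth = run_scenario(cfg)
    return result, estimates, truth
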