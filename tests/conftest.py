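import numpy as np
import pandas as pd
import pytest

from srnacontrib import FitConfig, SimulationConfig, fit_all, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but realistically proportioned simulated dataset."""
    cfg = SimulationConfig(n_genes=400, n_direct_targets=20, n_operon_partners=6,
                           seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    counts, design, annotation, truth = small_dataset
    fit = fit_all(counts, design, FitConfig())
    return fit, truth


def make_counts(arr, genes=None, libs=None) -> pd.DataFrame:
    arr = np.asarray(arr, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    libs = libs or [f"lib{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=libs)


def make_design(conditions, genotypes, libs=None) -> pd.DataFrame:
    libs = libs or [f"lib{j}" for j in range(len(conditions))]
    return pd.DataFrame(
        {"condition": conditions, "genotype": genotypes,
         "replicate": [str(i) for i in range(len(conditions))]},
        index=pd.Index(libs, name="library"),
    )
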