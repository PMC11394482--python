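import numpy as np
import pandas as pd
import pytest

from cmpnomics import AbundanceMatrix, ExperimentConfig, SampleInfo, generate_omics


@pytest.fixture(scope="session")
def small_config():
    return ExperimentConfig(
        n_features_protein=300, n_features_rna=400, effect_log2fc=2.0,
        frac_genotype_de=0.1, frac_treatment_de=0.1, seed=42,
    )


@pytest.fixture(scope="session")
def small_omics(small_config):
    return generate_omics(small_config)


@pytest.fixture
def tiny_matrix():
    """4 features x 4 samples, two groups, values chosen by hand (powers of 2)."""
    values = pd.DataFrame(
        np.power(2.0, np.arange(16, dtype=float).reshape(4, 4)),
        index=[f"f{i}" for i in range(4)],
        columns=["a1", "a2", "b1", "b2"],
    )
    design = {
        "a1": SampleInfo("WT", "VEH", 1),
        "a2": SampleInfo("WT", "VEH", 2),
        "b1": SampleInfo("WT", "PRG_MIF", 1),
        "b2": SampleInfo("WT", "PRG_MIF", 2),
    }
    return AbundanceMatrix(values=values, design=design, modality="proteomic")
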