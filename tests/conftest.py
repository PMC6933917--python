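import numpy as np
import pandas as pd
import pytest

from crossmod.data_io import ExpressionMatrix, SampleMetadata
from crossmod.synthetic import (
    DesignConfig,
    generate_design,
    generate_human_reference,
    generate_mouse_expression,
)


@pytest.fixture(scope="session")
def small_config() -> DesignConfig:
    """Desk-scale design: 3 mutant strains, 2 planted modules, 1 batch."""
    return DesignConfig(
        replicates={"strainA": 6, "strainB": 6, "strainC": 6, "B6": 6},
        batch_plan=None,
        module_sizes=(50, 40),
        n_background=150,
        noise_sd=0.3,
        module_delta={("M1", "strainA"): 1.0, ("M2", "strainB"): -0.8},
        n_de_per_strain=10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(design, tpm, counts, truth) for the small fixed-seed world."""
    design = generate_design(small_config, seed=11)
    tpm, counts, truth = generate_mouse_expression(design, small_config, seed=11)
    return design, tpm, counts, truth


@pytest.fixture(scope="session")
def small_human(small_config, small_dataset):
    """(catalog, lfc, omap) matched to the small dataset."""
    _, _, _, truth = small_dataset
    return generate_human_reference(truth, small_config, seed=12)


def make_expression(values, scale_tag="log2tpm", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale_tag
    )


def make_metadata(strains, batches=None, samples=None, control="B6"):
    samples = samples or [f"s{j}" for j in range(len(strains))]
    batches = batches or ["batch1"] * len(strains)
    return SampleMetadata(
        pd.DataFrame({"strain": strains, "batch": batches}, index=samples),
        control=control,
    )
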