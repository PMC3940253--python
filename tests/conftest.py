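import numpy as np
import pandas as pd
import pytest

from dexsea.io import ExpressionMatrix, SampleDesign


def make_design(n_per_cell: int = 2) -> SampleDesign:
    rows = []
    for tissue in ("blood", "cerebellum"):
        for genotype in ("transgenic", "wildtype"):
            for i in range(n_per_cell):
                rows.append((f"{tissue[:2]}_{genotype[:2]}_{i}", tissue, genotype))
    df = pd.DataFrame(rows, columns=["sample", "tissue", "genotype"])
    return SampleDesign(df.set_index("sample"))


def make_matrix(values: np.ndarray, design: SampleDesign,
                scale: str = "log2") -> ExpressionMatrix:
    genes = [f"G{i:04d}" for i in range(1, values.shape[0] + 1)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=design.sample_ids), scale=scale
    )


@pytest.fixture
def balanced_design() -> SampleDesign:
    """2 tissues x 2 genotypes x 2 replicates = 8 samples."""
    return make_design(2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
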