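import numpy as np
import pandas as pd
import pytest

from nephroscreen import ExpressionMatrix


def make_design(n_replicates: int = 4) -> pd.DataFrame:
    """A 2-strain x 2-treatment design with n replicates per group."""
    rows = {}
    for strain, s in (("susceptible", "sus"), ("resistant", "res")):
        for treatment, t in (("control", "ctrl"), ("diabetic", "dm")):
            for r in range(n_replicates):
                rows[f"{s}_{t}_{r + 1}"] = {"strain": strain, "treatment": treatment}
    design = pd.DataFrame.from_dict(rows, orient="index")
    design.index.name = "sample_id"
    return design


def make_matrix(
    values: np.ndarray | pd.DataFrame,
    design: pd.DataFrame,
    gene_symbols=None,
) -> ExpressionMatrix:
    """Wrap a plain array into an ExpressionMatrix over the given design."""
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(
            values,
            index=[f"p{i + 1}" for i in range(np.shape(values)[0])],
            columns=design.index,
        )
    if gene_symbols is None:
        gene_symbols = pd.Series(
            [f"g{i + 1}" for i in range(len(values))], index=values.index
        )
    return ExpressionMatrix(values, gene_symbols, design)


@pytest.fixture
def design4() -> pd.DataFrame:
    return make_design(4)


@pytest.fixture
def design2() -> pd.DataFrame:
    return make_design(2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
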