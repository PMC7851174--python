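import numpy as np
import pandas as pd
import pytest

from sqtlmap.io import CovariateTable, ExpressionTable
from sqtlmap.simulate import SimulationSpec, simulate_cohort


@pytest.fixture
def toy_expression() -> ExpressionTable:
    """2 transcripts of one gene, 3 samples."""
    tpm = pd.DataFrame(
        {"s1": [2.0, 2.0], "s2": [3.0, 1.0], "s3": [1.0, 4.0]},
        index=pd.Index(["tx1", "tx2"], name="transcript_id"),
    )
    gene = pd.Series(["g1", "g1"], index=tpm.index, name="gene_id")
    return ExpressionTable(tpm=tpm, gene_id=gene)


@pytest.fixture
def toy_covariates() -> CovariateTable:
    df = pd.DataFrame(
        {"age": [30.0, 40.0, 50.0], "sex": ["m", "f", "f"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return CovariateTable(df)


@pytest.fixture(scope="session")
def small_cohort():
    """60-gene cohort with 30% true sGenes at MD 0.3, shared across tests."""
    spec = SimulationSpec(
        n_samples=120, n_genes=60, transcripts_per_gene=3,
        effect_md=0.3, frac_sgenes=0.3, seed=42,
    )
    return spec, simulate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
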