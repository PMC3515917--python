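import numpy as np
import pandas as pd
import pytest

from naevus_omics import ExpressionMatrix


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 complete patient pairs, hand-written values."""
    values = pd.DataFrame(
        {
            "P1_MC": [5.0, 1.0, 2.0],
            "P1_DNMC": [7.0, 1.0, 2.5],
            "P2_MC": [4.0, 2.0, 3.0],
            "P2_DNMC": [4.5, 2.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    sheet = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2", "P2"],
            "condition": ["MC", "DNMC", "MC", "DNMC"],
        },
        index=pd.Index(["P1_MC", "P1_DNMC", "P2_MC", "P2_DNMC"], name="sample_id"),
    )
    return ExpressionMatrix(values=values, sample_sheet=sheet)


def paired_matrix(values: np.ndarray, gene_prefix: str = "g") -> ExpressionMatrix:
    """Wrap a genes x (2*n_pairs) array as MC columns then DNMC columns."""
    n = values.shape[1] // 2
    patients = [f"P{i+1}" for i in range(n)]
    mc = [f"{p}_MC" for p in patients]
    dn = [f"{p}_DNMC" for p in patients]
    genes = [f"{gene_prefix}{i+1}" for i in range(values.shape[0])]
    sheet = pd.DataFrame(
        {"patient_id": patients * 2, "condition": ["MC"] * n + ["DNMC"] * n},
        index=pd.Index(mc + dn, name="sample_id"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=mc + dn),
        sample_sheet=sheet,
    )
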