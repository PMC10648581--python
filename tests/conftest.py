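import numpy as np
import pandas as pd
import pytest

from mirec import (
    MirnaExpressionMatrix,
    SyntheticCohortConfig,
    generate_cohort,
    normalize_ct,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (352 + 32 assays, 119 samples)."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_expr(default_cohort):
    raw, _, _ = default_cohort
    return normalize_ct(raw)


@pytest.fixture(scope="session")
def default_annotations(default_cohort):
    return default_cohort[1]


def expr_matrix(values, mirna_ids=None, sample_ids=None) -> MirnaExpressionMatrix:
    """Small in-memory expression matrix from a nested list."""
    values = np.asarray(values, dtype=float)
    mirna_ids = mirna_ids or [f"m{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return MirnaExpressionMatrix(tuple(mirna_ids), tuple(sample_ids), values)


def two_group_annotations(n_pos, n_neg, variable="molecular", level="MMRd", other="p53wt"):
    """Annotation table with a single binary split on one variable."""
    n = n_pos + n_neg
    ann = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "histology": ["endometrioid"] * n,
            "grade": ["unknown"] * n,
            "molecular": ["unknown"] * n,
            "ctnnb1": ["unknown"] * n,
        }
    )
    ann.loc[: n_pos - 1, variable] = level
    ann.loc[n_pos:, variable] = other
    return ann
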