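import numpy as np
import pandas as pd
import pytest

from icgsig.containers import ExpressionMatrix


def make_matrix(values, feature_ids, sample_ids, **ann_columns) -> ExpressionMatrix:
    """Build a small ExpressionMatrix with optional annotation columns."""
    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids, dtype=float)
    annotation = None
    if ann_columns:
        annotation = pd.DataFrame(ann_columns, index=frame.index)
    return ExpressionMatrix(frame, annotation)


@pytest.fixture
def single_gene_matrix() -> ExpressionMatrix:
    """One gene, three samples, log2 values [1, 2, 3]."""
    return make_matrix([[1.0, 2.0, 3.0]], ["G1"], ["s1", "s2", "s3"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
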