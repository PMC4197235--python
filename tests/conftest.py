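import numpy as np
import pandas as pd
import pytest

from heartnet.study import ExpressionStudy


def study_from_matrix(mat, conditions, feature_ids=None, condition_order=None):
    """Build an ExpressionStudy from a plain matrix and condition labels."""
    mat = np.asarray(mat, dtype=float)
    n_feat, n_samp = mat.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(n_feat)]
    sample_ids = [f"s{i}" for i in range(n_samp)]
    values = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
    return ExpressionStudy(
        values=values,
        gene_symbols=pd.Series(feature_ids, index=feature_ids),
        conditions=pd.Series(list(conditions), index=sample_ids),
        replicates=pd.Series(range(n_samp), index=sample_ids),
        condition_order=condition_order,
    )


@pytest.fixture
def timecourse_conditions():
    """15-sample design: 5 conditions x 3 replicates."""
    return [c for c in ("control", "1d", "3d", "5d", "7d") for _ in range(3)]
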