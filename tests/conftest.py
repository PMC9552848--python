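import numpy as np
import pandas as pd
import pytest

from mesotyper.containers import ExpressionMatrix


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{j}" for j in range(12)]
    values = pd.DataFrame(rng.normal(7, 2, size=(30, 12)), index=genes,
                          columns=samples)
    return ExpressionMatrix(values)


def true_four_groups(truth):
    """Sample -> one of the four module-level groups (immune merged)."""
    t = truth.true_labels.labels
    grp = t.where(t == "non_immune", "immune")
    return grp.where(grp == "immune", truth.subgroup)
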