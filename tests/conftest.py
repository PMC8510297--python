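import numpy as np
import pandas as pd
import pytest

from reposign.expression_io import ExpressionDataset
from reposign.meta_analysis import GeneSignature


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    dataset_id: str,
    n_genes: int = 20,
    n_case: int = 5,
    n_ctrl: int = 5,
    effect: float = 0.0,
    seed: int = 0,
    gene_prefix: str = "G",
) -> ExpressionDataset:
    """Small normal-noise cohort; `effect` shifts case means of every gene."""
    r = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    case = r.normal(effect, 1.0, size=(n_genes, n_case))
    ctrl = r.normal(0.0, 1.0, size=(n_genes, n_ctrl))
    cols = [f"{dataset_id}_c{i}" for i in range(n_case)] + [
        f"{dataset_id}_n{i}" for i in range(n_ctrl)
    ]
    expr = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=cols)
    labels = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=cols)
    return ExpressionDataset(dataset_id, expr, labels)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, 2 case / 2 control, hand-set values."""
    expr = pd.DataFrame(
        [[2.0, 3.0, 0.0, 1.0], [5.0, 6.0, 5.5, 6.5], [1.0, 2.0, 3.0, 4.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series(["case", "case", "control", "control"],
                       index=["s1", "s2", "s3", "s4"])
    return ExpressionDataset("tiny", expr, labels)


@pytest.fixture
def simple_signature() -> GeneSignature:
    return GeneSignature(
        up=[("GU1", 1.5), ("GU2", 0.8)],
        down=[("GD1", -1.2), ("GD2", -0.5)],
    )
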