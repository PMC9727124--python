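import numpy as np
import pandas as pd
import pytest

from immunoclass.io import ExpressionMatrix, GeneSignature, SignatureCollection
from immunoclass.synth import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort: n=60, 2000 genes, default planted effects."""
    return generate_cohort(SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort for pipeline/IO tests."""
    return generate_cohort(SyntheticCohortSpec(n_samples=40, n_genes=300, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_expr():
    """5 genes x 4 samples, log2 scale, fixed values."""
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [2.0, 2.0, 2.0, 2.0],
                [0.0, 5.0, 1.0, 3.0],
                [3.0, 1.0, 4.0, 0.0],
            ]
        ),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(values, "log2norm")


def make_signature(name, genes, category="function"):
    return GeneSignature(name, category, frozenset(genes))


@pytest.fixture()
def tiny_sigs():
    return SignatureCollection(
        [
            GeneSignature("sigA", "cell_type", frozenset(["g0", "g1"])),
            GeneSignature("sigB", "cell_type", frozenset(["g3"])),
        ]
    )
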