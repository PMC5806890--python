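import numpy as np
import pandas as pd
import pytest

from coexnet import simgen
from coexnet.exprdata import ExpressionMatrix
from coexnet.goldstd import OntologyDAG


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, kind="raw_counts", gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values)
    return ExpressionMatrix(
        data=pd.DataFrame(
            values,
            index=[f"{gene_prefix}{i}" for i in range(values.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        ),
        kind=kind,
    )


@pytest.fixture()
def random_counts(rng):
    return make_matrix(rng.integers(0, 200, size=(100, 10)))


@pytest.fixture(scope="session")
def toy_dag():
    """Seven-term, two-branch DAG with hand-checkable IC values.

    root(8 genes) -> A(4: a1..a4), B(4: b1..b4); A -> A1(2: a1,a2),
    A2(2: a3,a4); B -> B1(2: b1,b2). Direct annotations only at the
    leaves plus b3,b4 directly on B.
    """
    parents = {
        "root": set(),
        "A": {"root"},
        "B": {"root"},
        "A1": {"A"},
        "A2": {"A"},
        "B1": {"B"},
        "B2": {"B"},
    }
    annotations = {
        "a1": {"A1"},
        "a2": {"A1"},
        "a3": {"A2"},
        "a4": {"A2"},
        "b1": {"B1"},
        "b2": {"B1"},
        "b3": {"B2"},
        "b4": {"B2"},
    }
    return OntologyDAG(parents=parents, annotations=annotations)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by the slower integration tests."""
    return simgen.simulate_study(
        simgen.SimConfig(n_genes=150, n_samples=60, n_modules=4, module_size=(10, 10), seed=3)
    )
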