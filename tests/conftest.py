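import numpy as np
import pandas as pd
import pytest

from drugatlas import (
    Annotation,
    DistanceMatrix,
    ResponseMatrix,
    SimConfig,
    cluster_drugs,
    generate_panel,
)


def random_distance_matrix(n: int, seed: int, labels=None) -> DistanceMatrix:
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    labels = labels or [f"L{i:02d}" for i in range(n)]
    return DistanceMatrix(pd.DataFrame(m, index=labels, columns=labels),
                          metric="cosine")


def random_tree(n: int, seed: int, method: str = "average"):
    return cluster_drugs(random_distance_matrix(n, seed), method=method)


@pytest.fixture(scope="session")
def default_panel():
    """One panel at the default study conditions, shared across tests."""
    return generate_panel(SimConfig(seed=11))


@pytest.fixture()
def small_response():
    """3 drugs x 4 cell lines, complete, hand-checkable."""
    values = pd.DataFrame(
        [[0.1, 0.2, 0.8, 0.9],
         [0.2, 0.1, 0.9, 0.8],
         [0.9, 0.8, 0.2, 0.1]],
        index=["dA", "dB", "dC"],
        columns=["c1", "c2", "c3", "c4"],
    )
    tissues = {c: "brain" for c in values.columns}
    return ResponseMatrix(values=values, value_kind="auc", tissue_of=tissues)


@pytest.fixture()
def toy_annotation():
    return Annotation(
        targets_of={"dA": {"EGFR"}, "dB": {"KRAS"}, "dC": {"EGFR", "BRAF"}},
        mutated_in={"c1": {"EGFR"}, "c2": {"KRAS", "BRAF"}, "c3": set()},
        pathway_of={"dA": "rtk", "dB": "ras", "dC": "rtk"},
        cross_reactive={"dC"},
    )
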