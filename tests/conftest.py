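import numpy as np
import pytest
from hypothesis import settings

from tmactive import (
    FeatureSet,
    GeneratorParams,
    PreparedProtein,
    PropertyTable,
    ProteinRecord,
    generate_dataset,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture(scope="session")
def small_dataset():
    """20 synthetic membrane proteins with gold labels and segments."""
    return generate_dataset(GeneratorParams(n_proteins=20, seed=7))


def make_prepared(
    protein_id: str,
    nodes: list[int],
    classes: list[int] | None = None,
    n_dims: int = 4,
) -> PreparedProtein:
    """Minimal PreparedProtein stub for selector tests: only node
    assignments and window counts matter there."""
    n = len(nodes)
    l = 16
    classes = classes if classes is not None else [0] * n
    record = ProteinRecord(
        id=protein_id, sequence="A" * (n + l - 1), labels=np.zeros(n + l - 1, dtype=np.int8)
    )
    features = FeatureSet(
        protein_id=protein_id,
        window_length=l,
        raw=np.zeros((n, 16), dtype=np.int64),
        window_starts=np.arange(n),
        projected=np.zeros((n, n_dims)),
    )
    return PreparedProtein(
        record=record,
        features=features,
        nodes=np.asarray(nodes),
        classes=np.asarray(classes, dtype=np.int8),
    )
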