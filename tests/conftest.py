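import numpy as np
import pandas as pd
import pytest

from germdiv.io import MarkerMatrix
from germdiv.synthetic import make_study_shaped_bundle


def make_marker_matrix(columns: dict[str, list], accessions=None) -> MarkerMatrix:
    """Build a MarkerMatrix from band -> values; band names 'PRIMER.suffix'."""
    n = len(next(iter(columns.values())))
    accs = accessions or [f"AP{i + 1}" for i in range(n)]
    data = pd.DataFrame({b: np.asarray(v, dtype=float) for b, v in columns.items()},
                        index=accs)
    primers = pd.Series({b: b.split(".", 1)[0] for b in columns})
    return MarkerMatrix(data=data, primers=primers)


@pytest.fixture(scope="session")
def bundle():
    """Study-shaped synthetic input bundle (24 accessions, 6 ecotypes,
    13 two-band primers, 9 traits x 3 blocks, 4 compounds)."""
    return make_study_shaped_bundle(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
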