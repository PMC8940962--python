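import numpy as np
import pandas as pd
import pytest

from matncycle import SimConfig


@pytest.fixture
def simcfg():
    return SimConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_refaln():
    """Minimal hand-built reference alignment for anchor/alignment tests.

    Anchor row 'refA' has the key tyrosine at ungapped position 5 (column 6,
    because of the single leading gap region in that row).
    """
    from matncycle import ReferenceAlignment

    rows = [
        ("refA", "AC-DEYFGHIKL"),
        ("refB", "ACMDEYFGHIKL"),
        ("refC", "ACMDEWFGHIKL"),
    ]
    return ReferenceAlignment(
        rows=rows,
        anchor_ref="refA",
        anchor_pos=5,
        class_labels={"refA": "AOB-HAO", "refB": "AOB-HAO", "refC": "epsilonHao"},
    )


def layers_ratio_matrix(rng, n_layers=6, n_markers=7):
    """Random positive layers x markers table for community tests."""
    data = 10 ** rng.normal(0, 0.5, size=(n_layers, n_markers))
    return pd.DataFrame(
        data,
        index=[f"Layer{i + 1}" for i in range(n_layers)],
        columns=[f"m{j}" for j in range(n_markers)],
    )
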