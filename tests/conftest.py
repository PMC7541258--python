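import numpy as np
import pandas as pd
import pytest

from mrsynergy.network import RegulatoryNetwork
from mrsynergy.signatures import DESignature


def make_network(rows):
    """Build a network from (regulator, target, mor, likelihood) tuples."""
    return RegulatoryNetwork(
        pd.DataFrame(rows, columns=["regulator", "target", "mor", "likelihood"])
    )


def make_signature(scores, dataset_id="ds1", platform="microarray"):
    return DESignature(
        dataset_id=dataset_id, platform=platform, scores=pd.Series(scores, dtype=float)
    )


@pytest.fixture
def toy_net():
    return make_network(
        [
            ("A", "g1", 1.0, 0.9),
            ("A", "g2", -0.5, 0.8),
            ("B", "g2", 1.0, 0.7),
            ("B", "g3", 0.8, 0.6),
        ]
    )


@pytest.fixture
def random_net():
    rng = np.random.default_rng(5)
    rows = []
    seen = set()
    while len(rows) < 50:
        reg = f"R{rng.integers(0, 8)}"
        tgt = f"g{rng.integers(0, 40)}"
        if reg == tgt or (reg, tgt) in seen:
            continue
        seen.add((reg, tgt))
        rows.append((reg, tgt, float(rng.uniform(-1, 1)), float(rng.uniform(0.1, 1))))
    return make_network(rows)
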