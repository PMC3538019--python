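import numpy as np
import pandas as pd
import pytest

from pyroaei.io_formats import MeasurementTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_measurements(rows):
    """rows: (sample_id, gene, tissue, material, pct_a) tuples; pct_b completes to 100."""
    df = pd.DataFrame(
        [
            {
                "sample_id": s,
                "gene": g,
                "tissue": t,
                "material": m,
                "pct_a": p,
                "pct_b": 100.0 - p,
            }
            for s, g, t, m, p in rows
        ]
    )
    return MeasurementTable(df)
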