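import numpy as np
import pandas as pd
import pytest

from chemosweep.trajdyn import TrajectoryTable

DAYS = [5.0, 7.0, 14.0, 20.0, 28.0, 35.0, 40.0, 45.0, 50.0, 56.0, 60.0]


def make_table(rows: dict, days=None) -> TrajectoryTable:
    """Build a TrajectoryTable from {mutation_id: (meta_dict, freq_list)}."""
    days = list(days) if days is not None else DAYS
    meta_defaults = {
        "position": 1, "ref": "A", "alt": "G", "mut_class": "SNP",
        "gene": "intergenic", "effect": "noncoding", "role": "passenger",
    }
    index = pd.Index(list(rows), name="mutation_id")
    meta = pd.DataFrame(
        [{**meta_defaults, **m} for m, _ in rows.values()], index=index
    )
    freqs = pd.DataFrame(
        [list(f) for _, f in rows.values()], index=index, columns=[float(d) for d in days]
    )
    return TrajectoryTable(meta=meta, freqs=freqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
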