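import numpy as np
import pandas as pd
import pytest

from microvol.core import LongitudinalMicrobiomeTable


def make_table(counts, subjects, times, taxa=None, depths=None):
    """Build a small table from a (taxa x samples) array and metadata lists."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    taxa = taxa or [f"t{j}" for j in range(n_taxa)]
    sample_ids = [f"s{k}" for k in range(n_samples)]
    meta = pd.DataFrame(
        {"subject": subjects, "time_days": times}, index=sample_ids
    )
    if depths is not None:
        meta["original_read_depth"] = depths
    return LongitudinalMicrobiomeTable(
        pd.DataFrame(counts, index=taxa, columns=sample_ids), meta
    )


@pytest.fixture
def tiny_table():
    """3 taxa x 4 samples, two subjects sampled on days 0 and 1."""
    return make_table(
        [[5, 2, 8, 0], [5, 8, 2, 10], [0, 10, 0, 10]],
        subjects=["A", "A", "B", "B"],
        times=[0.0, 1.0, 0.0, 1.0],
    )


@pytest.fixture
def daily_table():
    """One subject, 10 daily samples, 4 taxa, seeded random counts."""
    rng = np.random.default_rng(7)
    return make_table(
        rng.integers(0, 50, size=(4, 10)),
        subjects=["A"] * 10,
        times=list(range(10)),
    )
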