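import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrchain import SummaryStatsTable

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def make_table(rows, trait_id="trait", trait_type="quantitative"):
    """Build a SummaryStatsTable from a list of per-variant dicts.

    Missing optional fields (chrom, pos, eaf, n) are filled with defaults.
    """
    defaults = {"chrom": "1", "pos": 1_000_000, "eaf": 0.3, "n": 10_000.0}
    filled = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("pos", 1_000_000 * (i + 1))
        r.update(row)
        filled.append(r)
    df = pd.DataFrame(filled, columns=[
        "rsid", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "n",
    ])
    return SummaryStatsTable(trait_id, trait_type, df)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
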