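import numpy as np
import pandas as pd
import pytest

from revmr.sumstats import COLUMNS, SummaryStats


def make_table(rows, trait_name="trait", trait_type="continuous"):
    """Build a SummaryStats from (rsid, ea, oa, eaf, beta, se, pval, n) tuples."""
    df = pd.DataFrame(rows, columns=COLUMNS)
    return SummaryStats(trait_name=trait_name, trait_type=trait_type, df=df)


def random_table(rng, n=50, trait_name="rand", trait_type="continuous"):
    pairs = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
    rows = []
    for i in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        rows.append((
            f"rs{i:06d}", ea, oa, float(rng.uniform(0.01, 0.99)),
            float(rng.normal(0, 0.1)), float(rng.uniform(0.001, 0.05)),
            float(rng.uniform(1e-12, 1.0)), int(rng.integers(1000, 100000)),
        ))
    return make_table(rows, trait_name, trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def toy_harmonised():
    """Exactly proportional data: Gamma = 0.3 * gamma, tiny equal SEs."""
    from revmr.harmonise import HarmonisedSet

    gamma = np.array([0.1, 0.2, 0.4, 0.15, 0.3])
    return HarmonisedSet.from_arrays(
        gamma, np.full(5, 0.01), 0.3 * gamma, np.full(5, 0.02))
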