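import numpy as np
import pytest

from mrscreen.summstats import (
    AssociationTable,
    HarmonizedInstrument,
    VariantAssociation,
)

PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def make_instruments(gx, gy, se_y, se_x=None, ids=None):
    """Build HarmonizedInstrument list from parallel arrays."""
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    se_x = np.full_like(gx, 1e-6) if se_x is None else np.asarray(se_x, dtype=float)
    ids = ids or [f"rs{i}" for i in range(len(gx))]
    return [
        HarmonizedInstrument(
            snp_id=ids[i], gamma_x=gx[i], se_x=se_x[i], gamma_y=gy[i], se_y=se_y[i],
            eaf=0.3, n_x=50_000, n_y=100_000,
        )
        for i in range(len(gx))
    ]


def random_instruments(rng, j=10, beta=0.2):
    """Random well-conditioned instrument set for oracle comparisons."""
    gx = rng.uniform(0.05, 0.3, j) * rng.choice([-1.0, 1.0], j)
    se_x = rng.uniform(0.005, 0.02, j)
    se_y = rng.uniform(0.01, 0.05, j)
    gy = beta * gx + rng.normal(0.0, se_y)
    return make_instruments(gx, gy, se_y, se_x)


def random_table(rng, n=10, name="trait"):
    """Random valid AssociationTable (no palindromic SNPs)."""
    records = {}
    for i in range(n):
        ea, oa = PAIRS[int(rng.integers(len(PAIRS)))]
        sid = f"rs{i}"
        records[sid] = VariantAssociation(
            snp_id=sid, effect_allele=ea, other_allele=oa,
            eaf=float(rng.uniform(0.05, 0.95)),
            beta=float(rng.normal(0, 0.1)),
            se=float(rng.uniform(0.001, 0.1)),
            pval=float(rng.uniform(1e-12, 1.0)),
            n=int(rng.integers(1_000, 500_000)),
        )
    return AssociationTable(trait_name=name, records=records, sample_size_default=50_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
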