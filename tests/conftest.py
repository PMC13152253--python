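import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import HarmonizedInstrumentSet, SummaryStatSet


def make_sumstats(rows, trait="trait", scale="sd"):
    """Build a SummaryStatSet from a list of dicts with defaults filled in."""
    defaults = {
        "chromosome": "1",
        "position": 1_000_000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pvalue": 1e-10,
        "n": 100_000,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"variant_id": f"rs{i + 1}", **defaults, **row}
        records.append(rec)
    df = pd.DataFrame(records)[
        ["variant_id", "chromosome", "position", "effect_allele", "other_allele",
         "eaf", "beta", "se", "pvalue", "n"]
    ]
    return SummaryStatSet(trait, df, scale)


def make_harmonized(bx, sx, by, sy, scale="sd"):
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    n = len(bx)
    sx = np.broadcast_to(np.asarray(sx, float), (n,))
    sy = np.broadcast_to(np.asarray(sy, float), (n,))
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(n)],
            "beta_exposure": np.asarray(bx, float),
            "se_exposure": sx,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": sy,
        }
    )
    return HarmonizedInstrumentSet("exposure", "outcome", table, scale=scale)


@pytest.fixture
def random_instruments():
    """A reproducible 20-instrument set with heterogeneity (residual scale > 1)."""
    rng = np.random.default_rng(11)
    n = 20
    bx = rng.uniform(0.03, 0.12, n) * rng.choice([-1, 1], n)
    sx = np.full(n, 0.004)
    sy = rng.uniform(0.008, 0.02, n)
    by = 0.4 * bx + rng.standard_normal(n) * sy * 2.5  # over-dispersed
    return make_harmonized(bx, sx, by, sy)
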