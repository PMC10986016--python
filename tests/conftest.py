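import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrmediate import HarmonizedSet, SummaryStatTable


def make_table(label, rows):
    """Build a SummaryStatTable from dicts; unspecified fields get defaults."""
    defaults = {
        "CHR": "1",
        "BP": 1000,
        "EA": "A",
        "OA": "G",
        "EAF": 0.3,
        "BETA": 0.1,
        "SE": 0.01,
        "P": 1e-10,
        "N": 100_000,
    }
    full = []
    for i, row in enumerate(rows):
        r = {"SNP": f"rs{i + 1}", **defaults, **row}
        full.append(r)
    return SummaryStatTable(label, pd.DataFrame(full))


def make_harmonized(bx, sx, by, sy, bm=None, sm=None):
    """HarmonizedSet straight from effect arrays (exposure [, mediator], outcome)."""
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in (bx, sx, by, sy))
    k = len(bx)
    cols = [(bx, sx)]
    traits = ["exposure"]
    if bm is not None:
        cols.append((np.asarray(bm, float), np.asarray(sm, float)))
        traits.append("mediator")
    cols.append((by, sy))
    traits.append("outcome")
    beta = np.column_stack([c[0] for c in cols])
    se = np.column_stack([c[1] for c in cols])
    pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    snp_ids = [f"rs{i + 1}" for i in range(k)]
    return HarmonizedSet(
        snp_ids=snp_ids,
        traits=traits,
        beta=beta,
        se=se,
        eaf=np.full_like(beta, 0.3),
        n=np.full_like(beta, 100_000.0),
        pval=pval,
        effect_allele=["A"] * k,
        other_allele=["G"] * k,
        chrom=["1"] * k,
        pos=np.arange(1, k + 1, dtype=np.int64) * 1_000_000,
        drop_log=pd.DataFrame({"SNP": snp_ids, "disposition": ["kept"] * k}),
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def h_factory():
    return make_harmonized


@pytest.fixture
def rng():
    return np.random.default_rng(20240402)


def random_harmonized(rng, k, beta_true=0.5, sy_scale=0.01, sx_scale=0.005,
                      intercept=0.0):
    """Random noise-free-instrument pair instance for oracle comparisons."""
    bx = rng.uniform(0.05, 0.3, size=k) * rng.choice([-1, 1], size=k)
    sx = rng.uniform(0.5, 1.5, size=k) * sx_scale
    sy = rng.uniform(0.5, 1.5, size=k) * sy_scale
    by = intercept * np.sign(bx) + beta_true * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)
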