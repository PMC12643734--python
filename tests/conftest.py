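import numpy as np
import pandas as pd
import pytest

from mrmediation.summary_data import (
    HarmonizedSet,
    SummaryDataset,
    VariantAssociation,
)


def make_variant(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                 eaf=0.3, beta=0.1, se=0.02, pvalue=1e-6, n=3757):
    return VariantAssociation(snp_id, chrom, pos, ea, oa, eaf, beta, se, pvalue, n)


def make_dataset(variants, trait_id="trait", trait_type="exposure"):
    return SummaryDataset.from_variants(trait_id, variants, trait_type=trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_hset(rng):
    """20 instruments around a true slope of 0.4, moderate noise."""
    k = 20
    bx = rng.normal(0.15, 0.05, k)
    bx = np.where(np.abs(bx) < 0.02, 0.05, bx)
    sx = np.full(k, 0.02)
    sy = rng.uniform(0.01, 0.03, k)
    by = 0.4 * bx + rng.normal(0, sy)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


@pytest.fixture
def exact_line_hset():
    """Rows exactly on beta_y = 0.01 + 0.5 beta_x (all beta_x > 0)."""
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    by = 0.01 + 0.5 * bx
    return HarmonizedSet.from_arrays(bx, np.full(5, 0.02), by, np.full(5, 0.01))


def dense_panel(n=10, seed=0, p_scale=1e-8):
    """A one-chromosome panel with graded p-values for clumping tests."""
    rng = np.random.default_rng(seed)
    variants = []
    for i in range(n):
        variants.append(
            make_variant(
                snp_id=f"rs{i + 1}", chrom="1", pos=1000 + i * 3000,
                eaf=float(rng.uniform(0.1, 0.5)), beta=float(rng.normal(0.2, 0.05)),
                se=0.02, pvalue=p_scale * (i + 1), n=3757,
            )
        )
    return make_dataset(variants)
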