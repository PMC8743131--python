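import numpy as np
import pandas as pd
import pytest

from mrpipe.harmonize import HarmonizedSet
from mrpipe.sumstats import CANONICAL_COLUMNS, SummaryStats


def make_sumstats(trait_id="trait", variant_ids=None, betas=None, ses=None,
                  pvalues=None, chromosomes=None, positions=None,
                  effect_alleles=None, other_alleles=None, eafs=None, n=None):
    """Assemble a SummaryStats from plain lists, with sensible defaults."""
    k = len(variant_ids)
    betas = betas if betas is not None else [0.1] * k
    ses = ses if ses is not None else [0.01] * k
    from scipy import stats as st
    if pvalues is None:
        pvalues = [2 * st.norm.sf(abs(b / s)) for b, s in zip(betas, ses)]
    table = pd.DataFrame({
        "variant_id": variant_ids,
        "chromosome": chromosomes or ["1"] * k,
        "position": positions or [1_000_000 * (i + 1) for i in range(k)],
        "effect_allele": effect_alleles or ["A"] * k,
        "other_allele": other_alleles or ["G"] * k,
        "eaf": eafs if eafs is not None else [np.nan] * k,
        "beta": betas,
        "se": ses,
        "pvalue": pvalues,
        "n": n if n is not None else [np.nan] * k,
    })[CANONICAL_COLUMNS]
    return SummaryStats(trait_id, table)


def proportional_set(theta=0.5, n=10, sy=0.01, sx=1e-6, seed=0):
    """A harmonized set with by = theta * bx exactly (noiseless oracle data)."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.25, n)
    return HarmonizedSet.from_arrays(bx, np.full(n, sx), theta * bx, np.full(n, sy))


@pytest.fixture
def noiseless():
    return proportional_set()
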