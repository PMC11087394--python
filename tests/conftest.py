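import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrscreen.simulate import SimConfig
from mrscreen.sumstats import SumStatsTable, validate_records

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_table(rows, trait_id="trait", trait_type="quantitative", **kwargs):
    """Build a validated SumStatsTable from a list of row dicts."""
    defaults = {"chrom": "1", "eaf": 0.5, "n": 1000.0}
    full = [{**defaults, **r} for r in rows]
    clean, report = validate_records(pd.DataFrame(full))
    return SumStatsTable(trait_id=trait_id, records=clean, trait_type=trait_type,
                         validation=report, **kwargs)


def snp(variant_id, pval=1e-10, beta=0.2, se=0.02, pos=1_000_000,
        effect_allele="A", other_allele="G", chrom="1", **kw):
    return {"variant_id": variant_id, "chrom": chrom, "pval": pval, "beta": beta,
            "se": se, "pos": pos, "effect_allele": effect_allele,
            "other_allele": other_allele, **kw}


@pytest.fixture
def make_sumstats():
    return make_table


def fast_sim_config(seed, **overrides):
    """Replicate-scale generator settings: 50 strong instruments per trait,
    50 background nulls, trivial LD, no contamination.  Structural effects
    stay at the package defaults (proportion mediated 0.25) unless
    overridden."""
    base = dict(n_null_snps=50, ld_block_size=1, within_block_r2=0.0,
                frac_palindromic=0.0, frac_duplicated=0.0)
    base.update(overrides)
    return SimConfig(seed=seed, **base)


@pytest.fixture
def rng():
    return np.random.default_rng(20240510)
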