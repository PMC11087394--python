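"""Phenome-wide MR scan of one instrument set across many phenotypes.

Each phenotype's summary statistics are harmonized against the exposure's
instruments and fitted by IVW; phenotypes with no harmonizable
instruments appear as explicit *missing* rows rather than vanishing from
the output.  Multiple-testing adjustment reports both Bonferroni (divisor
= number of phenotypes actually tested) and Benjamini-Hochberg columns;
significance tiers are labeled, never filtered, so the caller decides
what to act on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import MRScreenError
from .harmonize import harmonize
from .instruments import InstrumentSet
from .mr import ivw
from .sumstats import SumStatsTable

PHEWAS_COLUMNS = [
    "phenotype_id", "phenotype_category", "status", "reason", "n_snps",
    "method", "beta", "se", "or_", "ci_low", "ci_high", "pval",
    "p_bonferroni", "p_bh", "significant_at",
]


def _tier(p, p_bonf, p_bh, alpha):
    if p_bonf < alpha:
        return "bonferroni"
    if p_bh < alpha:
        return "bh"
    if p < alpha:
        return "nominal"
    return "none"


def phewas_scan(exposure: InstrumentSet, phenotypes: list[SumStatsTable],
                alpha: float = 0.05, mode: str = "multiplicative_random",
                categories: dict | None = None) -> pd.DataFrame:
    """MR of one exposure against a battery of phenotypes.

    Parameters
    ----------
    exposure
        Clumped instrument set for the exposure.
    phenotypes
        One validated summary-statistics table per phenotype; ids are
        opaque labels (e.g. phecode strings).
    alpha
        Significance level for the labeled tiers.
    categories
        Optional phenotype_id -> free-text category mapping from a
        phenotype manifest.

    Returns
    -------
    DataFrame with one row per phenotype (tested or missing), sorted by
    raw p-value with missing rows last.
    """
    if not phenotypes:
        raise ValueError("empty phenotype battery: at least one phenotype table is required")
    categories = categories or {}

    rows = []
    for tab in phenotypes:
        base = {"phenotype_id": tab.trait_id,
                "phenotype_category": categories.get(tab.trait_id, "")}
        try:
            h = harmonize(exposure, tab)
            est = ivw(h, mode)
        except MRScreenError:
            rows.append({**base, "status": "missing",
                         "reason": "no harmonizable instruments"})
            continue
        rows.append({**base, "status": "tested", "reason": "",
                     "n_snps": est.n_snps, "method": est.method,
                     "beta": est.beta, "se": est.se, "or_": est.or_,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "pval": est.pval})

    df = pd.DataFrame(rows).reindex(columns=PHEWAS_COLUMNS)
    df["significant_at"] = df["significant_at"].astype(object)
    tested = df["status"] == "tested"
    m = int(tested.sum())
    if m:
        p = df.loc[tested, "pval"].to_numpy(float)
        df.loc[tested, "p_bonferroni"] = np.minimum(p * m, 1.0)
        df.loc[tested, "p_bh"] = multipletests(p, method="fdr_bh")[1]
        df.loc[tested, "significant_at"] = [
            _tier(pi, bi, hi, alpha)
            for pi, bi, hi in zip(p, df.loc[tested, "p_bonferroni"], df.loc[tested, "p_bh"])]
    df = df.sort_values(["status", "pval"], ascending=[False, True],
                        kind="mergesort", na_position="last").reset_index(drop=True)
    return df
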