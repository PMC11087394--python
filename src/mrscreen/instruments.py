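"""Instrument selection: genome-wide-significant variants pruned by LD clumping.

The relevance assumption of Mendelian randomization requires instruments
that are robustly associated with the exposure; the convention adopted
here is the genome-wide significance threshold p < 5e-8 (strict
inequality) followed by greedy clumping at r² < 0.001 within a 10,000 kb
window, so that retained instruments are approximately independent and
the IVW meta-analysis of their Wald ratios is valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from .sumstats import SumStatsTable, LDMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstrumentConfig:
    """Selection and clumping parameters.

    p_threshold
        Significance cutoff for candidate instruments (strict ``<``).
    clump_r2
        Candidates with r² at or above this value to a better (lower-p)
        index variant are discarded.
    clump_window_kb
        Index-to-candidate distance in kilobases within which the r²
        condition is applied; variants farther apart (or on different
        chromosomes) are always treated as independent.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError(f"clump_r2 must be in [0, 1], got {self.clump_r2}")
        if self.clump_window_kb <= 0:
            raise ValueError(f"clump_window_kb must be positive, got {self.clump_window_kb}")


@dataclass
class InstrumentSet:
    """Clumped genome-wide-significant instruments for one exposure."""

    exposure_id: str
    variants: pd.DataFrame  # canonical sumstats columns, one row per instrument
    config_used: InstrumentConfig = field(default_factory=InstrumentConfig)
    provenance: dict = field(default_factory=dict)  # candidates, removed_by_clumping

    @property
    def n_instruments(self) -> int:
        return len(self.variants)

    def summary(self) -> dict:
        return {"exposure_id": self.exposure_id,
                "n_instruments": self.n_instruments,
                "config": asdict(self.config_used),
                **self.provenance}


def select_candidates(sumstats: SumStatsTable,
                      config: InstrumentConfig | None = None) -> pd.DataFrame:
    """Return records with ``pval < p_threshold`` sorted by ascending p-value.

    Ties on p-value are broken by lexicographic ``variant_id`` so that the
    downstream greedy clump is deterministic under any permutation of the
    input rows.  An empty result is a normal outcome meaning the exposure
    has no usable instruments and must be skipped by the screen.
    """
    config = config or InstrumentConfig()
    rec = sumstats.records
    cand = rec[rec["pval"] < config.p_threshold]
    return (cand.sort_values(["pval", "variant_id"], kind="mergesort")
                .reset_index(drop=True))


def ld_clump(candidates: pd.DataFrame, ld: LDMatrix | None,
             config: InstrumentConfig | None = None,
             exposure_id: str = "") -> InstrumentSet:
    """Greedy LD clumping of significance-sorted candidates.

    Repeatedly takes the lowest-p remaining candidate as an index variant
    and discards every remaining candidate on the same chromosome within
    ``clump_window_kb`` of it whose r² to the index is at or above
    ``clump_r2``.  Candidates absent from the LD matrix are treated as
    uncorrelated with everything (logged); identical variant ids are
    maximally correlated, so exact duplicates collapse onto the best copy.
    """
    config = config or InstrumentConfig()
    cand = (candidates.sort_values(["pval", "variant_id"], kind="mergesort")
                      .reset_index(drop=True))
    n = len(cand)
    if ld is not None:
        absent = [v for v in cand["variant_id"] if v not in ld]
        if absent:
            logger.warning("%d candidate(s) absent from LD matrix; assumed "
                           "uncorrelated with all other variants: %s",
                           len(absent), ", ".join(absent[:5]) + ("..." if len(absent) > 5 else ""))
    else:
        logger.warning("no LD matrix supplied; all candidates assumed mutually uncorrelated")

    ids = cand["variant_id"].tolist()
    chroms = cand["chrom"].tolist()
    pos = cand["pos"].tolist()
    window_bp = config.clump_window_kb * 1000.0

    alive = [True] * n
    kept = []
    for i in range(n):
        if not alive[i]:
            continue
        kept.append(i)
        for j in range(i + 1, n):
            if not alive[j] or chroms[j] != chroms[i]:
                continue
            if abs(pos[j] - pos[i]) > window_bp:
                continue
            r2 = 1.0 if ids[j] == ids[i] else (ld.pairwise(ids[i], ids[j]) if ld is not None else 0.0)
            if r2 >= config.clump_r2:
                alive[j] = False

    retained = cand.iloc[kept].reset_index(drop=True)
    return InstrumentSet(
        exposure_id=exposure_id,
        variants=retained,
        config_used=config,
        provenance={"candidates": n, "removed_by_clumping": n - len(retained)},
    )


def select_instruments(sumstats: SumStatsTable, ld: LDMatrix | None = None,
                       config: InstrumentConfig | None = None) -> InstrumentSet:
    """Significance filter followed by LD clumping, in one call."""
    config = config or InstrumentConfig()
    cand = select_candidates(sumstats, config)
    return ld_clump(cand, ld, config, exposure_id=sumstats.trait_id)
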