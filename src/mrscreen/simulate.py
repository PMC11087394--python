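"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the data a proteome-wide two-sample MR study
consumes: three summary-statistics tables (exposure, mediator, outcome)
drawn from non-overlapping samples over a shared variant grid, plus an LD
matrix.  The structural model is the standard mediation decomposition —
per-SNP true effects are

    exposure:  gamma_j                         (true instruments only)
    mediator:  beta_EM * gamma_j  + delta_k    (delta_k: mediator's own instruments)
    outcome:   beta_direct * gamma_j + beta_MO * (mediator truth)

so the total exposure->outcome effect is beta_direct + beta_EM*beta_MO
and the implied proportion mediated is beta_EM*beta_MO / total.

Observed effects add independent normal noise per table with the standard
per-allele standard-error approximation se = 1/sqrt(2*n*eaf*(1-eaf)),
which yields realistic genome-wide-significance behavior at biobank-scale
sample sizes.  LD is block-diagonal: each true instrument heads a block
of tagging variants whose marginal true effect is sqrt(r2) times the
instrument's, so clumping has real work to do.  Contamination —
palindromic allele pairs and duplicated variant ids — is injected at
configurable rates.

Binary traits are generated directly on the log-odds scale; no
individual-level genotypes are simulated, since the pipeline consumes
only summary statistics.

Reproducibility: one child seed per output stream, derived from the
master seed via ``numpy.random.SeedSequence.spawn`` (children, in order:
variant grid, exposure noise, mediator noise, outcome noise, phenotype
battery).  A fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, SumStatsTable, validate_records

_P_FLOOR = 1e-300

#: Ordered non-palindromic allele pairs, cycled over the variant grid.
_NONPAL_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T"), ("C", "A"), ("T", "G")]
_PAL_PAIRS = [("A", "T"), ("C", "G"), ("T", "A"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults describe a biobank-scale mediation scenario: 50 strong pQTL
    instruments for the exposure (per-allele effects 0.3-0.8 SD at a
    protein-GWAS sample size of 3300), mediator and outcome GWAS at UK
    Biobank scale, and structural effects beta_EM = -0.02,
    beta_MO = 1.5, beta_direct = -0.09, implying a total effect of -0.12
    and a true proportion mediated of 0.25.
    """

    n_instruments: int = 50
    n_mediator_instruments: int = 50
    n_null_snps: int = 450
    instrument_effect_range: tuple = (0.3, 0.8)  # magnitude; sign is random
    n_exposure: int = 3_300
    n_mediator: int = 450_000
    n_outcome: int = 350_000
    beta_EM_true: float = -0.02
    beta_MO_true: float = 1.5
    beta_direct_true: float = -0.09
    ld_block_size: int = 5
    within_block_r2: float = 0.3
    frac_palindromic: float = 0.04
    frac_duplicated: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_palindromic", "frac_duplicated"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        if self.n_mediator_instruments < 0 or self.n_null_snps < 0:
            raise ValueError("variant counts must be non-negative")
        lo, hi = self.instrument_effect_range
        if not (0 < lo <= hi):
            raise ValueError("instrument_effect_range must satisfy 0 < lo <= hi")
        if not (0 <= self.within_block_r2 < 1):
            raise ValueError("within_block_r2 must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.ld_block_size > self.n_variants:
            raise ValueError(
                f"ld_block_size ({self.ld_block_size}) exceeds the variant count ({self.n_variants})")

    @property
    def n_variants(self) -> int:
        return self.n_instruments + self.n_mediator_instruments + self.n_null_snps

    @property
    def beta_total_true(self) -> float:
        return self.beta_direct_true + self.beta_EM_true * self.beta_MO_true

    @property
    def proportion_mediated_true(self) -> float:
        total = self.beta_total_true
        if total == 0:
            return float("nan")
        return self.beta_EM_true * self.beta_MO_true / total


@dataclass
class TripletTruth:
    """Ground truth carried alongside a simulated triplet."""

    beta_EM: float
    beta_MO: float
    beta_direct: float
    beta_total: float
    proportion_mediated: float
    exposure_instrument_ids: list
    mediator_instrument_ids: list
    palindromic_ids: list
    duplicated_ids: list
    per_variant: pd.DataFrame = field(repr=False, default=None)

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "per_variant"}
        return json.dumps(d, indent=2)


class _Grid:
    """Variant grid shared by the three tables of a triplet."""

    __slots__ = ("ids", "chrom", "pos", "ea", "oa", "eaf", "g_exp", "d_med",
                 "block", "exposure_instr", "mediator_instr",
                 "palindromic_ids", "duplicated_idx", "ld")

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        n = cfg.n_variants
        lo, hi = cfg.instrument_effect_range
        gamma = rng.uniform(lo, hi, cfg.n_instruments) * rng.choice([-1.0, 1.0], cfg.n_instruments)
        delta = rng.uniform(lo, hi, cfg.n_mediator_instruments) * rng.choice([-1.0, 1.0], cfg.n_mediator_instruments)
        eaf = rng.uniform(0.1, 0.9, n)

        # layout: each instrument heads a block, padded with tagging nulls;
        # leftover nulls form effect-free blocks of their own
        g_exp = np.zeros(n)
        d_med = np.zeros(n)
        block = np.zeros(n, dtype=int)
        kind = np.empty(n, dtype=object)
        tag = np.sqrt(cfg.within_block_r2)
        idx = 0
        b = 0
        nulls_left = cfg.n_null_snps

        def start_block(effects, vec, label):
            nonlocal idx, b, nulls_left
            for eff in effects:
                vec[idx] = eff
                block[idx] = b
                kind[idx] = label
                idx += 1
                pad = min(cfg.ld_block_size - 1, nulls_left)
                for _ in range(pad):
                    vec[idx] = tag * eff
                    block[idx] = b
                    kind[idx] = "tag"
                    idx += 1
                nulls_left -= pad
                b += 1

        start_block(gamma, g_exp, "exposure_instrument")
        start_block(delta, d_med, "mediator_instrument")
        while nulls_left > 0:
            take = min(cfg.ld_block_size, nulls_left)
            for _ in range(take):
                block[idx] = b
                kind[idx] = "null"
                idx += 1
            nulls_left -= take
            b += 1
        assert idx == n

        self.ids = np.array([f"rs{i:06d}" for i in range(n)])
        self.g_exp, self.d_med, self.block, self.eaf = g_exp, d_med, block, eaf
        self.exposure_instr = [self.ids[i] for i in range(n) if kind[i] == "exposure_instrument"]
        self.mediator_instr = [self.ids[i] for i in range(n) if kind[i] == "mediator_instrument"]

        # positions: blocks spread round-robin over 22 autosomes, 20 Mb
        # between block starts on a chromosome, 5 kb between block members
        chrom = np.empty(n, dtype=object)
        pos = np.zeros(n, dtype=np.int64)
        member = 0
        for i in range(n):
            member = 0 if (i == 0 or block[i] != block[i - 1]) else member + 1
            chrom[i] = str(block[i] % 22 + 1)
            pos[i] = 1_000_000 + (block[i] // 22) * 20_000_000 + 5_000 * member
        self.chrom, self.pos = chrom, pos

        # alleles: palindromic contamination gets A/T or C/G pairs
        n_pal = round(cfg.frac_palindromic * n)
        pal_idx = rng.choice(n, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
        ea = np.empty(n, dtype=object)
        oa = np.empty(n, dtype=object)
        for i in range(n):
            ea[i], oa[i] = _NONPAL_PAIRS[i % len(_NONPAL_PAIRS)]
        for k, i in enumerate(np.sort(pal_idx)):
            ea[i], oa[i] = _PAL_PAIRS[k % len(_PAL_PAIRS)]
        self.ea, self.oa = ea, oa
        self.palindromic_ids = sorted(self.ids[i] for i in pal_idx)

        n_dup = round(cfg.frac_duplicated * n)
        dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
        self.duplicated_idx = np.sort(dup_idx)

        # block-diagonal LD matrix
        r2 = np.eye(n)
        for blk in np.unique(block):
            members = np.where(block == blk)[0]
            if len(members) > 1:
                ix = np.ix_(members, members)
                sub = np.full((len(members), len(members)), cfg.within_block_r2)
                np.fill_diagonal(sub, 1.0)
                r2[ix] = sub
        self.ld = LDMatrix(list(self.ids), r2, self.pos.copy())


def _build_grid(cfg: SimConfig, grid_seed) -> _Grid:
    return _Grid(cfg, np.random.default_rng(grid_seed))


def _draw_table(grid: _Grid, truth_vec: np.ndarray, n_sample: int,
                trait_id: str, trait_type: str, sample_label: str,
                rng: np.random.Generator) -> SumStatsTable:
    se = 1.0 / np.sqrt(2.0 * n_sample * grid.eaf * (1.0 - grid.eaf))
    beta = truth_vec + rng.normal(0.0, se)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _P_FLOOR, 1.0)
    df = pd.DataFrame({
        "variant_id": grid.ids, "chrom": grid.chrom, "pos": grid.pos,
        "effect_allele": grid.ea, "other_allele": grid.oa,
        "eaf": grid.eaf, "beta": beta, "se": se, "pval": pval,
        "n": float(n_sample),
    })
    if len(grid.duplicated_idx):
        df = pd.concat([df, df.iloc[grid.duplicated_idx]], ignore_index=True)
    clean, report = validate_records(df)
    return SumStatsTable(trait_id=trait_id, records=clean, trait_type=trait_type,
                         sample_label=sample_label, validation=report)


def simulate_triplet(cfg: SimConfig) -> tuple[SumStatsTable, SumStatsTable,
                                              SumStatsTable, LDMatrix, TripletTruth]:
    """Generate (exposure, mediator, outcome) tables, LD, and ground truth."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    grid = _build_grid(cfg, seeds[0])

    truth_exp = grid.g_exp
    truth_med = cfg.beta_EM_true * grid.g_exp + grid.d_med
    truth_out = cfg.beta_direct_true * grid.g_exp + cfg.beta_MO_true * truth_med

    exposure = _draw_table(grid, truth_exp, cfg.n_exposure, "exposure",
                           "quantitative", "exposure_gwas", np.random.default_rng(seeds[1]))
    mediator = _draw_table(grid, truth_med, cfg.n_mediator, "mediator",
                           "quantitative", "mediator_gwas", np.random.default_rng(seeds[2]))
    outcome = _draw_table(grid, truth_out, cfg.n_outcome, "outcome",
                          "binary", "outcome_gwas", np.random.default_rng(seeds[3]))

    per_variant = pd.DataFrame({
        "variant_id": grid.ids,
        "true_beta_exposure": truth_exp,
        "true_beta_mediator": truth_med,
        "true_beta_outcome": truth_out,
    })
    truth = TripletTruth(
        beta_EM=cfg.beta_EM_true, beta_MO=cfg.beta_MO_true,
        beta_direct=cfg.beta_direct_true, beta_total=cfg.beta_total_true,
        proportion_mediated=cfg.proportion_mediated_true,
        exposure_instrument_ids=list(grid.exposure_instr),
        mediator_instrument_ids=list(grid.mediator_instr),
        palindromic_ids=list(grid.palindromic_ids),
        duplicated_ids=sorted(grid.ids[i] for i in grid.duplicated_idx),
        per_variant=per_variant,
    )
    return exposure, mediator, outcome, grid.ld, truth


def simulate_phenotype_battery(cfg: SimConfig, n_phenotypes: int,
                               frac_truly_associated: float,
                               phenotype_effect: float = 0.1
                               ) -> tuple[list[SumStatsTable], dict]:
    """Phenotype battery over the exposure's variant grid, for PheWAS tests.

    ``round(frac_truly_associated * n_phenotypes)`` phenotypes receive a
    true causal effect ``phenotype_effect`` of the exposure (per-SNP truth
    ``phenotype_effect * gamma_j``); the rest are exact nulls.  Phenotype
    sample size is ``cfg.n_outcome``.  Returns the tables plus a truth
    record naming the associated phenotypes.
    """
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    if not (0 <= frac_truly_associated <= 1):
        raise ValueError("frac_truly_associated must be in [0, 1]")
    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    grid = _build_grid(cfg, seeds[0])
    battery_seeds = seeds[4].spawn(n_phenotypes + 1)
    rng_pick = np.random.default_rng(battery_seeds[0])

    n_assoc = round(frac_truly_associated * n_phenotypes)
    assoc = set(rng_pick.choice(n_phenotypes, size=n_assoc, replace=False).tolist()) if n_assoc else set()

    tables = []
    for i in range(n_phenotypes):
        truth_vec = phenotype_effect * grid.g_exp if i in assoc else np.zeros(cfg.n_variants)
        tables.append(_draw_table(grid, truth_vec, cfg.n_outcome,
                                  f"pheno_{i:04d}", "binary", "phenotype_gwas",
                                  np.random.default_rng(battery_seeds[i + 1])))
    truth = {
        "n_phenotypes": n_phenotypes,
        "associated_ids": sorted(f"pheno_{i:04d}" for i in assoc),
        "phenotype_effect": phenotype_effect,
    }
    return tables, truth
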