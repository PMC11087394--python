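"""Allele harmonization of exposure instruments against outcome statistics.

Two-sample MR multiplies effects estimated in different GWAS, so the
per-variant exposure and outcome effects must refer to the same allele.
This module inner-joins the two sources on variant id and then, per
variant:

* identical allele pairs are kept as-is;
* swapped pairs (effect and other allele exchanged) keep the variant with
  the outcome beta negated;
* strand-complement pairs (A<->T, C<->G applied to both alleles) are
  complemented first and then resolved as above;
* palindromic variants (allele set {A,T} or {C,G}) are excluded
  unconditionally — their strand orientation is unresolvable from
  summary data;
* allele sets irreconcilable even after complementing are dropped as
  incompatible;
* a variant id appearing more than once in either source is dropped
  entirely (every copy), as are ids absent from the outcome.

Every drop is recorded in an audit table with its reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoHarmonizableInstrumentsError
from .instruments import InstrumentSet
from .sumstats import SumStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Retained-row columns of a harmonized table.
HARMONIZED_COLUMNS = [
    "variant_id", "effect_allele", "other_allele",
    "beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "action",
]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonizedTable:
    """Exposure/outcome rows aligned to a shared effect allele."""

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame  # HARMONIZED_COLUMNS
    audit: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"]))

    @property
    def n_snps(self) -> int:
        return len(self.rows)

    def write_audit(self, path) -> None:
        """Tab-delimited drop report: variant_id, reason."""
        self.audit.to_csv(path, sep="\t", index=False)


def harmonize(exposure_instruments: InstrumentSet, outcome: SumStatsTable,
              *, allow_empty: bool = False) -> HarmonizedTable:
    """Align outcome effects onto the exposure's effect alleles.

    Raises
    ------
    NoHarmonizableInstrumentsError
        If zero variants survive (unless ``allow_empty=True``); batch
        screens catch this per exposure and report it rather than abort.
    """
    exp = exposure_instruments.variants
    out = outcome.records
    audit: list[tuple[str, str]] = []

    exp_dup = set(exp["variant_id"][exp["variant_id"].duplicated(keep=False)])
    out_dup = set(out["variant_id"][out["variant_id"].duplicated(keep=False)])
    dup = exp_dup | out_dup
    for vid in sorted(dup & set(exp["variant_id"])):
        audit.append((vid, "dropped_duplicate"))

    exp_u = exp[~exp["variant_id"].isin(dup)]
    out_u = out[~out["variant_id"].isin(dup)]

    merged = exp_u.merge(out_u, on="variant_id", suffixes=("_exp", "_out"), how="left")
    absent = merged["beta_out"].isna()
    for vid in merged.loc[absent, "variant_id"]:
        audit.append((vid, "absent_from_outcome"))
    merged = merged[~absent]

    kept_rows = []
    for row in merged.itertuples(index=False):
        ea_e, oa_e = row.effect_allele_exp, row.other_allele_exp
        ea_o, oa_o = row.effect_allele_out, row.other_allele_out
        if is_palindromic(ea_e, oa_e) or is_palindromic(ea_o, oa_o):
            audit.append((row.variant_id, "dropped_palindromic"))
            continue
        # try direct orientation, then the strand complement of the outcome
        if {ea_o, oa_o} != {ea_e, oa_e}:
            ea_o, oa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
        if (ea_o, oa_o) == (ea_e, oa_e):
            beta_out, action = row.beta_out, "none"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out, action = -row.beta_out, "outcome_sign_flipped"
        else:
            audit.append((row.variant_id, "dropped_incompatible"))
            continue
        kept_rows.append((row.variant_id, ea_e, oa_e,
                          row.beta_exp, row.se_exp, beta_out, row.se_out, action))

    rows = pd.DataFrame(kept_rows, columns=HARMONIZED_COLUMNS)
    audit_df = pd.DataFrame(audit, columns=["variant_id", "reason"])
    table = HarmonizedTable(
        exposure_id=exposure_instruments.exposure_id,
        outcome_id=outcome.trait_id,
        rows=rows,
        audit=audit_df,
    )
    if table.n_snps == 0 and not allow_empty:
        raise NoHarmonizableInstrumentsError(
            f"no harmonizable instruments for exposure "
            f"{exposure_instruments.exposure_id!r} on outcome {outcome.trait_id!r}")
    return table


def harmonized_from_arrays(beta_exposure, se_exposure, beta_outcome, se_outcome,
                           exposure_id: str = "exposure",
                           outcome_id: str = "outcome") -> HarmonizedTable:
    """Build a HarmonizedTable directly from effect arrays (already aligned).

    Convenience constructor for estimator-level work where allele
    bookkeeping has been handled elsewhere.
    """
    n = len(np.asarray(beta_exposure))
    rows = pd.DataFrame({
        "variant_id": [f"snp{i}" for i in range(n)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exposure": np.asarray(beta_exposure, dtype=float),
        "se_exposure": np.asarray(se_exposure, dtype=float),
        "beta_outcome": np.asarray(beta_outcome, dtype=float),
        "se_outcome": np.asarray(se_outcome, dtype=float),
        "action": "none",
    })
    return HarmonizedTable(exposure_id, outcome_id, rows)
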