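"""Reading, validating and writing GWAS summary statistics and LD matrices.

This module is the single source of truth for variant identity and allele
conventions used by the rest of the package:

* one row per biallelic SNP: identifier, chromosome, 1-based position,
  effect allele, other allele, effect-allele frequency, per-allele effect
  (log-odds for binary traits), standard error, two-sided p-value, sample
  size;
* alleles are single bases A/C/G/T, normalized to uppercase; indels and
  multi-allelic records are rejected;
* missing values are encoded as ``NA`` on disk; only ``eaf`` and ``n`` may
  be missing;
* duplicated variant identifiers are *flagged* during validation but kept
  in the table — the harmonization stage removes every copy, mirroring the
  convention that ambiguous or duplicated SNPs are excluded from analysis.

Files are plain tab- (or comma-) delimited text with a header; a *dialect*
maps arbitrary header names onto the canonical column set so that summary
files from different providers can be ingested without rewriting them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SumStatsFormatError

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: Columns that must be present and non-missing in every retained row.
MANDATORY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval",
]

#: Default header dialect: canonical names map to themselves.
DEFAULT_DIALECT = {c: c for c in CANONICAL_COLUMNS}

VALID_ALLELES = frozenset("ACGT")

_NUMERIC_COLUMNS = ["pos", "eaf", "beta", "se", "pval", "n"]
_STRING_COLUMNS = ["variant_id", "chrom", "effect_allele", "other_allele"]


@dataclass
class ValidationReport:
    """Accounting of what validation did to a raw table."""

    n_input: int = 0
    n_retained: int = 0
    dropped: dict = field(default_factory=dict)  # reason -> count
    duplicated_ids: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SumStatsTable:
    """Validated per-variant association records for one trait in one sample.

    ``records`` is a :class:`pandas.DataFrame` with the canonical columns.
    ``sample_label`` exists purely for two-sample bookkeeping: exposure and
    outcome statistics must come from non-overlapping samples for the
    two-sample MR design to hold, and the label lets pipelines assert that.
    """

    trait_id: str
    records: pd.DataFrame
    trait_type: str = "quantitative"  # "binary" | "quantitative"
    sample_label: str = ""
    validation: ValidationReport | None = None

    def __post_init__(self):
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise SumStatsFormatError(f"records missing canonical column(s): {missing}")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def duplicated_variant_ids(self) -> list:
        ids = self.records["variant_id"]
        return sorted(ids[ids.duplicated(keep=False)].unique())


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _STRING_COLUMNS:
        out[col] = out[col].astype("string").str.strip()
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].str.upper()
    for col in _NUMERIC_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Normalize and filter raw records against the per-variant invariants.

    Rows violating any invariant are dropped and counted by the first
    reason that applies; the surviving frame is returned with canonical
    column order and dtypes.  Validation is idempotent: re-validating a
    clean table drops nothing.
    """
    report = ValidationReport(n_input=len(df))
    if len(df) == 0:
        clean = df.reindex(columns=CANONICAL_COLUMNS)
        report.n_retained = 0
        return _coerce_types(clean), report

    work = _coerce_types(df.reindex(columns=CANONICAL_COLUMNS))

    reasons = pd.Series("", index=work.index, dtype=object)

    def flag(mask, reason):
        mask = pd.Series(mask, index=work.index).fillna(False).astype(bool)
        mask &= reasons == ""
        reasons[mask] = reason

    mand = work[MANDATORY_COLUMNS]
    flag(mand.isna().any(axis=1) | (work["variant_id"] == ""), "missing_mandatory_field")
    flag(~(work["effect_allele"].isin(list(VALID_ALLELES))
           & work["other_allele"].isin(list(VALID_ALLELES))), "invalid_allele")
    flag(work["effect_allele"] == work["other_allele"], "identical_alleles")
    flag(work["pos"] < 1, "invalid_position")
    flag(work["se"] <= 0, "invalid_se")
    flag((work["pval"] <= 0) | (work["pval"] > 1), "invalid_pval")
    flag(work["eaf"].notna() & ((work["eaf"] < 0) | (work["eaf"] > 1)), "invalid_eaf")
    flag(work["n"].notna() & (work["n"] <= 0), "invalid_n")

    bad = reasons != ""
    for reason, count in reasons[bad].value_counts().items():
        report.dropped[reason] = int(count)

    clean = work[~bad].reset_index(drop=True)
    clean["pos"] = clean["pos"].astype(np.int64)
    report.n_retained = len(clean)

    dup_ids = clean["variant_id"][clean["variant_id"].duplicated(keep=False)]
    report.duplicated_ids = sorted(dup_ids.unique())
    if report.duplicated_ids:
        logger.warning("table contains %d duplicated variant_id(s); "
                       "harmonization will remove every copy", len(report.duplicated_ids))
    return clean, report


def read_sumstats(path, dialect: dict | None = None, *, trait_id: str | None = None,
                  trait_type: str = "quantitative", sample_label: str = "") -> SumStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    dialect
        Mapping from canonical field name to the header name used in the
        file; defaults to the canonical names themselves.  ``eaf`` and
        ``n`` may be omitted from the mapping (treated as missing).

    Raises
    ------
    SumStatsFormatError
        If the file is empty or a mandatory column is absent.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    import csv
    try:
        raw = pd.read_csv(path, sep=None, engine="python",
                          na_values=["NA"], keep_default_na=True, dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        raise SumStatsFormatError(f"empty or undelimited summary-statistics file: {path}") from None

    renames = {}
    for canonical, header in dialect.items():
        if header in raw.columns:
            renames[header] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise SumStatsFormatError(
                f"mandatory column {canonical!r} (header {header!r}) absent from {path}")
    for canonical in MANDATORY_COLUMNS:
        if canonical not in dialect:
            raise SumStatsFormatError(f"dialect does not map mandatory column {canonical!r}")
    df = raw.rename(columns=renames).reindex(columns=CANONICAL_COLUMNS)

    clean, report = validate_records(df)
    return SumStatsTable(trait_id=trait_id or str(path), records=clean,
                         trait_type=trait_type, sample_label=sample_label,
                         validation=report)


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table as tab-delimited text with the canonical header.

    Missing ``eaf``/``n`` are encoded as ``NA``.  Floats are written at
    round-trip precision, so ``read_sumstats(write_sumstats(t))`` equals
    ``t`` field for field.
    """
    table.records.reindex(columns=CANONICAL_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------

class LDMatrix:
    """Squared-correlation (r²) matrix over a set of variants.

    Symmetric, unit diagonal, entries in [0, 1].  Lookups for variants not
    present in the matrix return 0 (treated as uncorrelated) — callers that
    care, such as the clumping stage, log that assumption.
    """

    def __init__(self, variant_ids, r2, positions=None):
        self.variant_ids = list(variant_ids)
        self.r2 = np.asarray(r2, dtype=float)
        self.positions = None if positions is None else np.asarray(positions)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        self._validate()

    def _validate(self, tol: float = 1e-8):
        m = self.r2
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise SumStatsFormatError(f"LD matrix is not square: shape {m.shape}")
        if len(self.variant_ids) != m.shape[0]:
            raise SumStatsFormatError(
                f"LD id/row-count mismatch: {len(self.variant_ids)} ids, {m.shape[0]} rows")
        if len(self._index) != len(self.variant_ids):
            raise SumStatsFormatError("LD matrix has duplicated variant ids")
        if np.any(m < -tol) or np.any(m > 1 + tol):
            raise SumStatsFormatError("LD r2 out of range [0, 1]")
        if np.any(np.abs(m - m.T) > tol):
            raise SumStatsFormatError("LD matrix asymmetric beyond tolerance 1e-8")
        if np.any(np.abs(np.diag(m) - 1.0) > tol):
            raise SumStatsFormatError("LD matrix diagonal is not 1")
        # canonicalize: exact symmetry, exact unit diagonal, clipped range
        m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(m, 1.0)
        self.r2 = m
        if self.positions is not None and len(self.positions) != len(self.variant_ids):
            raise SumStatsFormatError("LD positions length does not match ids")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id) -> bool:
        return variant_id in self._index

    def pairwise(self, a: str, b: str) -> float:
        """r² between two variants; identical ids give 1, unknown ids give 0."""
        if a == b:
            return 1.0
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


def identity_ld(variant_ids, positions=None) -> LDMatrix:
    """An LD matrix with no correlation between distinct variants."""
    return LDMatrix(variant_ids, np.eye(len(list(variant_ids))), positions)


def load_ld(path, ids_path=None) -> LDMatrix:
    """Load an LD matrix from disk.

    Two on-disk layouts are supported:

    * dense: a tab-delimited square numeric matrix at ``path`` plus a
      one-column id file at ``ids_path`` (one variant id per line);
    * long: a three-column header file ``id1<TAB>id2<TAB>r2`` at ``path``
      (``ids_path`` omitted); unlisted pairs default to r² = 0.
    """
    if ids_path is not None:
        with open(ids_path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        try:
            mat = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise SumStatsFormatError(f"unreadable dense LD matrix {path}: {exc}") from None
        return LDMatrix(ids, mat)

    df = pd.read_csv(path, sep=None, engine="python")
    expected = ["id1", "id2", "r2"]
    if list(df.columns[:3]) != expected:
        raise SumStatsFormatError(
            f"long-format LD file must have header {expected}, got {list(df.columns)}")
    ids = list(dict.fromkeys(pd.concat([df["id1"], df["id2"]]).astype(str)))
    index = {v: i for i, v in enumerate(ids)}
    mat = np.eye(len(ids))
    for a, b, r2 in zip(df["id1"].astype(str), df["id2"].astype(str),
                        pd.to_numeric(df["r2"], errors="raise")):
        i, j = index[a], index[b]
        if i != j:
            prev = mat[i, j]
            if prev not in (0.0, 1.0) and abs(prev - r2) > 1e-8:
                raise SumStatsFormatError(f"conflicting r2 entries for pair ({a}, {b})")
            mat[i, j] = mat[j, i] = r2
    return LDMatrix(ids, mat)


def write_ld(ld: LDMatrix, matrix_path, ids_path) -> None:
    """Write a dense LD matrix plus its id list."""
    np.savetxt(matrix_path, ld.r2, delimiter="\t", fmt="%.10g")
    with open(ids_path, "w") as fh:
        fh.write("\n".join(ld.variant_ids) + "\n")
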