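"""Batch drivers for the four analyses: screen, risk-factor MR, mediation, PheWAS.

Each driver takes validated in-memory tables, loops over its work items
with row-level error containment (an exposure that cannot be analyzed is
counted and reported, never aborts the batch), and returns a results
DataFrame plus a machine-readable run manifest.  File-based wrappers
read the tab-delimited formats defined in :mod:`mrscreen.sumstats`,
record input checksums in the manifest, and write the outputs; the CLI
is a thin layer over those wrappers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .errors import ConfigError, MediationLegError, MRScreenError
from .harmonize import harmonize
from .instruments import InstrumentConfig, select_candidates, ld_clump, select_instruments
from .mediation import MediationInput, indirect_effect, mediate
from .mr import ivw, sensitivity
from .phewas import phewas_scan
from .sumstats import LDMatrix, SumStatsTable, load_ld, read_sumstats

SCREEN_COLUMNS = [
    "exposure", "outcome", "n_snps", "method", "beta", "se", "or",
    "ci_low", "ci_high", "pval", "p_bonferroni", "p_bh",
    "q_pval", "egger_intercept_pval",
]

MEDIATION_COLUMNS = [
    "exposure", "mediator", "outcome",
    "beta_EM", "se_EM", "beta_MO", "se_MO", "beta_EO", "se_EO",
    "indirect_beta", "indirect_se", "indirect_ci_low", "indirect_ci_high",
    "indirect_pval", "direct_beta", "proportion_mediated",
    "proportion_mediated_pct", "sign_discordant", "error",
]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _base_manifest(config_snapshot: dict) -> dict:
    return {"package": "mrscreen", "version": __version__,
            "config": config_snapshot, "input_checksums": {}}


def run_screen(exposures: list[SumStatsTable], outcome: SumStatsTable,
               ld: LDMatrix | None = None,
               config: InstrumentConfig | None = None,
               mode: str = "multiplicative_random",
               alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """IVW screen of many exposures against one outcome.

    Per exposure: significance filter -> LD clump -> harmonize -> IVW with
    the sensitivity battery.  Exposures with zero genome-wide-significant
    SNPs, or none harmonizable, are skipped and counted in the manifest.
    Bonferroni and Benjamini-Hochberg columns are computed over the
    exposures actually tested; neither filters the output.
    """
    config = config or InstrumentConfig()
    manifest = _base_manifest({"instruments": asdict(config), "mode": mode, "alpha": alpha})
    counts = {"exposures_attempted": len(exposures), "skipped_no_instruments": 0,
              "skipped_no_harmonizable": 0, "tested": 0, "significant_nominal": 0}
    rows = []
    for exp in exposures:
        cand = select_candidates(exp, config)
        if len(cand) == 0:
            counts["skipped_no_instruments"] += 1
            continue
        instruments = ld_clump(cand, ld, config, exposure_id=exp.trait_id)
        try:
            h = harmonize(instruments, outcome)
        except MRScreenError:
            counts["skipped_no_harmonizable"] += 1
            continue
        est = ivw(h, mode)
        sens = sensitivity(h, est, mode)
        rows.append({"exposure": exp.trait_id, "outcome": outcome.trait_id,
                     "n_snps": est.n_snps, "method": est.method,
                     "beta": est.beta, "se": est.se, "or": est.or_,
                     "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
                     "q_pval": sens.q_pval,
                     "egger_intercept_pval": sens.egger_intercept_pval})
    df = pd.DataFrame(rows).reindex(columns=SCREEN_COLUMNS)
    if len(df):
        p = df["pval"].to_numpy(float)
        df["p_bonferroni"] = np.minimum(p * len(p), 1.0)
        df["p_bh"] = multipletests(p, method="fdr_bh")[1]
        df = df.sort_values("pval", kind="mergesort").reset_index(drop=True)
        counts["significant_nominal"] = int((p < alpha).sum())
    counts["tested"] = len(df)
    manifest["counts"] = counts
    return df, manifest


def run_mediation(triples: list[dict],
                  ld: LDMatrix | None = None,
                  config: InstrumentConfig | None = None,
                  mode: str = "multiplicative_random") -> tuple[pd.DataFrame, dict]:
    """Two-step MR mediation over (exposure, mediator, outcome) triples.

    Each triple is a dict with ``exposure``, ``mediator`` and ``outcome``
    SumStatsTables.  A failing MR leg produces a row-level error entry;
    the run continues.
    """
    config = config or InstrumentConfig()
    manifest = _base_manifest({"instruments": asdict(config), "mode": mode})
    rows = []
    n_failed = 0
    for triple in triples:
        exp, med, out = triple["exposure"], triple["mediator"], triple["outcome"]
        base = {"exposure": exp.trait_id, "mediator": med.trait_id, "outcome": out.trait_id}
        try:
            exp_instr = select_instruments(exp, ld, config)
            med_instr = select_instruments(med, ld, config)
            res = mediate(exp_instr, med, out, med_instr, mode)
        except MRScreenError as exc:
            n_failed += 1
            leg = exc.leg if isinstance(exc, MediationLegError) else ""
            rows.append({**base, "error": f"{leg}: {exc}" if leg else str(exc)})
            continue
        em = res.components["exposure->mediator"]
        mo = res.components["mediator->outcome"]
        eo = res.components["exposure->outcome"]
        rows.append({**base,
                     "beta_EM": em.beta, "se_EM": em.se,
                     "beta_MO": mo.beta, "se_MO": mo.se,
                     "beta_EO": eo.beta, "se_EO": eo.se,
                     "indirect_beta": res.indirect_beta, "indirect_se": res.indirect_se,
                     "indirect_ci_low": res.indirect_ci_low,
                     "indirect_ci_high": res.indirect_ci_high,
                     "indirect_pval": res.indirect_pval, "direct_beta": res.direct_beta,
                     "proportion_mediated": res.proportion_mediated,
                     "proportion_mediated_pct": res.proportion_mediated_pct,
                     "sign_discordant": res.sign_discordant, "error": ""})
    df = pd.DataFrame(rows).reindex(columns=MEDIATION_COLUMNS)
    manifest["counts"] = {"triples_attempted": len(triples), "failed": n_failed,
                          "completed": len(triples) - n_failed}
    return df, manifest


def run_mediation_replay(estimates: list[dict]) -> tuple[pd.DataFrame, dict]:
    """Mediation from user-supplied effect estimates, bypassing the MR legs.

    Each entry carries ``beta_EM``/``beta_MO``/``beta_EO`` (log-odds or
    linear effects, e.g. the log of published ORs) and, optionally, their
    standard errors; without SEs only the point decomposition and the
    proportion mediated are reported.
    """
    manifest = _base_manifest({"replay": True})
    rows = []
    for est in estimates:
        base = {"exposure": est.get("exposure", ""), "mediator": est.get("mediator", ""),
                "outcome": est.get("outcome", "")}
        b_em, b_mo, b_eo = est["beta_EM"], est["beta_MO"], est["beta_EO"]
        has_se = all(est.get(k) is not None for k in ("se_EM", "se_MO", "se_EO"))
        if has_se:
            res = indirect_effect(MediationInput(
                beta_EM=b_em, se_EM=est["se_EM"], beta_MO=b_mo, se_MO=est["se_MO"],
                beta_EO=b_eo, se_EO=est["se_EO"]))
            rows.append({**base, "beta_EM": b_em, "se_EM": est["se_EM"],
                         "beta_MO": b_mo, "se_MO": est["se_MO"],
                         "beta_EO": b_eo, "se_EO": est["se_EO"],
                         "indirect_beta": res.indirect_beta, "indirect_se": res.indirect_se,
                         "indirect_ci_low": res.indirect_ci_low,
                         "indirect_ci_high": res.indirect_ci_high,
                         "indirect_pval": res.indirect_pval,
                         "direct_beta": res.direct_beta,
                         "proportion_mediated": res.proportion_mediated,
                         "proportion_mediated_pct": res.proportion_mediated_pct,
                         "sign_discordant": res.sign_discordant, "error": ""})
        else:
            indirect = b_em * b_mo
            prop = indirect / b_eo if b_eo != 0 else float("nan")
            rows.append({**base, "beta_EM": b_em, "beta_MO": b_mo, "beta_EO": b_eo,
                         "indirect_beta": indirect, "direct_beta": b_eo - indirect,
                         "proportion_mediated": prop,
                         "proportion_mediated_pct": 100.0 * prop,
                         "sign_discordant": b_eo != 0 and indirect != 0
                                            and (indirect > 0) != (b_eo > 0),
                         "error": ""})
    df = pd.DataFrame(rows).reindex(columns=MEDIATION_COLUMNS)
    manifest["counts"] = {"triples_attempted": len(estimates), "failed": 0,
                          "completed": len(estimates)}
    return df, manifest


def run_phewas(exposure: SumStatsTable, phenotypes: list[SumStatsTable],
               ld: LDMatrix | None = None,
               config: InstrumentConfig | None = None,
               alpha: float = 0.05, mode: str = "multiplicative_random",
               categories: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Multi-outcome MR scan of one exposure's instruments."""
    config = config or InstrumentConfig()
    manifest = _base_manifest({"instruments": asdict(config), "alpha": alpha, "mode": mode})
    instruments = select_instruments(exposure, ld, config)
    df = phewas_scan(instruments, phenotypes, alpha=alpha, mode=mode, categories=categories)
    manifest["counts"] = {
        "phenotypes": len(phenotypes),
        "tested": int((df["status"] == "tested").sum()),
        "missing": int((df["status"] == "missing").sum()),
        "instruments": instruments.n_instruments,
    }
    return df, manifest


# ---------------------------------------------------------------------------
# File-based orchestration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"configuration {path} is not a mapping")
    return cfg


def instrument_config_from(cfg: dict) -> InstrumentConfig:
    block = cfg.get("instruments", {}) or {}
    unknown = set(block) - {"p_threshold", "clump_r2", "clump_window_kb"}
    if unknown:
        raise ConfigError(f"unknown instrument option(s): {sorted(unknown)}")
    try:
        return InstrumentConfig(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _load_ld_block(cfg: dict) -> LDMatrix | None:
    ld_block = cfg.get("ld")
    if not ld_block:
        return None
    return load_ld(ld_block["matrix"], ld_block.get("ids"))


def _read_entry(entry, trait_type="quantitative") -> SumStatsTable:
    if isinstance(entry, str):
        return read_sumstats(entry, trait_type=trait_type)
    tab = read_sumstats(entry["path"], dialect=entry.get("dialect"),
                        trait_id=entry.get("id"),
                        trait_type=entry.get("trait_type", trait_type))
    return tab


def run_screen_files(cfg: dict, outdir) -> tuple[pd.DataFrame, dict]:
    """File-based screen: reads config-listed tables, writes results + manifest."""
    screen_cfg = cfg.get("screen")
    if not screen_cfg or "exposures" not in screen_cfg or "outcome" not in screen_cfg:
        raise ConfigError("screen config must list 'exposures' and exactly one 'outcome'")
    exposures = [_read_entry(e) for e in screen_cfg["exposures"]]
    outcome = _read_entry(screen_cfg["outcome"], trait_type="binary")
    ld = _load_ld_block(screen_cfg)
    df, manifest = run_screen(exposures, outcome, ld, instrument_config_from(cfg),
                              mode=cfg.get("mode", "multiplicative_random"),
                              alpha=cfg.get("alpha", 0.05))
    for e in screen_cfg["exposures"]:
        p = e if isinstance(e, str) else e["path"]
        manifest["input_checksums"][str(p)] = _sha256(p)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
    (outdir / "screen_manifest.json").write_text(json.dumps(manifest, indent=2))
    return df, manifest


def run_mediation_files(cfg: dict, outdir) -> tuple[pd.DataFrame, dict]:
    med_cfg = cfg.get("mediation")
    if not med_cfg or "triples" not in med_cfg:
        raise ConfigError("mediation config must list 'triples'")
    triples = []
    for t in med_cfg["triples"]:
        triples.append({"exposure": _read_entry(t["exposure"]),
                        "mediator": _read_entry(t["mediator"]),
                        "outcome": _read_entry(t["outcome"], trait_type="binary")})
    ld = _load_ld_block(med_cfg)
    df, manifest = run_mediation(triples, ld, instrument_config_from(cfg),
                                 mode=cfg.get("mode", "multiplicative_random"))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "mediation_results.tsv", sep="\t", index=False)
    (outdir / "mediation_manifest.json").write_text(json.dumps(manifest, indent=2))
    return df, manifest


def run_phewas_files(cfg: dict, outdir) -> tuple[pd.DataFrame, dict]:
    """File-based PheWAS over a tab-delimited phenotype manifest.

    The manifest has columns ``phenotype_id``, ``category``, ``path``.
    Phenotype files that are missing or unreadable become row-level
    errors; the scan continues.
    """
    ph_cfg = cfg.get("phewas")
    if not ph_cfg or "exposure" not in ph_cfg or "manifest" not in ph_cfg:
        raise ConfigError("phewas config must name an 'exposure' and a phenotype 'manifest'")
    exposure = _read_entry(ph_cfg["exposure"])
    manifest_df = pd.read_csv(ph_cfg["manifest"], sep="\t", dtype=str)
    for col in ("phenotype_id", "category", "path"):
        if col not in manifest_df.columns:
            raise ConfigError(f"phenotype manifest missing column {col!r}")
    phenotypes, categories, file_errors = [], {}, []
    for row in manifest_df.itertuples(index=False):
        try:
            tab = read_sumstats(row.path, trait_id=row.phenotype_id, trait_type="binary")
        except (OSError, MRScreenError) as exc:
            file_errors.append({"phenotype_id": row.phenotype_id, "status": "missing",
                                "reason": f"unreadable phenotype file: {exc}"})
            continue
        phenotypes.append(tab)
        categories[row.phenotype_id] = row.category
    if not phenotypes and not file_errors:
        raise ConfigError("phenotype manifest lists no phenotypes")
    ld = _load_ld_block(ph_cfg)
    df, manifest = run_phewas(exposure, phenotypes, ld, instrument_config_from(cfg),
                              alpha=ph_cfg.get("alpha", cfg.get("alpha", 0.05)),
                              mode=cfg.get("mode", "multiplicative_random"),
                              categories=categories)
    if file_errors:
        df = pd.concat([df, pd.DataFrame(file_errors)], ignore_index=True)
        manifest["counts"]["unreadable"] = len(file_errors)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "phewas_results.tsv", sep="\t", index=False)
    (outdir / "phewas_manifest.json").write_text(json.dumps(manifest, indent=2))
    return df, manifest
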