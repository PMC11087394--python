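"""Causal-effect estimation from harmonized summary statistics.

The primary estimator is inverse-variance-weighted (IVW) meta-analysis of
per-SNP Wald ratios: with exposure effects bx_j, outcome effects by_j and
outcome standard errors sey_j,

    beta_IVW = sum_j(bx_j * by_j / sey_j^2) / sum_j(bx_j^2 / sey_j^2)

which is exactly weighted least squares of by on bx through the origin
with weights 1/sey^2.  The fixed-effect standard error is
sqrt(1 / sum_j(bx_j^2 / sey_j^2)); the multiplicative-random-effects
variant (the default for screens) inflates it by sqrt(max(1, Q/(J-1)))
where Q is Cochran's heterogeneity statistic — it never deflates, and
reduces to the fixed-effect answer exactly when instruments are
homogeneous.

Sensitivity analyses: Cochran's Q for heterogeneity, the Egger intercept
as a probe for directional horizontal pleiotropy, and leave-one-out
refits for single-instrument influence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInstrumentError, NoInstrumentsError
from .harmonize import HarmonizedTable

#: Two-sided 95% normal multiplier, fixed so printed-CI reconstruction is
#: bit-stable across platforms.
Z95 = 1.959964

_P_FLOOR = 1e-300  # keep p-values inside (0, 1] under extreme z


@dataclass(frozen=True)
class MREstimate:
    """Causal effect per unit exposure, with Wald CI and OR transform.

    ``beta`` is on the outcome scale (log-odds for binary outcomes), so
    ``or_ = exp(beta)`` is the odds ratio per unit increase in the
    genetically predicted exposure.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snps: int
    method: str


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else _P_FLOOR
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(beta) / se), _P_FLOOR)))


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate an effect and its 95% Wald interval to the OR scale."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    return (math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))


def _make_estimate(beta: float, se: float, n_snps: int, method: str,
                   pval: float | None = None) -> MREstimate:
    or_, lo, hi = beta_to_or(beta, se)
    return MREstimate(
        beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pval=_normal_p(beta, se) if pval is None else float(pval),
        or_=or_, or_ci_low=lo, or_ci_high=hi,
        n_snps=int(n_snps), method=method,
    )


def wald_ratio(bx: float, sex: float, by: float, sey: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order SE sey/|bx|.

    The first-order SE ignores uncertainty in bx (the usual no-measurement-
    error convention for strong instruments).
    """
    if bx == 0:
        raise DegenerateInstrumentError("instrument has zero exposure effect (bx = 0)")
    return _make_estimate(by / bx, sey / abs(bx), 1, "wald_ratio")


def _arrays(h: HarmonizedTable):
    r = h.rows
    return (r["beta_exposure"].to_numpy(float), r["se_exposure"].to_numpy(float),
            r["beta_outcome"].to_numpy(float), r["se_outcome"].to_numpy(float))


def ivw(h: HarmonizedTable, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over the harmonized instruments.

    ``mode`` is ``"fixed"`` or ``"multiplicative_random"``.  With a single
    instrument the result equals :func:`wald_ratio` exactly.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    bx, sex, by, sey = _arrays(h)
    j = len(bx)
    if j == 0:
        raise NoInstrumentsError(
            f"no instruments for {h.exposure_id!r} -> {h.outcome_id!r}")
    if np.any(bx == 0):
        raise DegenerateInstrumentError("an instrument has zero exposure effect")
    if j == 1:
        return wald_ratio(bx[0], sex[0], by[0], sey[0])

    w = bx ** 2 / sey ** 2
    beta = float(np.sum(bx * by / sey ** 2) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    if mode == "fixed":
        return _make_estimate(beta, se_fixed, j, "ivw_fe")
    q = float(np.sum(w * (by / bx - beta) ** 2))
    se = se_fixed * math.sqrt(max(1.0, q / (j - 1)))
    return _make_estimate(beta, se, j, "ivw_mre")


def cochran_q(h: HarmonizedTable, ivw_beta: float) -> tuple[float, int, float] | None:
    """Cochran's Q over per-SNP Wald ratios; None with fewer than 2 SNPs.

    Q = sum_j w_j (by_j/bx_j - beta_IVW)^2 with w_j = bx_j^2/sey_j^2, on
    J-1 degrees of freedom.  Inflation signals heterogeneity consistent
    with pleiotropic or otherwise invalid instruments.
    """
    bx, _, by, sey = _arrays(h)
    j = len(bx)
    if j < 2:
        return None
    w = bx ** 2 / sey ** 2
    q = float(np.sum(w * (by / bx - ivw_beta) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass(frozen=True)
class EggerResult:
    """Egger regression: intercept probes directional pleiotropy."""

    intercept: float
    intercept_se: float
    intercept_pval: float
    slope: MREstimate


def egger(h: HarmonizedTable) -> EggerResult | None:
    """Weighted regression of by on bx with intercept; None below 3 SNPs.

    Pairs are oriented so bx >= 0 (the standard identifiability
    convention), then by is regressed on bx with weights 1/sey^2.  SEs use
    a multiplicative residual scale floored at 1, matching the IVW
    default; p-values use the t distribution on J-2 df.
    """
    bx, sex, by, sey = _arrays(h)
    j = len(bx)
    if j < 3:
        return None
    sign = np.where(bx < 0, -1.0, 1.0)
    bxo, byo = bx * sign, by * sign
    res = sm.WLS(byo, sm.add_constant(bxo), weights=1.0 / sey ** 2).fit()
    # unscaled (X'WX)^-1 diagonal, with the residual scale floored at 1
    se_unscaled = np.sqrt(np.diag(res.normalized_cov_params))
    infl = math.sqrt(max(1.0, float(res.scale)))
    se_int, se_slope = se_unscaled * infl
    est_int, est_slope = res.params
    df = j - 2

    def t_p(estimate, se):
        if se == 0:
            return 1.0 if estimate == 0 else _P_FLOOR
        return float(min(1.0, max(2.0 * stats.t.sf(abs(estimate) / se, df), _P_FLOOR)))

    slope = _make_estimate(est_slope, se_slope, j, "egger", pval=t_p(est_slope, se_slope))
    return EggerResult(float(est_int), float(se_int), t_p(est_int, se_int), slope)


def _drop_row(h: HarmonizedTable, i: int) -> HarmonizedTable:
    rows = h.rows.drop(h.rows.index[i]).reset_index(drop=True)
    return HarmonizedTable(h.exposure_id, h.outcome_id, rows, h.audit)


def leave_one_out(h: HarmonizedTable,
                  mode: str = "multiplicative_random") -> list[tuple[str, MREstimate]]:
    """Refit IVW once per omitted instrument; empty list below 2 SNPs."""
    if h.n_snps < 2:
        return []
    out = []
    for i in range(h.n_snps):
        left_out = h.rows["variant_id"].iat[i]
        out.append((left_out, ivw(_drop_row(h, i), mode)))
    return out


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy and influence diagnostics for one fit."""

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    loo: list = field(default_factory=list)


def sensitivity(h: HarmonizedTable, estimate: MREstimate,
                mode: str = "multiplicative_random") -> SensitivityReport:
    """Run the full sensitivity battery appropriate to the SNP count."""
    report = SensitivityReport()
    q = cochran_q(h, estimate.beta)
    if q is not None:
        report.q_stat, report.q_df, report.q_pval = q
    e = egger(h)
    if e is not None:
        report.egger_intercept = e.intercept
        report.egger_intercept_se = e.intercept_se
        report.egger_intercept_pval = e.intercept_pval
    report.loo = leave_one_out(h, mode)
    return report
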