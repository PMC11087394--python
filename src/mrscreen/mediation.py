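"""Two-step MR mediation: product-of-coefficients with delta-method inference.

The total effect of an exposure on an outcome decomposes into the
indirect path through a mediator and the direct remainder:

    indirect = beta_EM * beta_MO        (product method)
    direct   = beta_EO - indirect
    proportion mediated = indirect / beta_EO

where beta_EM is the exposure->mediator effect, beta_MO the
mediator->outcome effect, and beta_EO the total exposure->outcome effect,
each estimated by univariable IVW MR.  The delta-method (first-order)
variance of the product,

    var(indirect) = beta_EM^2 * se_MO^2 + beta_MO^2 * se_EM^2,

carries no covariance term: the two legs are estimated from
non-overlapping samples under the two-sample design, so their sampling
errors are treated as independent.

Proportions mediated outside [0, 1] (inconsistent mediation, where the
indirect and total effects disagree in sign or the indirect path
overshoots the total) are reported verbatim with a flag, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .errors import MediationLegError, MRScreenError
from .harmonize import harmonize
from .instruments import InstrumentSet
from .mr import Z95, MREstimate, ivw, _P_FLOOR
from .sumstats import SumStatsTable


@dataclass(frozen=True)
class MediationInput:
    """Effect estimates for the three MR legs of one mediation triple."""

    beta_EM: float
    se_EM: float
    beta_MO: float
    se_MO: float
    beta_EO: float
    se_EO: float

    def __post_init__(self):
        for name in ("se_EM", "se_MO", "se_EO"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MediationResult:
    """Indirect/direct decomposition with delta-method inference."""

    indirect_beta: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    indirect_pval: float
    direct_beta: float
    proportion_mediated: float  # NaN when the total effect is zero
    sign_discordant: bool
    proportion_defined: bool
    components: dict = field(default_factory=dict)  # leg -> MREstimate, for audit

    @property
    def proportion_mediated_pct(self) -> float:
        return 100.0 * self.proportion_mediated


def proportion_mediated(beta_EM: float, beta_MO: float, beta_EO: float) -> float:
    """Point-estimate proportion mediated, (beta_EM*beta_MO)/beta_EO.

    Useful for replaying published effect estimates (e.g. log odds ratios
    read off a results table) without standard errors.
    """
    if beta_EO == 0:
        raise MRScreenError("proportion mediated undefined: total effect is zero")
    return beta_EM * beta_MO / beta_EO


def indirect_effect(inp: MediationInput) -> MediationResult:
    """Product-method indirect effect with delta-method SE, CI and p-value."""
    indirect = inp.beta_EM * inp.beta_MO
    var = inp.beta_EM ** 2 * inp.se_MO ** 2 + inp.beta_MO ** 2 * inp.se_EM ** 2
    se = math.sqrt(var)
    if se == 0:
        pval = 1.0 if indirect == 0 else _P_FLOOR
    else:
        pval = float(min(1.0, max(2.0 * stats.norm.sf(abs(indirect) / se), _P_FLOOR)))
    direct = inp.beta_EO - indirect
    defined = inp.beta_EO != 0
    prop = indirect / inp.beta_EO if defined else float("nan")
    discordant = defined and indirect != 0 and (indirect > 0) != (inp.beta_EO > 0)
    return MediationResult(
        indirect_beta=indirect, indirect_se=se,
        indirect_ci_low=indirect - Z95 * se, indirect_ci_high=indirect + Z95 * se,
        indirect_pval=pval, direct_beta=direct,
        proportion_mediated=prop, sign_discordant=discordant,
        proportion_defined=defined,
    )


def mediate(exposure_instruments: InstrumentSet,
            mediator_sumstats: SumStatsTable,
            outcome_sumstats: SumStatsTable,
            mediator_instruments: InstrumentSet,
            mode: str = "multiplicative_random") -> MediationResult:
    """Run the three component MR fits and assemble the mediation result.

    Legs: exposure->mediator and exposure->outcome use the exposure's
    instruments; mediator->outcome uses the mediator's own instruments
    (univariable MR, not multivariable adjustment).  The three component
    estimates are attached to the result under ``components`` for audit.

    Raises
    ------
    MediationLegError
        Naming the failing leg when any leg has no harmonizable
        instruments.
    """
    legs: dict[str, MREstimate] = {}
    for leg, instruments, table in (
        ("exposure->mediator", exposure_instruments, mediator_sumstats),
        ("mediator->outcome", mediator_instruments, outcome_sumstats),
        ("exposure->outcome", exposure_instruments, outcome_sumstats),
    ):
        try:
            legs[leg] = ivw(harmonize(instruments, table), mode)
        except MRScreenError as exc:
            raise MediationLegError(leg, str(exc)) from exc

    inp = MediationInput(
        beta_EM=legs["exposure->mediator"].beta, se_EM=legs["exposure->mediator"].se,
        beta_MO=legs["mediator->outcome"].beta, se_MO=legs["mediator->outcome"].se,
        beta_EO=legs["exposure->outcome"].beta, se_EO=legs["exposure->outcome"].se,
    )
    result = indirect_effect(inp)
    result.components = legs
    return result
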