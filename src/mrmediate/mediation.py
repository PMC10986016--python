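"""Product-of-coefficients mediation with delta-method confidence intervals.

The two-step MR decomposition works on three coefficients per mediator:

- beta0: total effect of the exposure on the outcome (univariable MR),
- beta1: effect of the exposure on the mediator (univariable MR),
- beta2: effect of the mediator on the outcome adjusted for the exposure
  (multivariable MR).

The indirect (mediated) effect is beta1*beta2, the direct effect is
beta0 - beta1*beta2, and the proportion mediated is

    P = (beta1 * beta2) / beta0

with the first-order delta-method standard error for a product over a ratio
of independent estimates

    SE(P) = |P| * sqrt((se1/beta1)^2 + (se2/beta2)^2 + (se0/beta0)^2)

and 95% CI  P +/- 1.96 SE(P).  Estimates sharing the outcome GWAS (beta0,
beta2) are treated as independent; see the methods note for the consequences
of that assumption.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import Z95, _normal_p
from .exceptions import ParameterError, UndefinedProportionError

logger = logging.getLogger(__name__)

FLAG_SIGN_INCONSISTENT = "sign-inconsistency"
FLAG_PROPORTION_OUTSIDE = "proportion-outside-[0,1]"
FLAG_ZERO_COEFFICIENT = "zero-coefficient"

TRIPLES_COLUMNS = ["mediator", "outcome", "beta1", "se1", "beta2", "se2", "beta0", "se0"]


@dataclass
class CoefficientTriple:
    """(beta0, beta1, beta2) with standard errors for one mediation path."""

    beta0: float
    se0: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    mediator: str = ""
    outcome: str = ""

    def __post_init__(self):
        if min(self.se0, self.se1, self.se2) <= 0:
            raise ParameterError("all standard errors must be positive")


@dataclass
class MediationResult:
    indirect: float
    indirect_se: float
    direct: float
    proportion: float
    proportion_se: float
    ci_low: float
    ci_high: float
    pvalue: float
    flags: list[str] = field(default_factory=list)
    mediator: str = ""
    outcome: str = ""

    @property
    def proportion_pct(self) -> float:
        """Proportion mediated as a percentage at one decimal."""
        return round(100.0 * self.proportion, 1)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return round(100.0 * self.ci_low, 1), round(100.0 * self.ci_high, 1)


def mediate(t: CoefficientTriple) -> MediationResult:
    """Decompose a total effect into indirect/direct and proportion mediated.

    Raises :class:`UndefinedProportionError` when beta0 = 0.  When beta1 or
    beta2 is exactly zero the proportion is 0 with the SE built from the
    surviving product terms, and the result is flagged.
    """
    if t.beta0 == 0:
        raise UndefinedProportionError("total effect beta0 is zero")
    indirect = t.beta1 * t.beta2
    indirect_se = float(np.hypot(t.beta1 * t.se2, t.beta2 * t.se1))
    direct = t.beta0 - indirect
    flags: list[str] = []

    if t.beta1 == 0 or t.beta2 == 0 or indirect == 0:  # incl. product underflow
        proportion = 0.0
        proportion_se = indirect_se / abs(t.beta0)
        flags.append(FLAG_ZERO_COEFFICIENT)
    else:
        proportion = indirect / t.beta0
        with np.errstate(over="ignore"):  # near-zero coefficients -> inf SE
            rel = (
                np.float64(t.se1 / t.beta1) ** 2
                + np.float64(t.se2 / t.beta2) ** 2
                + np.float64(t.se0 / t.beta0) ** 2
            )
        proportion_se = abs(proportion) * float(np.sqrt(rel))
    if np.sign(indirect) != np.sign(t.beta0) and indirect != 0:
        flags.append(FLAG_SIGN_INCONSISTENT)
    if not 0 <= proportion <= 1:
        flags.append(FLAG_PROPORTION_OUTSIDE)
    return MediationResult(
        indirect=indirect,
        indirect_se=indirect_se,
        direct=direct,
        proportion=proportion,
        proportion_se=proportion_se,
        ci_low=proportion - Z95 * proportion_se,
        ci_high=proportion + Z95 * proportion_se,
        pvalue=_normal_p(proportion / proportion_se) if proportion_se > 0 else 1.0,
        flags=flags,
        mediator=t.mediator,
        outcome=t.outcome,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_coefficient_triples(path) -> list[CoefficientTriple]:
    """Read a coefficient-triples TSV (mediator, outcome, b1, se1, b2, se2, b0, se0)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIPLES_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"triples file missing column(s): {missing}")
    return [
        CoefficientTriple(
            beta0=r["beta0"], se0=r["se0"], beta1=r["beta1"], se1=r["se1"],
            beta2=r["beta2"], se2=r["se2"], mediator=r["mediator"], outcome=r["outcome"],
        )
        for _, r in df.iterrows()
    ]


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Percentage-scale summary table (proportion and CI at one decimal)."""
    return pd.DataFrame(
        {
            "mediator": [r.mediator for r in results],
            "outcome": [r.outcome for r in results],
            "proportion_pct": [r.proportion_pct for r in results],
            "ci_low_pct": [r.ci_pct[0] for r in results],
            "ci_high_pct": [r.ci_pct[1] for r in results],
            "pvalue": [r.pvalue for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )


# Published coefficient triples from a two-step MR analysis of birth weight,
# fatty-acid ratio mediators and glycaemic outcomes (log-odds scale for T2DM,
# SD units for the quantitative traits).  Used as a worked input for the
# mediation stage and in the acceptance checks.
_BIRTHWEIGHT_TRIPLES_TSV = """\
mediator\toutcome\tbeta1\tse1\tbeta2\tse2\tbeta0\tse0
PUFA/MUFA ratio\tT2DM\t0.107\t0.026\t-0.819\t0.246\t-1.113\t0.235
PUFA/TFA ratio\tT2DM\t0.095\t0.025\t-0.846\t0.254\t-1.113\t0.235
Omega-6/TFA ratio\tT2DM\t0.106\t0.028\t-0.850\t0.255\t-1.113\t0.235
LA/TFA ratio\tT2DM\t0.082\t0.025\t-0.807\t0.261\t-1.113\t0.235
PUFA/MUFA ratio\tFasting glucose\t0.107\t0.026\t-0.079\t0.022\t-0.061\t0.015
PUFA/TFA ratio\tFasting glucose\t0.095\t0.025\t-0.083\t0.022\t-0.061\t0.015
Omega-6/TFA ratio\tFasting glucose\t0.106\t0.028\t-0.081\t0.022\t-0.061\t0.015
LA/TFA ratio\tFasting glucose\t0.082\t0.025\t-0.078\t0.022\t-0.061\t0.015
PUFA/MUFA ratio\tFasting insulin\t0.107\t0.026\t-0.069\t0.021\t-0.080\t0.014
PUFA/TFA ratio\tFasting insulin\t0.095\t0.025\t-0.068\t0.021\t-0.080\t0.014
Omega-6/TFA ratio\tFasting insulin\t0.106\t0.028\t-0.074\t0.021\t-0.080\t0.014
LA/TFA ratio\tFasting insulin\t0.082\t0.025\t-0.074\t0.021\t-0.080\t0.014
PUFA/MUFA ratio\tTwo-hour glucose\t0.107\t0.026\t-0.304\t0.063\t-0.250\t0.056
PUFA/TFA ratio\tTwo-hour glucose\t0.095\t0.025\t-0.269\t0.064\t-0.250\t0.056
Omega-6/TFA ratio\tTwo-hour glucose\t0.106\t0.028\t-0.245\t0.063\t-0.250\t0.056
LA/TFA ratio\tTwo-hour glucose\t0.082\t0.025\t-0.239\t0.062\t-0.250\t0.056
"""


def birthweight_fatty_acid_triples() -> list[CoefficientTriple]:
    """Worked-example coefficient triples (birth weight -> fatty-acid ratios
    -> glycaemic outcomes) from a published two-step MR study."""
    return read_coefficient_triples(io.StringIO(_BIRTHWEIGHT_TRIPLES_TSV))
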