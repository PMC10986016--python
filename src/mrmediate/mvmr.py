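"""Multivariable MR: joint direct effects of several exposures on one outcome.

The outcome betas are regressed on the matrix of exposure betas without an
intercept, weighted by inverse outcome variance.  In the two-step mediation
design the exposures are (primary exposure, mediator) and the mediator's
coefficient is the mediator->outcome effect adjusted for the exposure (the
beta2 of the product-of-coefficients decomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .estimators import _normal_p
from .exceptions import CollinearityError, InsufficientInstrumentsError, ParameterError
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

COND_NUMBER_MAX = 1e8


@dataclass
class MVMRResult:
    """One coefficient (beta, se, p) per exposure; n_snp instruments."""

    exposure_labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    n_snp: int
    model: str
    extras: dict = field(default_factory=dict)

    def coefficient(self, label: str) -> tuple[float, float, float]:
        i = self.exposure_labels.index(label)
        return float(self.beta[i]), float(self.se[i]), float(self.pvalue[i])


def mvmr_ivw(
    h: HarmonizedSet,
    model: str = "multiplicative-random",
    cond_number_max: float = COND_NUMBER_MAX,
) -> MVMRResult:
    """Multivariable IVW on a jointly harmonized set.

    ``h`` must carry at least two exposure traits followed by the outcome
    (last trait).  Under ``multiplicative-random`` the SEs are scaled by
    sqrt(max(1, Q/(k - p))) with p predictors.  Near-collinear exposure
    columns (weighted design condition number above ``cond_number_max``)
    raise :class:`CollinearityError` naming the most correlated pair.
    """
    if model not in ("fixed", "multiplicative-random"):
        raise ParameterError(f"unknown MVMR model '{model}'")
    if len(h.traits) < 3:
        raise ParameterError("MVMR needs >= 2 exposure traits plus the outcome")
    p = len(h.traits) - 1
    k = h.n_snp
    if k < p + 1:
        raise InsufficientInstrumentsError(
            f"MVMR with {p} exposures requires >= {p + 1} SNPs, got {k}"
        )
    x = h.beta[:, :p]
    y = h.beta[:, p]
    sy = h.se[:, p]
    w = 1.0 / sy**2

    # an all-zero column carries no instrument signal: its coefficient is
    # reported as 0 with infinite SE and the remaining columns are fitted,
    # preserving the nested-model identity with univariable IVW
    nonzero = [j for j in range(p) if np.any(x[:, j] != 0)]
    if not nonzero:
        raise ParameterError("all exposure beta columns are zero")
    xs = x[:, nonzero]

    xw = xs * np.sqrt(w)[:, None]
    cond = float(np.linalg.cond(xw))
    if cond > cond_number_max:
        corr = np.corrcoef(xs, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        pair = (h.traits[nonzero[i]], h.traits[nonzero[j]])
        raise CollinearityError(
            f"exposure beta columns are near-collinear (condition number "
            f"{cond:.3g}); most correlated pair: {pair[0]} vs {pair[1]}",
            pair=pair,
        )

    fit = sm.WLS(y, xs, weights=w).fit()
    q = float(np.sum((fit.resid / sy) ** 2))
    scale = 1.0
    if model == "multiplicative-random" and k > p:
        scale = max(1.0, q / (k - p))
    unscaled = np.asarray(fit.bse) / np.sqrt(fit.scale)
    beta = np.zeros(p)
    se = np.full(p, np.inf)
    beta[nonzero] = np.asarray(fit.params)
    se[nonzero] = unscaled * np.sqrt(scale)
    pvals = np.array(
        [_normal_p(b / s) if np.isfinite(s) and s > 0 else 1.0
         for b, s in zip(beta, se)]
    )
    return MVMRResult(
        exposure_labels=list(h.traits[:p]),
        beta=beta,
        se=se,
        pvalue=pvals,
        n_snp=k,
        model=model,
        extras={"Q": q, "scale": scale, "condition_number": cond},
    )


def conditional_f(h: HarmonizedSet) -> dict[str, float]:
    """Approximate conditional instrument strength per exposure.

    For each exposure, its betas are regressed (inverse-variance weighted by
    its own SEs) on the other exposures' betas; the conditional F is the
    standardised residual sum of squares over (k - p + 1) degrees of
    freedom.  A diagnostic only -- nothing in the pipeline gates on it.
    """
    p = len(h.traits) - 1
    if p < 2:
        raise ParameterError("conditional F needs >= 2 exposures")
    k = h.n_snp
    out = {}
    for i in range(p):
        others = [j for j in range(p) if j != i]
        xi = h.beta[:, i]
        si = h.se[:, i]
        design = h.beta[:, others]
        fit = sm.WLS(xi, design, weights=1.0 / si**2).fit()
        q = float(np.sum((fit.resid / si) ** 2))
        out[h.traits[i]] = q / (k - p + 1)
    return out
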