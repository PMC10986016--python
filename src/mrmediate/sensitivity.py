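"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

- Cochran's Q: weighted dispersion of per-SNP Wald ratios about the
  fixed-effect IVW estimate (df = k - 1).
- Rucker's Q: weighted residual sum of squares about the Egger fit
  (df = k - 2); never exceeds Cochran's Q because the origin-constrained
  model is nested in the intercept model.
- Egger intercept test: two-sided normal test of average directional
  pleiotropy.
- MR-PRESSO: simulation-based residual-sum-of-squares test.  Observed
  leave-one-out residuals are compared to an empirical null built by
  redrawing every SNP's effects from their stated normal errors under the
  leave-one-out IVW fit.  Per-SNP outlier p-values are empirical tail
  probabilities, Bonferroni-corrected over SNPs; a distortion test compares
  the outlier-corrected estimate against removals of random same-size SNP
  subsets.
- Leave-one-out: IVW re-estimated excluding each SNP in turn, flagging
  exclusions that change the sign or move the estimate by more than a
  configurable multiple of the full-set SE.

Empirical p-values use the (r+1)/(n_sim+1) convention.  All diagnostics are
invariant to SNP input order (MR-PRESSO sorts internally before drawing its
simulation noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _egger_fit, _normal_p, ivw
from .exceptions import InsufficientInstrumentsError, ParameterError
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

DEFAULT_PRESSO_N_SIM = 1000
DEFAULT_PRESSO_SIG = 0.05
DEFAULT_LOO_FLAG_MULTIPLIER = 1.0


@dataclass
class HeterogeneityResult:
    statistic: float
    df: int
    pvalue: float
    flavor: str  # "cochran-ivw" | "rucker-egger"


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float


@dataclass
class PressoResult:
    global_rss: float
    global_pvalue: float
    outlier_snps: pd.DataFrame  # columns: SNP, pvalue, pvalue_bonferroni
    distortion_pvalue: float | None
    corrected_estimate: MREstimate | None


@dataclass
class LeaveOneOutResult:
    table: pd.DataFrame  # columns: SNP, beta, se, flagged
    full_estimate: MREstimate


def _ratio_stats(h: HarmonizedSet, outcome=-1):
    bx, _, by, sy = h.pair(outcome)
    ratios = by / bx
    w = bx**2 / sy**2  # inverse-variance of the first-order ratio SE
    return ratios, w


def cochran_q(h: HarmonizedSet, outcome: int | str = -1) -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW estimate."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 SNPs")
    ratios, w = _ratio_stats(h, outcome)
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = h.n_snp - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)), "cochran-ivw")


def rucker_q(h: HarmonizedSet, outcome: int | str = -1) -> HeterogeneityResult:
    """Rucker's Q: weighted residual dispersion about the Egger fit."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("Rucker's Q requires >= 3 SNPs")
    *_, q = _egger_fit(h, outcome)
    df = h.n_snp - 2
    return HeterogeneityResult(float(q), df, float(stats.chi2.sf(q, df)), "rucker-egger")


def egger_intercept_test(h: HarmonizedSet, outcome: int | str = -1) -> PleiotropyResult:
    """Directional-pleiotropy test on the Egger regression intercept."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("Egger intercept test requires >= 3 SNPs")
    a, _, se_a, *_ = _egger_fit(h, outcome)
    return PleiotropyResult(a, se_a, _normal_p(a / se_a) if se_a > 0 else 0.0)


def _loo_residuals(bx, by, sy, sy_weight):
    """Leave-one-out IVW predictions and sy-standardised residuals."""
    w = 1.0 / sy_weight**2
    s_xy = np.sum(bx * by * w, axis=-1, keepdims=True)
    s_xx = np.sum(bx**2 * w, axis=-1, keepdims=True)
    beta_loo = (s_xy - bx * by * w) / (s_xx - bx**2 * w)
    return (by - beta_loo * bx) / sy


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_PRESSO_N_SIM,
    significance: float = DEFAULT_PRESSO_SIG,
    seed: int = 0,
    outcome: int | str = -1,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the sum of squared sy-standardised
    leave-one-out residuals.  The null redraws each SNP's exposure and
    outcome effects from N(bx_j, sx_j) and N(beta_loo_j * bx_j, sy_j) and
    recomputes the same statistic ``n_sim`` times.
    """
    if h.n_snp < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 SNPs")
    if n_sim < 100:
        raise ParameterError("n_sim must be >= 100")
    if not 0 < significance < 1:
        raise ParameterError("significance must be in (0, 1)")

    # order-invariance: work in snp_id order, report back in input order
    order = np.argsort(np.asarray(h.snp_ids))
    bx_all, sx_all, by_all, sy_all = h.pair(outcome)
    bx, sx, by, sy = (a[order] for a in (bx_all, sx_all, by_all, sy_all))
    k = len(bx)

    w = 1.0 / sy**2
    s_xy = np.sum(bx * by * w)
    s_xx = np.sum(bx**2 * w)
    beta_loo = (s_xy - bx * by * w) / (s_xx - bx**2 * w)
    resid_obs = (by - beta_loo * bx) / sy
    rss_obs = float(np.sum(resid_obs**2))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    resid_sim = _loo_residuals(bx_sim, by_sim, sy, sy)
    rss_sim = np.sum(resid_sim**2, axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    p_snp = (np.sum(resid_sim**2 >= resid_obs[None, :] ** 2, axis=0) + 1) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_snp * k)
    is_out = p_bonf < significance

    snps_sorted = [h.snp_ids[i] for i in order]
    out_df = pd.DataFrame(
        {
            "SNP": np.array(snps_sorted)[is_out],
            "pvalue": p_snp[is_out],
            "pvalue_bonferroni": p_bonf[is_out],
        }
    )

    distortion_p = None
    corrected = None
    if is_out.any():
        outliers = set(out_df["SNP"])
        keep_mask = np.array([s not in outliers for s in h.snp_ids])
        corrected = ivw(h.subset(keep_mask), outcome=outcome)
        beta_full = ivw(h, outcome=outcome).beta
        d_obs = corrected.beta - beta_full
        n_out = int(is_out.sum())
        n_draw = min(n_sim, 1000)
        d_null = np.empty(n_draw)
        idx = np.arange(k)
        for b in range(n_draw):
            drop = rng.choice(idx, size=n_out, replace=False)
            m = np.ones(k, dtype=bool)
            m[drop] = False
            wj = w[m]
            d_null[b] = np.sum(bx[m] * by[m] * wj) / np.sum(bx[m] ** 2 * wj) - beta_full
        distortion_p = float((np.sum(np.abs(d_null) >= abs(d_obs)) + 1) / (n_draw + 1))
        logger.info(
            "MR-PRESSO: %d outlier(s) removed, distortion p = %.3g", n_out, distortion_p
        )
    return PressoResult(rss_obs, global_p, out_df, distortion_p, corrected)


def leave_one_out(
    h: HarmonizedSet,
    flag_multiplier: float = DEFAULT_LOO_FLAG_MULTIPLIER,
    outcome: int | str = -1,
) -> LeaveOneOutResult:
    """IVW estimates with each SNP excluded in turn."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 SNPs")
    full = ivw(h, outcome=outcome)
    bx, _, by, sy = h.pair(outcome)
    k = h.n_snp
    # closed-form LOO from the weighted sums (equals IVW on each subset)
    w = 1.0 / sy**2
    s_xx = np.sum(bx**2 * w)
    s_xy = np.sum(bx * by * w)
    s_yy = np.sum(by**2 * w)
    xx = s_xx - bx**2 * w
    xy = s_xy - bx * by * w
    yy = s_yy - by**2 * w
    beta = xy / xx
    se_fixed = xx**-0.5
    q = np.maximum(0.0, yy - 2 * beta * xy + beta**2 * xx)
    if full.extras.get("model", "multiplicative-random") == "multiplicative-random":
        scale = np.maximum(1.0, q / (k - 2))
        se = se_fixed * np.sqrt(scale)
    else:
        se = se_fixed
    flagged = (np.sign(beta) != np.sign(full.beta)) | (
        np.abs(beta - full.beta) > flag_multiplier * full.se
    )
    table = pd.DataFrame(
        {"SNP": h.snp_ids, "beta": beta, "se": se, "flagged": flagged}
    )
    return LeaveOneOutResult(table, full)
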