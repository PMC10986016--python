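"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrmediate.gwas_io.HarmonizedSet` whose
first trait is the exposure; the outcome defaults to the last trait.  The
building block is the per-SNP Wald ratio beta_y / beta_x with first-order
standard error se_y / |beta_x| (exposure-side error is ignored at this stage
and handled explicitly by RAPS).

Methods
-------
ivw
    Inverse-variance-weighted combination, equivalent to weighted regression
    of outcome on exposure betas through the origin.  The default model is
    multiplicative random effects: the fixed-effect SE is inflated by
    sqrt(max(1, Q/(k-1))) where Q is Cochran's heterogeneity statistic, so it
    never shrinks below the fixed-effect SE.
egger
    Weighted regression *with* an intercept; the intercept estimates average
    directional pleiotropy, the slope is the adjusted causal effect.
weighted_median
    The ratio at which cumulative inverse-variance weight crosses 50%;
    consistent when at least half the weight comes from valid instruments.
    SE by seeded parametric bootstrap.
mode_based
    Argmax of a normal-kernel density of the ratios (simple: unweighted;
    weighted: inverse-variance weights), modified-Silverman bandwidth.
raps
    Root of the profile score accounting for exposure-side sampling error
    (simple, non-robust variant; no overdispersion term).

All p-values are two-sided normal; 95% CIs are beta +/- 1.96 se.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    ParameterError,
)
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96
DEFAULT_N_BOOT = 1000
DEFAULT_SEED = 20240402  # recorded in output; override per study


@dataclass
class MREstimate:
    """A single method's causal-effect estimate."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snp": self.n_snp,
        }
        d.update({k: v for k, v in self.extras.items() if np.isscalar(v)})
        return d


def _normal_p(z: float) -> float:
    return float(min(1.0, max(np.nextafter(0, 1), 2.0 * stats.norm.sf(abs(z)))))


def _finish(method: str, beta: float, se: float, n_snp: int, extras: dict) -> MREstimate:
    beta, se = float(beta), float(se)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se) if se > 0 else np.nextafter(0, 1),
        n_snp=n_snp,
        extras=extras,
    )


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios with first-order SEs and inverse-variance weights."""

    ratios: np.ndarray
    ses: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_harmonized(cls, h: HarmonizedSet, outcome: int | str = -1) -> "RatioEstimates":
        bx, _, by, sy = h.pair(outcome)
        if np.all(bx == 0):
            raise DegenerateInstrumentsError("all exposure betas are zero")
        ratios = by / bx
        ses = sy / np.abs(bx)
        return cls(ratios=ratios, ses=ses, weights=1.0 / ses**2)


def _require(h: HarmonizedSet, minimum: int, method: str):
    if h.n_snp < minimum:
        raise InsufficientInstrumentsError(
            f"{method} requires >= {minimum} SNPs, got {h.n_snp}"
        )


def ivw(
    h: HarmonizedSet,
    model: str = "multiplicative-random",
    outcome: int | str = -1,
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    beta = sum(bx by / sy^2) / sum(bx^2 / sy^2); fixed-effect
    SE = (sum bx^2/sy^2)^(-1/2).  Under ``multiplicative-random`` (default)
    the SE is scaled by sqrt(max(1, Q/(k-1))).  A single SNP degenerates to
    the Wald ratio (allowed with a warning).
    """
    if model not in ("fixed", "multiplicative-random"):
        raise ParameterError(f"unknown IVW model '{model}'")
    bx, _, by, sy = h.pair(outcome)
    k = h.n_snp
    if k < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 SNP")
    if np.all(bx == 0):
        raise DegenerateInstrumentsError("all exposure betas are zero")
    if k == 1:
        warnings.warn("single SNP: IVW degenerates to the Wald ratio", stacklevel=2)
    w = 1.0 / sy**2
    s_xy = float(np.sum(bx * by * w))
    s_xx = float(np.sum(bx**2 * w))
    beta = s_xy / s_xx
    se_fixed = s_xx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = 1.0
    if model == "multiplicative-random" and k > 1:
        scale = max(1.0, q / (k - 1))
    se = se_fixed * np.sqrt(scale)
    return _finish("IVW", beta, se, k, {"model": model, "Q": q, "scale": scale})


def _egger_fit(h: HarmonizedSet, outcome: int | str = -1):
    """Weighted regression of by on bx with intercept, bx oriented >= 0.

    Returns (intercept, slope, se_int, se_slope, dispersion, residual_q).
    SEs carry the multiplicative random-effects floor: the residual
    dispersion never scales them below their unit-dispersion value.
    """
    bx, _, by, sy = h.pair(outcome)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=1.0 / sy**2).fit()
    resid_q = float(np.sum((fit.resid / sy) ** 2))
    dispersion = resid_q / (len(bx) - 2)
    unscaled = fit.bse / np.sqrt(fit.scale)
    floored = unscaled * np.sqrt(max(1.0, dispersion))
    return (
        float(fit.params[0]),
        float(fit.params[1]),
        float(floored[0]),
        float(floored[1]),
        dispersion,
        resid_q,
    )


def egger(h: HarmonizedSet, outcome: int | str = -1) -> MREstimate:
    """MR-Egger: slope of the intercept-including weighted regression."""
    _require(h, 3, "MR-Egger")
    a, b, se_a, se_b, disp, q = _egger_fit(h, outcome)
    extras = {
        "intercept": a,
        "intercept_se": se_a,
        "intercept_pvalue": _normal_p(a / se_a) if se_a > 0 else np.nextafter(0, 1),
        "dispersion": disp,
        "residual_q": q,
    }
    return _finish("Egger", b, se_b, h.n_snp, extras)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at the 50% weight crossing."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = np.flatnonzero(p < 0.5)
    if len(below) == 0:
        return float(r[0])
    i = below[-1]
    if i + 1 >= len(r):
        return float(r[-1])
    return float(r[i] + (r[i + 1] - r[i]) * (0.5 - p[i]) / (p[i + 1] - p[i]))


def _bootstrap_se(h, outcome, statistic, n_boot, seed):
    """Parametric bootstrap: redraw (bx, by) from their stated normal errors."""
    if n_boot < 2:
        raise ParameterError("n_boot must be >= 2")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; SE will be noisy", stacklevel=3)
    bx, sx, by, sy = h.pair(outcome)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        est[b] = statistic(by_b / bx_b, sy / np.abs(bx_b))
    return float(np.std(est, ddof=1))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    outcome: int | str = -1,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    _require(h, 3, "weighted median")
    re = RatioEstimates.from_harmonized(h, outcome)
    beta = _weighted_median(re.ratios, re.weights)
    se = _bootstrap_se(
        h, outcome, lambda r, s: _weighted_median(r, 1.0 / s**2), n_boot, seed
    )
    return _finish(
        "weighted-median", beta, se, h.n_snp, {"n_boot": n_boot, "seed": seed}
    )


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule over the ratio estimates.

    0.9 * min(sd, IQR/1.349) * k^(-1/5); the IQR term guards against
    outlier-inflated spread.  Zero spread (identical ratios) yields 0 and is
    handled by the caller.
    """
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return factor * 0.9 * spread * len(ratios) ** (-0.2)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth: float,
              n_grid: int = 4096) -> float:
    grid = np.linspace(ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth, n_grid)
    dens = (weights[None, :] * stats.norm.pdf(
        (grid[:, None] - ratios[None, :]) / bandwidth
    )).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_based(
    h: HarmonizedSet,
    variant: str = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    outcome: int | str = -1,
) -> MREstimate:
    """Mode-based estimate: argmax of a smoothed density of Wald ratios.

    ``simple`` weights every ratio equally; ``weighted`` uses inverse-variance
    weights.  If the ratios are all identical the common value is returned
    directly (the kernel degenerates).
    """
    if variant not in ("simple", "weighted"):
        raise ParameterError(f"unknown mode variant '{variant}'")
    if bandwidth_factor <= 0:
        raise ParameterError("bandwidth_factor must be positive")
    if h.n_snp == 1:
        warnings.warn("single SNP: mode equals the Wald ratio", stacklevel=2)
        re = RatioEstimates.from_harmonized(h, outcome)
        return _finish(f"{variant}-mode", re.ratios[0], re.ses[0], 1, {})
    _require(h, 3, "mode-based estimator")
    re = RatioEstimates.from_harmonized(h, outcome)

    def statistic(ratios, ses):
        w = np.ones_like(ratios) if variant == "simple" else 1.0 / ses**2
        bw = _mode_bandwidth(ratios, bandwidth_factor)
        if bw == 0:
            return float(ratios[0])
        return _kde_mode(ratios, w, bw)

    beta = statistic(re.ratios, re.ses)
    se = _bootstrap_se(h, outcome, statistic, n_boot, seed)
    bw = _mode_bandwidth(re.ratios, bandwidth_factor)
    return _finish(
        f"{variant}-mode", beta, se, h.n_snp,
        {"bandwidth": bw, "n_boot": n_boot, "seed": seed},
    )


def _profile_score(beta, bx, sx, by, sy):
    """Derivative of the profile log-likelihood in the causal effect.

    Zero of  sum_j (by - b bx)(bx sy^2 + b by sx^2) / (sy^2 + b^2 sx^2)^2.
    """
    v = sy**2 + beta**2 * sx**2
    return np.sum((by - beta * bx) * (bx * sy**2 + beta * by * sx**2) / v**2)


def raps(
    h: HarmonizedSet,
    robust: bool = False,
    overdispersion: bool = False,
    outcome: int | str = -1,
) -> MREstimate:
    """Profile-score estimator accounting for exposure-side sampling error.

    Solves the simple (non-robust, no-overdispersion) profile score; the
    ``robust`` and ``overdispersion`` flags are reserved and currently
    rejected if enabled.  SE is the estimating-equation sandwich with the
    score derivative obtained numerically at the root.
    """
    if robust or overdispersion:
        raise ParameterError(
            "only the simple profile-score variant is implemented; "
            "robust/overdispersion must be False"
        )
    _require(h, 3, "RAPS")
    bx, sx, by, sy = h.pair(outcome)
    if np.all(bx == 0):
        raise DegenerateInstrumentsError("all exposure betas are zero")

    center = ivw(h, model="fixed", outcome=outcome)
    half = max(10 * center.se, 0.5)
    lo, hi = center.beta - half, center.beta + half
    score = lambda b: _profile_score(b, bx, sx, by, sy)
    for _ in range(60):
        if np.sign(score(lo)) != np.sign(score(hi)):
            break
        half *= 2
        lo, hi = center.beta - half, center.beta + half
    else:
        raise ConvergenceError(
            f"profile score has no sign change on [{lo:.4g}, {hi:.4g}]",
            bracket=(lo, hi),
        )
    root = float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14))

    eps = 1e-6 * (1 + abs(root))
    dscore = (score(root + eps) - score(root - eps)) / (2 * eps)
    v = sy**2 + root**2 * sx**2
    psi = (by - root * bx) * (bx * sy**2 + root * by * sx**2) / v**2
    se = float(np.sqrt(np.sum(psi**2)) / abs(dscore))
    return _finish("RAPS", root, se, h.n_snp, {"bracket": (lo, hi)})


def all_estimates(
    h: HarmonizedSet,
    methods: list[str] | None = None,
    ivw_model: str = "multiplicative-random",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    mode_bandwidth_factor: float = 1.0,
    outcome: int | str = -1,
) -> list[MREstimate]:
    """Run a set of estimators (default: the full suite) on one pair."""
    methods = methods or [
        "IVW", "Egger", "weighted-median", "simple-mode", "weighted-mode", "RAPS",
    ]
    out = []
    for m in methods:
        if m == "IVW":
            out.append(ivw(h, model=ivw_model, outcome=outcome))
        elif m == "Egger":
            out.append(egger(h, outcome=outcome))
        elif m == "weighted-median":
            out.append(weighted_median(h, n_boot=n_boot, seed=seed, outcome=outcome))
        elif m == "simple-mode":
            out.append(mode_based(h, "simple", mode_bandwidth_factor, n_boot, seed, outcome))
        elif m == "weighted-mode":
            out.append(mode_based(h, "weighted", mode_bandwidth_factor, n_boot, seed, outcome))
        elif m == "RAPS":
            out.append(raps(h, outcome=outcome))
        else:
            raise ParameterError(f"unknown method '{m}'")
    return out
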