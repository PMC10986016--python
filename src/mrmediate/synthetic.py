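"""Synthetic GWAS summary statistics from a known mediation DAG.

The generator emulates the data a two-step MR study consumes: three GWAS
summary-statistic tables (exposure, mediator, outcome) whose per-SNP effects
follow the causal diagram

    SNP_j --gamma_j--> exposure --alpha--> mediator --beta2--> outcome
                                \\------------direct------------^

Per SNP j (gamma_j = 0 for mediator-specific instruments, delta_j = 0 for
exposure instruments):

    effect on mediator  = alpha * gamma_j + delta_j + pleiotropy_j
    effect on outcome   = direct * gamma_j + beta2 * (effect on mediator)
                          (+ outlier shift if planted)

The ``n_mediator_snps`` mediator-specific instruments (non-zero delta_j,
zero gamma_j) mirror the independent genetic signal a real mediator GWAS
carries; without them the multivariable design (gamma, alpha*gamma) would be
collinear and the mediator's direct effect unidentifiable.

Observed betas add normal noise with SE = 1/sqrt(2 maf (1-maf) N) per trait
(the standard approximation for a standardised continuous trait; binary
outcomes on the log-odds scale are emulated by the same machinery through an
effective N).  Instrument effects are drawn from a truncated normal bounded
away from zero so that every planted instrument passes genome-wide
significance at the configured sample sizes, decoupling selection testing
from estimator testing; effects are expressed relative to the
trait-increasing allele, so planted instrument effects are positive.

Defaults describe a well-powered study: 100 exposure SNPs (plus 100
mediator SNPs); GWAS sizes of 261,932 (exposure), 115,006 (mediator) and
298,957 (outcome), the scale of large biobank consortia; alpha = 0.5,
beta2 = -0.8, direct = -0.7 (total effect -1.1, mediated proportion 4/11).
The instrument-effect spread (gamma_sd) is wide relative to the sampling
error so that instrument strengths are heterogeneous, as in real GWAS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .gwas_io import SummaryStatTable
from .instruments import LDMatrix

logger = logging.getLogger(__name__)

_SNPS_PER_CHROM = 25  # contiguous runs per chromosome, 0.5 Mb apart


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic scenario."""

    n_snps: int = 100            # exposure instruments
    n_mediator_snps: int = 100   # mediator-specific instruments
    n_exposure: int = 261_932
    n_mediator: int = 115_006
    n_outcome: int = 298_957
    gamma_min: float = 0.10     # lower bound of |instrument effect|
    gamma_sd: float = 0.04      # spread of the truncated-normal excess
    alpha: float = 0.5          # exposure -> mediator
    beta2_true: float = -0.8    # mediator -> outcome
    direct_true: float = -0.7   # exposure -> outcome, not via mediator
    pleiotropy: str = "none"    # none | balanced | directional
    pleiotropy_magnitude: float = 0.01
    pleiotropy_frac: float = 1.0
    n_outliers: int = 0
    outlier_shift: float = 10.0  # in outcome-SE units
    maf_range: tuple[float, float] = (0.05, 0.5)
    noise: bool = True          # False: observed betas equal the truth
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 4:
            raise ParameterError("n_snps must be >= 4")
        if self.n_mediator_snps < 0:
            raise ParameterError("n_mediator_snps must be >= 0")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) <= 0:
            raise ParameterError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ParameterError(f"unknown pleiotropy mode '{self.pleiotropy}'")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ParameterError("pleiotropy_frac must be in [0, 1]")
        if not 0 <= self.n_outliers <= self.n_snps:
            raise ParameterError("n_outliers must be in [0, n_snps]")
        if self.gamma_min <= 0:
            raise ParameterError("gamma_min must be positive")

    @property
    def total_true(self) -> float:
        return self.direct_true + self.alpha * self.beta2_true

    @property
    def proportion_true(self) -> float:
        return (self.alpha * self.beta2_true) / self.total_true


@dataclass
class SimTruth:
    """Per-SNP true effects and scenario-level truth for recovery tests."""

    snp_ids: list[str]
    gamma: np.ndarray
    delta: np.ndarray
    mediator_effects: np.ndarray
    outcome_effects: np.ndarray
    pleiotropy: np.ndarray
    outlier_ids: list[str]
    exposure_instrument_ids: list[str]
    mediator_instrument_ids: list[str]
    alpha: float
    beta2_true: float
    direct_true: float
    total_true: float
    proportion_true: float

    def write_json(self, path) -> None:
        d = asdict(self)
        for key in ("gamma", "delta", "mediator_effects", "outcome_effects", "pleiotropy"):
            d[key] = [float(v) for v in d[key]]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def _positions(n: int):
    chrom = [str(j // _SNPS_PER_CHROM % 22 + 1) for j in range(n)]
    pos = [1_000_000 + (j % _SNPS_PER_CHROM) * 500_000 for j in range(n)]
    return chrom, pos


def _table(label, snp_ids, chrom, pos, maf, true_beta, se, n, rng, noise):
    beta = true_beta + rng.normal(0.0, se) if noise else true_beta.copy()
    p = np.clip(2 * stats.norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": chrom,
            "BP": pos,
            "EA": "A",
            "OA": "G",
            "EAF": maf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )
    return SummaryStatTable(label, df)


def simulate_mediation_gwas(cfg: SimConfig):
    """Simulate (exposure, mediator, outcome) summary tables plus the truth.

    Fully reproducible per ``cfg.seed``; two calls with the same config
    produce identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    nx, nm = cfg.n_snps, cfg.n_mediator_snps
    n = nx + nm
    snp_ids = [f"rs{j + 1}" for j in range(n)]
    chrom, pos = _positions(n)

    maf = rng.uniform(*cfg.maf_range, size=n)
    draw = lambda k: cfg.gamma_min + np.abs(rng.normal(0.0, cfg.gamma_sd, size=k))
    gamma = np.concatenate([draw(nx), np.zeros(nm)])
    delta = np.concatenate([np.zeros(nx), draw(nm)])

    # horizontal pleiotropy is planted on exposure instruments only
    pleio = np.zeros(n)
    n_pleio = int(round(cfg.pleiotropy_frac * nx))
    if cfg.pleiotropy != "none" and n_pleio > 0:
        which = rng.choice(nx, size=n_pleio, replace=False)
        if cfg.pleiotropy == "directional":
            pleio[which] = cfg.pleiotropy_magnitude
        else:
            pleio[which] = rng.normal(0.0, cfg.pleiotropy_magnitude, size=n_pleio)

    med_true = cfg.alpha * gamma + delta + pleio
    out_true = cfg.direct_true * gamma + cfg.beta2_true * med_true

    var_factor = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_factor * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(var_factor * cfg.n_mediator)
    se_y = 1.0 / np.sqrt(var_factor * cfg.n_outcome)

    outlier_ids: list[str] = []
    if cfg.n_outliers:
        idx = rng.choice(nx, size=cfg.n_outliers, replace=False)
        out_true[idx] += cfg.outlier_shift * se_y[idx]
        outlier_ids = [snp_ids[i] for i in sorted(idx)]

    exposure = _table("exposure", snp_ids, chrom, pos, maf, gamma, se_x,
                      cfg.n_exposure, rng, cfg.noise)
    mediator = _table("mediator", snp_ids, chrom, pos, maf, med_true, se_m,
                      cfg.n_mediator, rng, cfg.noise)
    outcome = _table("outcome", snp_ids, chrom, pos, maf, out_true, se_y,
                     cfg.n_outcome, rng, cfg.noise)
    truth = SimTruth(
        snp_ids=snp_ids,
        gamma=gamma,
        delta=delta,
        mediator_effects=med_true,
        outcome_effects=out_true,
        pleiotropy=pleio,
        outlier_ids=outlier_ids,
        exposure_instrument_ids=snp_ids[:nx],
        mediator_instrument_ids=snp_ids[nx:],
        alpha=cfg.alpha,
        beta2_true=cfg.beta2_true,
        direct_true=cfg.direct_true,
        total_true=cfg.total_true,
        proportion_true=cfg.proportion_true,
    )
    return exposure, mediator, outcome, truth


def simulate_ld_matrix(
    snp_ids,
    positions: dict[str, tuple[str, int]],
    block_size: int,
    within_block_r2: float,
    seed: int | None = None,
    jitter: float = 0.0,
) -> LDMatrix:
    """Block-diagonal LD: consecutive runs of ``block_size`` SNPs share r^2.

    With ``jitter`` > 0 the within-block values are perturbed uniformly by up
    to ``jitter`` (clipped to [0, 1]) using ``seed``; by default the matrix
    is deterministic and the seed is unused.
    """
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    if not 0 <= within_block_r2 <= 1:
        raise ParameterError("within_block_r2 must be in [0, 1]")
    snp_ids = list(snp_ids)
    k = len(snp_ids)
    r2 = np.eye(k)
    rng = np.random.default_rng(seed)
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        for i in range(start, stop):
            for j in range(i + 1, stop):
                val = within_block_r2
                if jitter > 0:
                    val = float(np.clip(val + rng.uniform(-jitter, jitter), 0.0, 1.0))
                r2[i, j] = r2[j, i] = val
    return LDMatrix(snp_ids, r2, dict(positions))
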