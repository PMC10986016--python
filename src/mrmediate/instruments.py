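"""Instrument selection: significance filter, LD clumping, strength metrics.

Instruments are SNPs associated with the exposure at genome-wide significance
(p < 5e-8 by default), pruned to approximate linkage equilibrium by greedy
clumping (r^2 > 0.001 within 10,000 kb removed, most significant SNP kept per
region), and quantified by the explained-variance fraction

    R^2_j = (2 EAF (1-EAF) beta^2) / (2 EAF (1-EAF) beta^2 + 2 EAF (1-EAF) N SE^2)

(which reduces algebraically to beta^2 / (beta^2 + N SE^2)) and the
instrument F statistic

    F = R^2 (N - K - 1) / (K (1 - R^2))

with R^2 the cumulative explained variance over the K selected SNPs.
Sets with F < 10 are flagged as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, MissingEAFError, ParameterError
from .gwas_io import SummaryStatTable

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000.0
WEAK_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Squared-correlation matrix over an ordered set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ParameterError(f"r2 matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T):
            raise ParameterError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ParameterError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ParameterError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r^2 between two SNPs, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    def write_tsv(self, matrix_path, positions_path=None) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            matrix_path, sep="\t", index_label="SNP"
        )
        if positions_path is not None:
            pd.DataFrame(
                [(s, c, p) for s, (c, p) in self.positions.items()],
                columns=["SNP", "CHR", "BP"],
            ).to_csv(positions_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, matrix_path, positions_path=None) -> "LDMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise FormatError("LD matrix row and column SNP labels differ")
        positions = {}
        if positions_path is not None:
            side = pd.read_csv(positions_path, sep="\t", dtype={"CHR": str})
            positions = {
                r["SNP"]: (str(r["CHR"]), int(r["BP"])) for _, r in side.iterrows()
            }
        return cls([str(s) for s in df.index], df.to_numpy(dtype=float), positions)


def select_by_pvalue(
    table: SummaryStatTable, threshold: float = DEFAULT_P_THRESHOLD
) -> SummaryStatTable:
    """SNPs with p strictly below ``threshold``, input order preserved."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    keep = table.records["P"] < threshold
    return SummaryStatTable(table.trait_label, table.records[keep].copy())


def ld_clump(
    table: SummaryStatTable,
    ld: LDMatrix | None,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> SummaryStatTable:
    """Greedy LD clumping keeping the most significant SNP per region.

    Repeatedly takes the remaining SNP with the smallest p-value as the index
    SNP (ties broken by chromosome, position, then id) and removes remaining
    SNPs on the same chromosome within ``window_kb`` of it whose r^2 with it
    exceeds ``r2_threshold``.  SNPs absent from ``ld`` (or all SNPs when
    ``ld`` is None) are treated as independent and logged.
    """
    if window_kb < 0:
        raise ParameterError("window_kb must be non-negative")
    if not 0 <= r2_threshold <= 1:
        raise ParameterError("r2_threshold must be in [0, 1]")

    df = table.records
    snp = df["SNP"].to_numpy()
    chrom = df["CHR"].to_numpy()
    bp = df["BP"].to_numpy(dtype=np.int64)
    pval = df["P"].to_numpy()
    order = sorted(
        range(len(df)), key=lambda i: (pval[i], chrom[i], bp[i], snp[i])
    )
    ld_idx = (
        np.array([ld._index.get(s, -1) for s in snp]) if ld is not None else None
    )
    unknown: set[str] = set()
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    window_bp = window_kb * 1000.0
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_bp)
        if ld is None:
            continue
        for j in np.flatnonzero(near):
            if ld_idx[i] < 0 or ld_idx[j] < 0:
                unknown.update({snp[i], snp[j]})
                continue
            if ld.r2[ld_idx[i], ld_idx[j]] > r2_threshold:
                alive[j] = False
    if unknown:
        logger.warning(
            "%d SNP(s) absent from the LD matrix treated as independent", len(unknown)
        )
    keep_mask = np.zeros(len(df), dtype=bool)
    keep_mask[kept] = True
    return SummaryStatTable(table.trait_label, df[keep_mask].copy())


def per_snp_r2(eaf: float, beta: float, se: float, n: float) -> float:
    """Explained-variance fraction of one SNP on the exposure.

    Evaluates the full frequency-weighted form; the 2*EAF*(1-EAF) factor
    cancels, so the value is independent of EAF, but EAF must still be
    present for the record to contribute.
    """
    if eaf is None or not np.isfinite(eaf):
        raise MissingEAFError("cannot compute R^2 without effect-allele frequency")
    if not 0 < eaf < 1:
        raise ParameterError("eaf must be in (0, 1)")
    if se <= 0 or n <= 0:
        raise ParameterError("se and n must be positive")
    var = 2.0 * eaf * (1.0 - eaf)
    return (var * beta**2) / (var * beta**2 + var * n * se**2)


def f_statistic(cumulative_r2: float, n: float, k: int) -> float:
    """Instrument-strength F for K instruments with cumulative R^2 and size N."""
    if not 0 <= cumulative_r2 < 1:
        raise ParameterError("cumulative R^2 must be in [0, 1)")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n <= k + 1:
        raise ParameterError(f"sample size N={n} must exceed K+1={k + 1}")
    return cumulative_r2 * (n - k - 1) / (k * (1 - cumulative_r2))


@dataclass
class InstrumentSet:
    """Strength summary of a selected instrument set.

    ``per_snp_r2`` is NaN where EAF was missing; such SNPs count toward K but
    cannot contribute explained variance (they are listed in
    ``missing_eaf_snps``).
    """

    snp_ids: list[str]
    per_snp_r2: np.ndarray
    cumulative_r2: float
    f_stat: float
    k: int
    n: int
    weak: bool
    missing_eaf_snps: list[str] = field(default_factory=list)

    def per_snp_f(self) -> np.ndarray:
        """Single-SNP F statistics (K=1 form), NaN where EAF was missing."""
        r = self.per_snp_r2
        return r * (self.n - 2) / (1 - r)


def build_instrument_set(table: SummaryStatTable) -> InstrumentSet:
    """Compute per-SNP and cumulative R^2 and the set-level F statistic.

    Uses the median reported per-SNP sample size as N.  Sets with F below 10
    are flagged weak (``weak=True``) rather than silently discarded.
    """
    df = table.records
    if len(df) == 0:
        raise ParameterError("cannot summarise an empty instrument set")
    r2 = np.full(len(df), np.nan)
    missing = []
    for i, row in df.reset_index(drop=True).iterrows():
        if np.isfinite(row["EAF"]):
            r2[i] = per_snp_r2(row["EAF"], row["BETA"], row["SE"], row["N"])
        else:
            missing.append(row["SNP"])
    cumulative = float(np.nansum(r2)) if np.isfinite(r2).any() else 0.0
    k = len(df)
    n = int(np.median(df["N"]))
    f = f_statistic(cumulative, n, k)
    if missing:
        logger.warning("%d instrument(s) lack EAF and contribute no R^2", len(missing))
    if f < WEAK_F_THRESHOLD:
        logger.warning("instrument set is weak: F = %.2f < %.0f", f, WEAK_F_THRESHOLD)
    return InstrumentSet(
        snp_ids=list(df["SNP"]),
        per_snp_r2=r2,
        cumulative_r2=cumulative,
        f_stat=f,
        k=k,
        n=n,
        weak=f < WEAK_F_THRESHOLD,
        missing_eaf_snps=missing,
    )
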