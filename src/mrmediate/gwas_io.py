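"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics are exchanged as tab-separated tables with the canonical
header ``SNP CHR BP EA OA EAF BETA SE P N`` (one row per variant, 1-based
positions, EA = effect allele).  A *dialect* mapping renames columns from
other conventions at read time.

Harmonization aligns every trait's per-SNP effect to the exposure's effect
allele, so a positive harmonized beta always means "per extra copy of the
exposure's effect allele".  Strand flips are resolved through allele
complements; palindromic variants (A/T, C/G) are resolved through allele
frequencies when both are informative and dropped otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default ambiguity band for palindromic variants: frequencies inside
#: [limit, 1 - limit] carry no usable strand information
DEFAULT_PALINDROMIC_EAF_LIMIT = 0.42

# per-SNP dispositions recorded during harmonization
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped-palindromic"
DROPPED_MISSING = "dropped-missing"
DROPPED_MISMATCH = "dropped-mismatch"


@dataclass
class SummaryStatTable:
    """Per-SNP association records for one trait.

    ``records`` is a DataFrame with the canonical columns; ``SNP`` values are
    unique.  ``EAF`` may be NaN (kept for estimation, unusable for R^2).
    """

    trait_label: str
    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {missing}")
        self.records = self.records[CANONICAL_COLUMNS].reset_index(drop=True)
        dup = self.records["SNP"][self.records["SNP"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate snp_id(s): {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, snp_ids) -> "SummaryStatTable":
        """Rows for ``snp_ids``, preserving this table's row order."""
        keep = self.records["SNP"].isin(set(snp_ids))
        return SummaryStatTable(self.trait_label, self.records[keep].copy())


def _row_errors(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Record-invariant violations as (file line number, message) pairs.

    Line numbers are 1-based counting the header, so the first data row is 2.
    """
    errs: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2
        if row["EA"] not in VALID_ALLELES or row["OA"] not in VALID_ALLELES:
            errs.append((line, f"invalid allele pair {row['EA']}/{row['OA']}"))
        elif row["EA"] == row["OA"]:
            errs.append((line, "effect and other allele identical"))
        if not np.isfinite(row["BETA"]):
            errs.append((line, "non-finite beta"))
        if not (np.isfinite(row["SE"]) and row["SE"] > 0):
            errs.append((line, "se must be > 0"))
        if not (np.isfinite(row["P"]) and 0 < row["P"] <= 1):
            errs.append((line, "p-value must be in (0, 1]"))
        if not (row["N"] > 0):
            errs.append((line, "sample size must be positive"))
        if not np.isnan(row["EAF"]) and not (0 < row["EAF"] < 1):
            errs.append((line, "eaf must be in (0, 1) when present"))
        if not (np.isfinite(row["BP"]) and row["BP"] >= 1):
            errs.append((line, "position must be >= 1"))
    return errs


def read_summary_stats(
    path,
    dialect: dict[str, str] | None = None,
    trait_label: str | None = None,
) -> SummaryStatTable:
    """Read a tab-separated summary-statistic file.

    Parameters
    ----------
    path
        File with a header line; columns separated by tabs.
    dialect
        Optional mapping ``{file column -> canonical column}`` for files using
        other naming conventions.
    trait_label
        Defaults to the file's stem.

    Raises
    ------
    FormatError
        A mandatory column is absent after applying the dialect.
    ValidationError
        Rows contain unparsable numbers or violate record invariants; the
        error lists the offending file line numbers.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect:
        raw = raw.rename(columns=dialect)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {missing}")
    raw = raw[CANONICAL_COLUMNS]

    df = pd.DataFrame({"SNP": raw["SNP"].astype(str), "CHR": raw["CHR"].astype(str)})
    df["EA"] = raw["EA"].str.upper()
    df["OA"] = raw["OA"].str.upper()
    bad_rows: list[int] = []
    for col in ("BP", "EAF", "BETA", "SE", "P", "N"):
        parsed = np.empty(len(raw), dtype=float)
        for i, v in enumerate(raw[col]):
            if v in ("", "NA", "nan"):
                parsed[i] = np.nan
                if col != "EAF":  # only EAF may be missing
                    bad_rows.append(i + 2)
                continue
            try:
                # float() is correctly rounded (pandas' fast parser is not)
                parsed[i] = float(v)
            except ValueError:
                parsed[i] = np.nan
                bad_rows.append(i + 2)
        df[col] = parsed
    if bad_rows:
        rows = sorted(set(bad_rows))
        raise ValidationError(f"{path}: unparsable/missing numeric values on line(s) {rows}", rows)
    df["BP"] = df["BP"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)

    errs = _row_errors(df)
    if errs:
        rows = sorted({line for line, _ in errs})
        detail = "; ".join(f"line {line}: {msg}" for line, msg in errs[:20])
        raise ValidationError(f"{path}: invalid row(s): {detail}", rows)

    label = trait_label if trait_label is not None else _stem(path)
    return SummaryStatTable(label, df)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_summary_stats(table: SummaryStatTable, path) -> None:
    """Write a table in the canonical tab-separated layout.

    Numeric fields are written with ``repr``-level precision so that
    ``read_summary_stats(write_summary_stats(t))`` reproduces every value
    bit-for-bit.
    """
    out = table.records.copy()
    for col in ("EAF", "BETA", "SE", "P"):
        out[col] = [
            "NA" if not np.isfinite(v) else repr(float(v)) for v in out[col]
        ]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def _informative(eaf: float, limit: float) -> bool:
    return np.isfinite(eaf) and (eaf < limit or eaf > 1 - limit)


def _classify(ea_x, oa_x, ea_o, oa_o, eaf_x, eaf_o, limit):
    """Orientation of one non-exposure record relative to the exposure.

    Returns ``'same'``, ``'flip'``, ``'drop-palindromic'`` or ``'mismatch'``.
    For palindromic pairs allele labels cannot distinguish a strand flip from
    an effect-allele swap, so orientation is inferred from whether the two
    frequencies sit on the same side of 0.5 (both must be informative).
    """
    if _is_palindromic(ea_x, oa_x):
        if {ea_o, oa_o} != {ea_x, oa_x}:
            return "mismatch"
        if not (_informative(eaf_x, limit) and _informative(eaf_o, limit)):
            return "drop-palindromic"
        # align the other trait's frequency to the exposure's effect allele
        # before comparing sides
        f_o = eaf_o if ea_o == ea_x else 1 - eaf_o
        same_side = (eaf_x < 0.5) == (f_o < 0.5)
        return "same" if (ea_o == ea_x) == same_side else "flip"
    if (ea_o, oa_o) == (ea_x, oa_x):
        return "same"
    if (ea_o, oa_o) == (oa_x, ea_x):
        return "flip"
    cea, coa = COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)
    if (cea, coa) == (ea_x, oa_x):
        return "same"
    if (cea, coa) == (oa_x, ea_x):
        return "flip"
    return "mismatch"


@dataclass
class HarmonizedSet:
    """Allele-aligned effect matrices across traits (exposure first).

    ``beta``, ``se``, ``eaf``, ``n``, ``pval`` are ``(n_snp, n_trait)`` arrays
    whose columns follow ``traits``.  ``drop_log`` records one disposition per
    input SNP (union over tables).
    """

    snp_ids: list[str]
    traits: list[str]
    beta: np.ndarray
    se: np.ndarray
    eaf: np.ndarray
    n: np.ndarray
    pval: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    chrom: list[str]
    pos: np.ndarray
    drop_log: pd.DataFrame = field(repr=False)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def pair(self, outcome: int | str = -1):
        """(beta_x, se_x, beta_y, se_y) for exposure vs one outcome trait."""
        j = self.traits.index(outcome) if isinstance(outcome, str) else outcome
        return self.beta[:, 0], self.se[:, 0], self.beta[:, j], self.se[:, j]

    def subset(self, keep) -> "HarmonizedSet":
        """Restrict to a boolean mask or an iterable of snp_ids."""
        if not isinstance(keep, np.ndarray) or keep.dtype != bool:
            wanted = set(keep)
            keep = np.array([s in wanted for s in self.snp_ids])
        idx = np.flatnonzero(keep)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            traits=list(self.traits),
            beta=self.beta[idx],
            se=self.se[idx],
            eaf=self.eaf[idx],
            n=self.n[idx],
            pval=self.pval[idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            other_allele=[self.other_allele[i] for i in idx],
            chrom=[self.chrom[i] for i in idx],
            pos=self.pos[idx],
            drop_log=self.drop_log,
        )

    def to_tables(self) -> list[SummaryStatTable]:
        """Rebuild one canonical table per trait from the aligned arrays."""
        out = []
        for j, label in enumerate(self.traits):
            df = pd.DataFrame(
                {
                    "SNP": self.snp_ids,
                    "CHR": self.chrom,
                    "BP": self.pos,
                    "EA": self.effect_allele,
                    "OA": self.other_allele,
                    "EAF": self.eaf[:, j],
                    "BETA": self.beta[:, j],
                    "SE": self.se[:, j],
                    "P": self.pval[:, j],
                    "N": self.n[:, j].astype(np.int64),
                }
            )
            out.append(SummaryStatTable(label, df))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (one row per SNP x trait)."""
        rows = []
        for j, label in enumerate(self.traits):
            rows.append(
                pd.DataFrame(
                    {
                        "SNP": self.snp_ids,
                        "trait": label,
                        "EA": self.effect_allele,
                        "OA": self.other_allele,
                        "EAF": self.eaf[:, j],
                        "BETA": self.beta[:, j],
                        "SE": self.se[:, j],
                        "P": self.pval[:, j],
                        "N": self.n[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def harmonize(
    exposure: SummaryStatTable,
    others: list[SummaryStatTable],
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
) -> HarmonizedSet:
    """Align all traits to the exposure's effect allele.

    SNPs are matched by id on the intersection of all tables.  A non-exposure
    record whose alleles are swapped (directly or on the complementary strand)
    has its beta negated and its EAF replaced by 1-EAF.  Palindromic SNPs are
    kept only when both frequencies are informative (outside
    ``[limit, 1-limit]``); the inferred orientation may itself be a flip.
    Allele pairs matching on neither strand drop the SNP with a recorded
    reason rather than raising.
    """
    if not 0 < palindromic_eaf_limit <= 0.5:
        raise ValueError("palindromic_eaf_limit must be in (0, 0.5]")
    tables = [exposure] + list(others)
    indexed = [
        {r.SNP: r for r in t.records.itertuples(index=False)} for t in tables
    ]
    union: list[str] = []
    seen = set()
    for t in tables:
        for s in t.records["SNP"]:
            if s not in seen:
                seen.add(s)
                union.append(s)
    in_all = set.intersection(*(set(ix) for ix in indexed))

    disposition: dict[str, str] = {}
    kept_rows = []
    for snp in exposure.records["SNP"]:
        if snp not in in_all:
            continue
        ex = indexed[0][snp]
        row_beta = [ex.BETA]
        row_se = [ex.SE]
        row_eaf = [ex.EAF]
        row_n = [ex.N]
        row_p = [ex.P]
        flipped_any = False
        verdict = KEPT
        for ix in indexed[1:]:
            rec = ix[snp]
            action = _classify(
                ex.EA, ex.OA, rec.EA, rec.OA,
                ex.EAF, rec.EAF, palindromic_eaf_limit,
            )
            if action == "mismatch":
                verdict = DROPPED_MISMATCH
                break
            if action == "drop-palindromic":
                verdict = DROPPED_PALINDROMIC
                break
            if action == "flip":
                flipped_any = True
                row_beta.append(-rec.BETA)
                row_eaf.append(1 - rec.EAF if np.isfinite(rec.EAF) else np.nan)
            else:
                row_beta.append(rec.BETA)
                row_eaf.append(rec.EAF)
            row_se.append(rec.SE)
            row_n.append(rec.N)
            row_p.append(rec.P)
        if verdict in (DROPPED_MISMATCH, DROPPED_PALINDROMIC):
            disposition[snp] = verdict
            continue
        disposition[snp] = FLIPPED if flipped_any else KEPT
        kept_rows.append((snp, ex, row_beta, row_se, row_eaf, row_n, row_p))

    for snp in union:
        if snp not in disposition:
            disposition[snp] = DROPPED_MISSING

    n_kept = len(kept_rows)
    n_traits = len(tables)
    beta = np.empty((n_kept, n_traits))
    se = np.empty_like(beta)
    eaf = np.empty_like(beta)
    nn = np.empty_like(beta)
    pv = np.empty_like(beta)
    snp_ids, ea, oa, chrom, pos = [], [], [], [], []
    for i, (snp, ex, rb, rs, rf, rn, rp) in enumerate(kept_rows):
        beta[i] = rb
        se[i] = rs
        eaf[i] = rf
        nn[i] = rn
        pv[i] = rp
        snp_ids.append(snp)
        ea.append(ex.EA)
        oa.append(ex.OA)
        chrom.append(ex.CHR)
        pos.append(int(ex.BP))

    drop_log = pd.DataFrame(
        {"SNP": union, "disposition": [disposition[s] for s in union]}
    )
    logger.info(
        "harmonized %d trait(s) against %s: %d kept, %d dropped",
        len(others), exposure.trait_label, n_kept, len(union) - n_kept,
    )
    return HarmonizedSet(
        snp_ids=snp_ids,
        traits=[t.trait_label for t in tables],
        beta=beta,
        se=se,
        eaf=eaf,
        n=nn,
        pval=pv,
        effect_allele=ea,
        other_allele=oa,
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64),
        drop_log=drop_log,
    )
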