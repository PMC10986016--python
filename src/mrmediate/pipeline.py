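"""Study orchestration: total effect -> mediator effects -> MVMR -> mediation.

``run_two_step`` executes, per outcome:

1. instrument selection on the exposure (p < threshold, LD clumping, F),
   harmonization, and total-effect estimation with the configured estimator
   suite plus the full diagnostic panel;
2. per mediator: exposure->mediator estimation (beta1), multivariable MR for
   the mediator's direct effect (beta2), and the product-of-coefficients
   mediation decomposition;
3. Benjamini-Hochberg adjustment of the mediation p-values (per outcome
   family by default);
4. an automatic outlier-removal pass (MR-PRESSO detect -> remove ->
   re-estimate -> re-test the Egger intercept) when the Egger intercept is
   significant at 0.05, mirroring the detect/remove/re-estimate sequence of
   pleiotropy-affected analyses.  ``outlier_pass`` can force or suppress it.

``run_reverse_mr`` swaps each mediator into the exposure role against the
original exposure as outcome and runs univariable estimation only.

Every number in the report comes from a module operation; the orchestrator
only routes data.  Reports embed a provenance block (config hash, seed,
package version) and are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import DEFAULT_N_BOOT, all_estimates, ivw
from .exceptions import ParameterError, PipelineStageError
from .gwas_io import (
    DEFAULT_PALINDROMIC_EAF_LIMIT,
    HarmonizedSet,
    SummaryStatTable,
    harmonize,
    read_summary_stats,
)
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_KB,
    DEFAULT_P_THRESHOLD,
    LDMatrix,
    build_instrument_set,
    ld_clump,
    select_by_pvalue,
)
from .mediation import CoefficientTriple, bh_adjust, mediate, mediation_table
from .mvmr import MVMRResult, mvmr_ivw
from .sensitivity import (
    DEFAULT_LOO_FLAG_MULTIPLIER,
    DEFAULT_PRESSO_N_SIM,
    DEFAULT_PRESSO_SIG,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
    rucker_q,
)

logger = logging.getLogger(__name__)

ALL_METHODS = ["IVW", "Egger", "weighted-median", "simple-mode", "weighted-mode", "RAPS"]


@dataclass
class StudyConfig:
    """Paths and parameters of one two-step study."""

    exposure: str
    outcomes: list[str] = field(default_factory=list)
    mediators: list[str] = field(default_factory=list)
    ld_matrix: str | None = None
    ld_positions: str | None = None
    outdir: str = "mrmediate-out"
    seed: int = 0
    dialect: dict[str, str] | None = None
    # module parameters
    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_kb: float = DEFAULT_CLUMP_WINDOW_KB
    f_min: float = 10.0
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT
    ivw_model: str = "multiplicative-random"
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    n_boot: int = DEFAULT_N_BOOT
    mode_bandwidth_factor: float = 1.0
    raps_robust: bool = False
    raps_overdispersion: bool = False
    presso_n_sim: int = DEFAULT_PRESSO_N_SIM
    presso_sig: float = DEFAULT_PRESSO_SIG
    loo_flag_multiplier: float = DEFAULT_LOO_FLAG_MULTIPLIER
    outlier_pass: str = "auto"  # auto | always | never
    bh_scope: str = "per-outcome"  # per-outcome | global
    run_presso: bool = True

    def __post_init__(self):
        if self.outlier_pass not in ("auto", "always", "never"):
            raise ParameterError("outlier_pass must be auto, always or never")
        if self.bh_scope not in ("per-outcome", "global"):
            raise ParameterError("bh_scope must be per-outcome or global")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ParameterError(f"unknown method(s): {sorted(unknown)}")
        if self.raps_robust or self.raps_overdispersion:
            raise ParameterError(
                "raps_robust/raps_overdispersion are reserved flags; only the "
                "simple profile-score RAPS variant is implemented"
            )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ParameterError(f"unknown config key(s): {sorted(extra)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All per-pair outputs plus provenance."""

    direction: str  # "forward" | "reverse"
    instruments: pd.DataFrame
    estimates: pd.DataFrame
    diagnostics: pd.DataFrame
    mvmr: pd.DataFrame
    mediation: pd.DataFrame
    snp_counts: pd.DataFrame
    errors: list[dict]
    provenance: dict

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name in ("instruments", "estimates", "diagnostics", "mvmr",
                     "mediation", "snp_counts"):
            getattr(self, name).to_csv(
                os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False
            )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "provenance": self.provenance,
            "errors": self.errors,
        }
        for name in ("instruments", "estimates", "diagnostics", "mvmr",
                     "mediation", "snp_counts"):
            d[name] = getattr(self, name).to_dict(orient="records")
        return d


def _load(path, cfg: StudyConfig) -> SummaryStatTable:
    return read_summary_stats(path, dialect=cfg.dialect)


def _select_instruments(table: SummaryStatTable, ld: LDMatrix | None, cfg: StudyConfig):
    """Significance filter + clumping; returns (subset table, count log)."""
    sig = select_by_pvalue(table, cfg.p_threshold)
    clumped = ld_clump(sig, ld, cfg.clump_r2, cfg.clump_window_kb)
    counts = {
        "trait": table.trait_label,
        "input": len(table),
        "selected": len(sig),
        "clumped": len(clumped),
    }
    logger.info(
        "%s: %d SNPs -> %d significant -> %d after clumping",
        table.trait_label, len(table), len(sig), len(clumped),
    )
    return clumped, counts


def _univariable(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    ld: LDMatrix | None,
    cfg: StudyConfig,
    seed: int,
):
    """Instrument selection, harmonization, estimation and diagnostics for
    one exposure->outcome pair.  Returns a dict of stage outputs."""
    pair = f"{exposure.trait_label}->{outcome.trait_label}"
    selected, counts = _select_instruments(exposure, ld, cfg)
    inst = build_instrument_set(selected)
    h = harmonize(selected, [outcome], cfg.palindromic_eaf_limit)
    counts["harmonized"] = h.n_snp

    estimates = all_estimates(
        h,
        methods=cfg.methods,
        ivw_model=cfg.ivw_model,
        n_boot=cfg.n_boot,
        seed=seed,
        mode_bandwidth_factor=cfg.mode_bandwidth_factor,
    )
    diagnostics = {}
    if h.n_snp >= 2:
        diagnostics["cochran_q"] = cochran_q(h)
    if h.n_snp >= 3:
        diagnostics["rucker_q"] = rucker_q(h)
        diagnostics["egger_intercept"] = egger_intercept_test(h)
        diagnostics["leave_one_out"] = leave_one_out(h, cfg.loo_flag_multiplier)
    presso = None
    if cfg.run_presso and h.n_snp >= 4:
        presso = mr_presso(h, cfg.presso_n_sim, cfg.presso_sig, seed=seed)

    # automatic detect -> remove -> re-estimate -> re-test pass
    post = None
    intercept = diagnostics.get("egger_intercept")
    trigger = cfg.outlier_pass == "always" or (
        cfg.outlier_pass == "auto"
        and intercept is not None
        and intercept.pvalue < 0.05
    )
    if trigger and presso is not None and len(presso.outlier_snps):
        removed = set(presso.outlier_snps["SNP"])
        keep = np.array([s not in removed for s in h.snp_ids])
        h_post = h.subset(keep)
        post = {
            "removed": sorted(removed),
            "ivw": ivw(h_post, model=cfg.ivw_model),
            "egger_intercept": (
                egger_intercept_test(h_post) if h_post.n_snp >= 3 else None
            ),
            "n_snp": h_post.n_snp,
        }
        counts["post_presso"] = h_post.n_snp
        logger.info("%s: removed %d outlier SNP(s)", pair, len(removed))

    return {
        "pair": pair,
        "exposure": exposure.trait_label,
        "outcome": outcome.trait_label,
        "instrument_set": inst,
        "selected": selected,
        "harmonized": h,
        "estimates": estimates,
        "diagnostics": diagnostics,
        "presso": presso,
        "post_outlier": post,
        "counts": counts,
    }


def _total_ivw(res: dict):
    """Total-effect IVW, preferring the post-outlier re-estimate if one ran."""
    if res["post_outlier"] is not None:
        return res["post_outlier"]["ivw"]
    return next(e for e in res["estimates"] if e.method == "IVW")


def _estimates_rows(res: dict) -> list[dict]:
    rows = []
    for e in res["estimates"]:
        rows.append({"exposure": res["exposure"], "outcome": res["outcome"],
                     "pass": "primary", **e.to_dict()})
    if res["post_outlier"] is not None:
        rows.append(
            {"exposure": res["exposure"], "outcome": res["outcome"],
             "pass": "post-outlier", **res["post_outlier"]["ivw"].to_dict()}
        )
    return rows


def _diagnostics_rows(res: dict) -> list[dict]:
    rows = []
    base = {"exposure": res["exposure"], "outcome": res["outcome"]}
    d = res["diagnostics"]
    for key in ("cochran_q", "rucker_q"):
        if key in d:
            het = d[key]
            rows.append({**base, "diagnostic": het.flavor, "statistic": het.statistic,
                         "df": het.df, "pvalue": het.pvalue})
    if "egger_intercept" in d:
        pl = d["egger_intercept"]
        rows.append({**base, "diagnostic": "egger-intercept", "statistic": pl.intercept,
                     "se": pl.se, "pvalue": pl.pvalue})
    if res["presso"] is not None:
        pr = res["presso"]
        rows.append({**base, "diagnostic": "presso-global", "statistic": pr.global_rss,
                     "pvalue": pr.global_pvalue,
                     "n_outliers": len(pr.outlier_snps),
                     "distortion_pvalue": pr.distortion_pvalue})
    if "leave_one_out" in d:
        loo = d["leave_one_out"]
        rows.append({**base, "diagnostic": "leave-one-out",
                     "n_flagged": int(loo.table["flagged"].sum())})
    if res["post_outlier"] is not None and res["post_outlier"]["egger_intercept"]:
        pl = res["post_outlier"]["egger_intercept"]
        rows.append({**base, "diagnostic": "egger-intercept-post-outlier",
                     "statistic": pl.intercept, "se": pl.se, "pvalue": pl.pvalue})
    return rows


def _provenance(cfg: StudyConfig) -> dict:
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package": "mrmediate",
        "version": __version__,
    }


def _load_ld(cfg: StudyConfig) -> LDMatrix | None:
    if cfg.ld_matrix is None:
        return None
    return LDMatrix.read_tsv(cfg.ld_matrix, cfg.ld_positions)


def run_two_step(
    cfg: StudyConfig,
    exposure_table: SummaryStatTable | None = None,
    outcome_tables: list[SummaryStatTable] | None = None,
    mediator_tables: list[SummaryStatTable] | None = None,
    ld: LDMatrix | None = None,
) -> StudyReport:
    """Run the full two-step mediation workflow.

    Tables may be passed in memory (tests, simulations); otherwise they are
    read from the paths in ``cfg``.  Stage failures are recorded per pair in
    ``report.errors`` and do not abort the remaining pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    exposure = exposure_table or _load(cfg.exposure, cfg)
    outcomes = outcome_tables or [_load(p, cfg) for p in cfg.outcomes]
    mediators = mediator_tables or [_load(p, cfg) for p in cfg.mediators]
    if ld is None:
        ld = _load_ld(cfg)

    inst_rows, est_rows, diag_rows, mvmr_rows, count_rows = [], [], [], [], []
    mediation_results = []
    errors: list[dict] = []

    # beta1 per mediator is outcome-independent; compute once
    beta1: dict[str, tuple[float, float]] = {}
    med_results_cache: dict[str, dict] = {}
    for med in mediators:
        seed = int(rng.integers(2**31))
        try:
            res = _univariable(exposure, med, ld, cfg, seed)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            errors.append({"stage": "exposure->mediator", "pair": med.trait_label,
                           "error": str(exc)})
            continue
        med_results_cache[med.trait_label] = res
        est = _total_ivw(res)
        beta1[med.trait_label] = (est.beta, est.se)
        est_rows += _estimates_rows(res)
        diag_rows += _diagnostics_rows(res)
        count_rows.append(res["counts"])
        inst_rows.append(_inst_row(res))

    for out_table in outcomes:
        seed = int(rng.integers(2**31))
        try:
            res = _univariable(exposure, out_table, ld, cfg, seed)
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "total-effect", "pair": out_table.trait_label,
                           "error": str(exc)})
            continue
        total = _total_ivw(res)
        est_rows += _estimates_rows(res)
        diag_rows += _diagnostics_rows(res)
        count_rows.append(res["counts"])
        inst_rows.append(_inst_row(res))

        for med in mediators:
            if med.trait_label not in beta1:
                continue
            pair = f"{med.trait_label}|{out_table.trait_label}"
            try:
                mv = _mvmr_beta2(exposure, med, out_table, ld, cfg)
            except Exception as exc:  # noqa: BLE001
                errors.append({"stage": "mvmr", "pair": pair, "error": str(exc)})
                continue
            b2, se2, p2 = mv.coefficient(med.trait_label)
            bx, sx = mv.coefficient(exposure.trait_label)[0:2]
            mvmr_rows.append(
                {"outcome": out_table.trait_label, "mediator": med.trait_label,
                 "beta2": b2, "se2": se2, "pvalue": p2,
                 "direct_exposure_beta": bx, "direct_exposure_se": sx,
                 "n_snp": mv.n_snp}
            )
            b1, se1 = beta1[med.trait_label]
            try:
                triple = CoefficientTriple(
                    beta0=total.beta, se0=total.se, beta1=b1, se1=se1,
                    beta2=b2, se2=se2, mediator=med.trait_label,
                    outcome=out_table.trait_label,
                )
                mediation_results.append(mediate(triple))
            except Exception as exc:  # noqa: BLE001
                errors.append({"stage": "mediation", "pair": pair, "error": str(exc)})

    med_df = mediation_table(mediation_results)
    if len(med_df):
        if cfg.bh_scope == "per-outcome":
            adj = np.empty(len(med_df))
            for out_label in med_df["outcome"].unique():
                m = med_df["outcome"] == out_label
                adj[m.to_numpy()] = bh_adjust(med_df.loc[m, "pvalue"])
            med_df["pvalue_bh"] = adj
        else:
            med_df["pvalue_bh"] = bh_adjust(med_df["pvalue"])

    return StudyReport(
        direction="forward",
        instruments=pd.DataFrame(inst_rows),
        estimates=pd.DataFrame(est_rows),
        diagnostics=pd.DataFrame(diag_rows),
        mvmr=pd.DataFrame(mvmr_rows),
        mediation=med_df,
        snp_counts=pd.DataFrame(count_rows),
        errors=errors,
        provenance=_provenance(cfg),
    )


def _inst_row(res: dict) -> dict:
    inst = res["instrument_set"]
    return {
        "exposure": res["exposure"],
        "outcome": res["outcome"],
        "k": inst.k,
        "r2_cumulative": inst.cumulative_r2,
        "f_stat": inst.f_stat,
        "weak": inst.weak,
    }


def _mvmr_beta2(exposure, mediator, outcome, ld, cfg) -> MVMRResult:
    """MVMR on the union of exposure and mediator instruments.

    Union SNPs must be present in all three tables; harmonization handles
    alignment and drops the rest.
    """
    exp_sel, _ = _select_instruments(exposure, ld, cfg)
    med_sel, _ = _select_instruments(mediator, ld, cfg)
    union = list(dict.fromkeys(list(exp_sel.records["SNP"]) + list(med_sel.records["SNP"])))
    exp_sub = exposure.subset(union)
    med_sub = mediator.subset(union)
    out_sub = outcome.subset(union)
    h = harmonize(exp_sub, [med_sub, out_sub], cfg.palindromic_eaf_limit)
    return mvmr_ivw(h, model=cfg.ivw_model)


def run_reverse_mr(
    cfg: StudyConfig,
    exposure_table: SummaryStatTable | None = None,
    mediator_tables: list[SummaryStatTable] | None = None,
    ld: LDMatrix | None = None,
) -> StudyReport:
    """Reverse-direction univariable MR: each mediator -> original exposure."""
    rng = np.random.default_rng(cfg.seed)
    exposure = exposure_table or _load(cfg.exposure, cfg)
    mediators = mediator_tables or [_load(p, cfg) for p in cfg.mediators]
    if ld is None:
        ld = _load_ld(cfg)

    inst_rows, est_rows, diag_rows, count_rows = [], [], [], []
    errors: list[dict] = []
    for med in mediators:
        seed = int(rng.integers(2**31))
        try:
            res = _univariable(med, exposure, ld, cfg, seed)
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "reverse", "pair": med.trait_label,
                           "error": str(exc)})
            continue
        est_rows += _estimates_rows(res)
        diag_rows += _diagnostics_rows(res)
        count_rows.append(res["counts"])
        inst_rows.append(_inst_row(res))

    return StudyReport(
        direction="reverse",
        instruments=pd.DataFrame(inst_rows),
        estimates=pd.DataFrame(est_rows),
        diagnostics=pd.DataFrame(diag_rows),
        mvmr=pd.DataFrame(),
        mediation=pd.DataFrame(),
        snp_counts=pd.DataFrame(count_rows),
        errors=errors,
        provenance=_provenance(cfg),
    )
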