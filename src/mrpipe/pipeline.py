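"""End-to-end analysis orchestration.

A declarative :class:`AnalysisPlan` names the input files and thresholds;
:func:`run_plan` executes the full graph — instrument selection, LD
clumping, proxy substitution, harmonization, univariable estimators with
optional Steiger refit, optional multivariable MR with a second exposure,
and effect-scale conversion — and emits tab-delimited result tables plus a
run manifest (all parameters, seed, package version) sufficient to re-run
the plan and reproduce its outputs byte-identically.

Every excluded variant (clump, failed proxy, palindrome, Steiger) is
logged with its ID and reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from mrpipe._version import __version__ as _version
from mrpipe.errors import ConfigurationError, DataError, MRPipeError
from mrpipe.harmonize import HarmonizedSet, harmonize
from mrpipe.mvmr import mvmr_ivw, mvmr_robust
from mrpipe.scale import ScaleSpec, doubling_effect, or_ci_from_log_scale, round_report
from mrpipe.sumstats import (LDTable, SummaryStats, clump, find_proxy,
                             read_sumstats, select_instruments)
from mrpipe.uvmr import (MREstimate, egger, egger_simex, ivw, mr_raps,
                         per_snp_f, steiger_filter, weighted_median,
                         weighted_mode)

logger = logging.getLogger(__name__)

_METHOD_MIN_SNPS = {"ivw": 1, "egger": 3, "egger_simex": 3, "wmedian": 3,
                    "wmode": 3, "raps": 3}


@dataclass
class AnalysisPlan:
    """Declarative description of one MR analysis.

    File references point at tab-delimited summary statistics (and a
    three-column LD table); ``second_exposure`` switches on multivariable
    MR.  ``n_exposure``/``n_outcome`` are the GWAS sample sizes used by
    Steiger filtering (when absent they are taken from the files' N
    column).  The plan round-trips losslessly through YAML.
    """

    exposure: str
    outcome: str
    ld: Optional[str] = None
    second_exposure: Optional[str] = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_kb: int = 10_000
    proxy_r2: float = 0.9
    methods: list[str] = field(default_factory=lambda: ["ivw", "egger", "wmedian",
                                                        "wmode", "raps"])
    steiger: bool = False
    robust: bool = False
    exposure_binary: bool = False
    outcome_binary: bool = False
    n_exposure: Optional[int] = None
    n_outcome: Optional[int] = None
    eaf_available: bool = False
    outcome_sd_years: Optional[float] = None
    time_unit: str = "months"
    boot_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if not (0.0 < self.clump_r2 < 1.0) or self.clump_kb <= 0:
            raise ConfigurationError("invalid clumping parameters")
        if not (0.0 < self.proxy_r2 < 1.0):
            raise ConfigurationError("proxy_r2 must lie in (0, 1)")
        unknown = set(self.methods) - set(_METHOD_MIN_SNPS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisPlan":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigurationError(f"unknown plan fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage(name: str):
    """Decorator: re-raise pipeline errors tagged with the failing stage."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MRPipeError as exc:
                exc.stage = name
                if not str(exc).startswith("[stage:"):
                    exc.args = (f"[stage:{name}] {exc}",)
                raise
        return inner
    return wrap


def _estimate(method: str, h: HarmonizedSet, boot_reps: int, seed: int) -> MREstimate:
    if method == "ivw":
        return ivw(h)
    if method == "egger":
        return egger(h)
    if method == "egger_simex":
        return egger_simex(h, seed=seed)
    if method == "wmedian":
        return weighted_median(h, boot_reps=boot_reps, seed=seed)
    if method == "wmode":
        return weighted_mode(h, boot_reps=boot_reps, seed=seed)
    if method == "raps":
        return mr_raps(h)
    raise ConfigurationError(f"unknown method {method!r}")


def _estimator_table(h: HarmonizedSet, methods, boot_reps, seed) -> pd.DataFrame:
    rows = []
    for m in methods:
        if h.n_snps < _METHOD_MIN_SNPS[m]:
            rows.append({"method": m, "n_snps": h.n_snps, "beta": np.nan,
                         "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "pvalue": np.nan, "intercept": np.nan, "intercept_se": np.nan,
                         "intercept_pvalue": np.nan, "Q": np.nan, "Q_df": np.nan,
                         "Q_pvalue": np.nan, "status": "not_estimable"})
            continue
        row = _estimate(m, h, boot_reps, seed).to_row()
        row["method"] = m  # plan-level key, stable across estimator labels
        row["status"] = "ok"
        rows.append(row)
    return pd.DataFrame(rows)


def _sample_size(ss: SummaryStats, override: Optional[int], side: str) -> int:
    if override is not None:
        return int(override)
    n = ss.table["n"].dropna()
    if n.empty:
        raise ConfigurationError(
            f"Steiger filtering needs the {side} sample size: set it in the plan "
            f"or provide an N column")
    return int(n.median())


@_stage("steiger_refit")
def steiger_refit(plan: AnalysisPlan, h: HarmonizedSet,
                  n_exposure: int, n_outcome: int) -> dict:
    """Estimators on the full vs the Steiger-filtered set, with attenuation.

    Returns the filtered set, the per-variant Steiger report, and a
    comparison table carrying the difference and ratio of betas per method.
    Methods that fall below their instrument minimum on the filtered set
    are recorded as not estimable rather than aborting.
    """
    filtered, report = steiger_filter(h, n_exposure, n_outcome,
                                      plan.exposure_binary, plan.outcome_binary)
    full_tab = _estimator_table(h, plan.methods, plan.boot_reps, plan.seed)
    filt_tab = _estimator_table(filtered, plan.methods, plan.boot_reps, plan.seed)
    cmp = full_tab[["method", "beta", "se"]].merge(
        filt_tab[["method", "beta", "se", "status"]], on="method",
        suffixes=("_full", "_filtered"))
    cmp["beta_diff"] = cmp["beta_filtered"] - cmp["beta_full"]
    cmp["beta_ratio"] = cmp["beta_filtered"] / cmp["beta_full"]
    return {"filtered": filtered, "report": report, "comparison": cmp,
            "filtered_table": filt_tab}


@_stage("instruments")
def _instrument_stage(plan: AnalysisPlan, exposure: SummaryStats,
                      ld: LDTable) -> tuple[SummaryStats, list[dict]]:
    log: list[dict] = []
    selected = select_instruments(exposure, plan.p_threshold)
    for vid in set(exposure.variant_ids) - set(selected.variant_ids):
        log.append({"variant_id": vid, "stage": "selection",
                    "action": "dropped", "reason": "pvalue_above_threshold"})
    clumped = clump(selected, ld, plan.clump_r2, plan.clump_kb)
    for vid in set(selected.variant_ids) - set(clumped.variant_ids):
        log.append({"variant_id": vid, "stage": "clump",
                    "action": "dropped", "reason": "ld_with_better_instrument"})
    if len(clumped) == 0:
        raise DataError("no instruments survive selection and clumping")
    return clumped, log


@_stage("proxy")
def _proxy_stage(plan: AnalysisPlan, instruments: SummaryStats,
                 exposure_full: SummaryStats, outcome: SummaryStats,
                 ld: LDTable) -> tuple[SummaryStats, list[dict]]:
    """Replace instruments missing from the outcome by their best LD proxy.

    A proxy must be present in both the (full) exposure and the outcome with
    r2 above the plan threshold; failed lookups drop the instrument.
    """
    log: list[dict] = []
    outcome_ids = set(outcome.variant_ids)
    exposure_ids = set(exposure_full.variant_ids)
    keep_rows = []
    for vid in instruments.variant_ids:
        if vid in outcome_ids:
            keep_rows.append(exposure_full.get(vid))
            continue
        candidates = outcome.subset(outcome_ids & exposure_ids)
        proxy = find_proxy(vid, candidates, ld, plan.proxy_r2)
        if proxy is None:
            log.append({"variant_id": vid, "stage": "proxy", "action": "dropped",
                        "reason": "absent_from_outcome_no_proxy"})
        else:
            log.append({"variant_id": vid, "stage": "proxy", "action": "substituted",
                        "reason": f"proxy={proxy},r2={ld.r2(vid, proxy):.3f}"})
            keep_rows.append(exposure_full.get(proxy))
    if not keep_rows:
        raise DataError("no instruments remain after proxy resolution")
    table = pd.DataFrame(keep_rows).reset_index(drop=True)
    return SummaryStats(instruments.trait_id, table), log


@_stage("harmonize")
def _harmonize_stage(plan: AnalysisPlan, exposures, outcome) -> HarmonizedSet:
    h = harmonize(exposures, outcome, eaf_available=plan.eaf_available)
    for vid, reason in h.exclusions:
        logger.info("harmonize: excluded %s (%s)", vid, reason)
    return h


def _scale_table(plan: AnalysisPlan, table: pd.DataFrame) -> Optional[pd.DataFrame]:
    """Convert estimator rows to reporting units where the plan allows it."""
    if plan.outcome_binary:
        rows = []
        for r in table.itertuples(index=False):
            if not np.isfinite(r.beta):
                continue
            or_point = float(np.exp(r.beta))
            lo, hi = or_ci_from_log_scale(or_point, float(r.se))
            rows.append({"method": r.method, "unit": "odds_ratio_per_sd",
                         "value": or_point, "ci_low": lo, "ci_high": hi,
                         "value_rounded": round_report(or_point, "or"),
                         "ci_low_rounded": round_report(lo, "or"),
                         "ci_high_rounded": round_report(hi, "or")})
        return pd.DataFrame(rows) if rows else None
    if plan.exposure_binary and plan.outcome_sd_years is not None:
        spec = ScaleSpec(exposure_type="binary_liability", outcome_type="continuous_sd",
                         outcome_sd_years=plan.outcome_sd_years,
                         time_unit=plan.time_unit)
        rows = []
        for r in table.itertuples(index=False):
            if not np.isfinite(r.beta):
                continue
            val = doubling_effect(float(r.beta), spec)
            lo = doubling_effect(float(r.ci_low), spec)
            hi = doubling_effect(float(r.ci_high), spec)
            rows.append({"method": r.method,
                         "unit": f"{plan.time_unit}_per_liability_doubling",
                         "value": val, "ci_low": lo, "ci_high": hi,
                         "value_rounded": round_report(val, plan.time_unit),
                         "ci_low_rounded": round_report(lo, plan.time_unit),
                         "ci_high_rounded": round_report(hi, plan.time_unit)})
        return pd.DataFrame(rows) if rows else None
    return None


def run_plan(plan: AnalysisPlan, outdir: Optional[str | Path] = None) -> dict:
    """Execute an analysis plan; return (and optionally write) the report bundle.

    The bundle maps table names to DataFrames (``results``, ``strength``,
    ``harmonization_report``, ``instrument_log``, plus ``steiger_*`` and
    ``mvmr_results`` when enabled) and includes the run ``manifest``.  Any
    stage failure raises the original error class tagged with the stage
    name.
    """
    exposure = read_sumstats(plan.exposure)
    outcome = read_sumstats(plan.outcome)
    ld = LDTable.read(plan.ld, window_kb=plan.clump_kb) if plan.ld else LDTable(
        window_kb=plan.clump_kb)

    instruments, log = _instrument_stage(plan, exposure, ld)
    instruments, proxy_log = _proxy_stage(plan, instruments, exposure, outcome, ld)
    log.extend(proxy_log)
    h = _harmonize_stage(plan, [instruments], outcome)
    for vid, reason in h.exclusions:
        log.append({"variant_id": vid, "stage": "harmonize",
                    "action": "dropped", "reason": reason})

    strength = per_snp_f(h)
    results = _estimator_table(h, plan.methods, plan.boot_reps, plan.seed)
    bundle: dict = {
        "results": results,
        "strength": pd.DataFrame({
            "variant_id": list(strength.per_snp_f),
            "F": list(strength.per_snp_f.values()),
        }),
        "harmonization_report": h.exclusion_report(),
        "harmonized": h,
    }

    if plan.steiger:
        n_exp = _sample_size(exposure, plan.n_exposure, "exposure")
        n_out = _sample_size(outcome, plan.n_outcome, "outcome")
        refit = steiger_refit(plan, h, n_exp, n_out)
        bundle["steiger_report"] = refit["report"]
        bundle["steiger_comparison"] = refit["comparison"]
        bundle["steiger_filtered_results"] = refit["filtered_table"]
        for r in refit["report"].itertuples(index=False):
            if not r.kept:
                log.append({"variant_id": r.variant_id, "stage": "steiger",
                            "action": "dropped", "reason": "explains_more_outcome_variance"})

    if plan.second_exposure:
        second = read_sumstats(plan.second_exposure)
        bundle["mvmr_results"] = _mvmr_stage(plan, exposure, second, outcome, ld)

    scaled = _scale_table(plan, results)
    if scaled is not None:
        bundle["scaled_results"] = scaled

    bundle["instrument_log"] = pd.DataFrame(
        log, columns=["variant_id", "stage", "action", "reason"])
    manifest = {"plan": plan.to_dict(), "version": _version,
                "n_instruments": h.n_snps,
                "mean_F": strength.mean_f}
    bundle["manifest"] = manifest

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


@_stage("mvmr")
def _mvmr_stage(plan: AnalysisPlan, exposure: SummaryStats, second: SummaryStats,
                outcome: SummaryStats, ld: LDTable) -> pd.DataFrame:
    """Joint-instrument multivariable MR.

    Instruments significant for either exposure are pooled, jointly
    clumped, and harmonized across both exposures and the outcome.
    """
    sel1 = select_instruments(exposure, plan.p_threshold)
    sel2 = select_instruments(second, plan.p_threshold)
    pooled_ids = list(dict.fromkeys(sel1.variant_ids + sel2.variant_ids))
    # pool on the primary exposure's records; variants only instrumenting the
    # second exposure are taken from its file
    rows = []
    have1 = set(exposure.variant_ids)
    for vid in pooled_ids:
        src = exposure if vid in have1 else second
        rows.append(src.get(vid))
    pooled = SummaryStats("pooled", pd.DataFrame(rows).reset_index(drop=True))
    # joint clump ranks by the better of the two exposures' p-values
    best_p = {}
    for ss in (sel1, sel2):
        for vid, p in zip(ss.variant_ids, ss.table["pvalue"]):
            best_p[vid] = min(best_p.get(vid, 1.0), float(p))
    pooled.table["pvalue"] = [best_p[v] for v in pooled.variant_ids]
    clumped = clump(pooled, ld, plan.clump_r2, plan.clump_kb)
    exp1 = exposure.subset(clumped.variant_ids)
    exp2 = second.subset(clumped.variant_ids)
    h = harmonize([exp1, exp2], outcome, eaf_available=plan.eaf_available)
    if plan.robust:
        res = mvmr_robust(h, boot_reps=plan.boot_reps, seed=plan.seed)
    else:
        res = mvmr_ivw(h)
    rows = res.to_rows()
    model_row = {"exposure_id": "_model", "direct_beta": np.nan, "se": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "pvalue": res.q_a.pvalue,
                 "conditional_F": np.nan, "Q_a": res.q_a.Q, "Q_df": res.q_a.df}
    table = pd.DataFrame(rows + [model_row])
    return table


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                       float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1, sort_keys=True)
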