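"""Multi-exposure MR screen: orchestration, tiering, and report export.

One exposure runs through instrument selection → LD clumping → proxy
substitution → harmonization → the estimator applicability matrix (IVW at
J ≥ 2; Egger and the medians at J ≥ 3; MR-PRESSO at J ≥ 4) → diagnostics.
Study-level significance uses Bonferroni tiers over the k analyzable
exposures: p < alpha/k is significant, alpha/k ≤ p < alpha suggestive.

All randomness derives from the single study seed: exposure i uses
``numpy.random.SeedSequence(seed, spawn_key=(i,))``, whose first four
32-bit words seed the simple median, weighted median, MR-PRESSO and any
auxiliary draw, so any exposure can be recomputed independently of the
others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from .instruments import (
    InstrumentStrength,
    LDMatrix,
    SelectionCriteria,
    select_instruments,
    ld_clump,
    strength_summary,
)
from .summstats import (
    AssociationTable,
    HarmonizationLog,
    HarmonizedInstrument,
    apply_proxies,
    harmonize,
    read_association_table,
    read_proxy_map,
)

logger = logging.getLogger(__name__)

TIERS = ("significant", "suggestive", "null", "unanalyzable")


@dataclass
class ExposureSpec:
    name: str
    path: str
    unit: str = "sd"
    n: int | None = None
    sd: float = 1.0


@dataclass
class OutcomeSpec:
    name: str
    path: str
    n: int | None = None


@dataclass
class StudyConfig:
    exposures: list[ExposureSpec]
    outcome: OutcomeSpec
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    seed: int = 0
    n_boot: int = 1000
    n_sim: int = 5000
    alpha: float = 0.05
    palindrome_policy: str = "infer"
    ld_matrix: str | None = None
    proxy_map: str | None = None
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        crit = SelectionCriteria(**raw.get("criteria", {}))
        return cls(
            exposures=[ExposureSpec(**e) for e in raw["exposures"]],
            outcome=OutcomeSpec(**raw["outcome"]),
            criteria=crit,
            seed=int(raw.get("seed", 0)),
            n_boot=int(raw.get("n_boot", 1000)),
            n_sim=int(raw.get("n_sim", 5000)),
            alpha=float(raw.get("alpha", 0.05)),
            palindrome_policy=raw.get("palindrome_policy", "infer"),
            ld_matrix=raw.get("ld_matrix"),
            proxy_map=raw.get("proxy_map"),
            base_dir=path.parent,
        )


@dataclass
class ExposureReport:
    """Everything the study tables need for one exposure."""

    name: str
    n_instruments: int
    estimates: dict[str, est.MREstimate] = field(default_factory=dict)
    strength: InstrumentStrength | None = None
    heterogeneity: diag.HeterogeneityResult | None = None
    egger_fit: est.EggerFit | None = None
    presso: diag.PressoResult | None = None
    steiger: diag.SteigerResult | None = None
    loo: list[diag.LooRecord] | None = None
    tier: str = "unanalyzable"
    fallback_threshold: bool = False
    not_applicable: list[str] = field(default_factory=list)
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def analyzable(self) -> bool:
        return self.n_instruments >= 2

    @property
    def ivw_p(self) -> float | None:
        ivw_est = self.estimates.get("ivw_mre")
        return ivw_est.pval if ivw_est else None


def _sub_seeds(study_seed: int, index: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(study_seed, spawn_key=(index,))
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def classify_tier(pval: float, k: int, alpha: float = 0.05) -> str:
    """Bonferroni tier over k exposures; the boundary p = alpha/k is
    assigned to the weaker ("suggestive") tier."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if pval < alpha / k:
        return "significant"
    if pval < alpha:
        return "suggestive"
    return "null"


def run_exposure(
    exposure: AssociationTable,
    outcome: AssociationTable,
    config: StudyConfig,
    ld: LDMatrix | None = None,
    proxy_map: dict | None = None,
    exposure_index: int = 0,
    sd: float = 1.0,
) -> ExposureReport:
    """Run the full single-exposure pipeline and collect the report."""
    seeds = _sub_seeds(config.seed, exposure_index)
    selection = select_instruments(exposure, config.criteria)
    selected = selection.table
    if ld is not None and len(selected) > 0:
        selected = ld_clump(selected, ld, config.criteria)
    if proxy_map:
        selected = apply_proxies(selected, proxy_map, outcome)
    hlog = HarmonizationLog()
    instruments = harmonize(
        selected, outcome, palindrome_policy=config.palindrome_policy, log=hlog
    )
    report = ExposureReport(
        name=exposure.trait_name,
        n_instruments=len(instruments),
        fallback_threshold=selection.fallback_used,
        instruments=instruments,
        drop_log=selection.dropped + hlog.dropped,
    )
    j = len(instruments)
    if j < config.criteria.min_ivs:
        report.tier = "unanalyzable"
        return report

    report.estimates["ivw_mre"] = est.to_odds_ratio(est.ivw(instruments, model="mre"))
    report.estimates["ivw_fe"] = est.to_odds_ratio(est.ivw(instruments, model="fe"))
    report.heterogeneity = diag.cochran_q(instruments)
    if j >= 3:
        report.egger_fit = est.egger(instruments)
        report.estimates["egger"] = est.to_odds_ratio(report.egger_fit.slope)
        report.estimates["simple_median"] = est.to_odds_ratio(
            est.simple_median(instruments, n_boot=config.n_boot, seed=seeds[0])
        )
        report.estimates["weighted_median"] = est.to_odds_ratio(
            est.weighted_median(instruments, n_boot=config.n_boot, seed=seeds[1])
        )
        report.loo = diag.leave_one_out(instruments)
    else:
        report.not_applicable += ["egger", "simple_median", "weighted_median", "leave_one_out"]
    if j >= diag.MIN_SNPS_PRESSO:
        report.presso = diag.mr_presso(instruments, n_sim=config.n_sim, seed=seeds[2])
        if report.presso.outlier_ids:
            keep = [i for i in instruments if i.snp_id not in report.presso.outlier_ids]
            report.estimates["ivw_mre_outlier_corrected"] = est.to_odds_ratio(
                est.ivw(keep, model="mre")
            )
    else:
        report.not_applicable.append("mr_presso")
    try:
        report.steiger = diag.steiger(instruments)
    except ValueError:
        report.not_applicable.append("steiger")
    return report


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> list[ExposureReport]:
    """Process every exposure, set k, classify tiers, and export the report.

    Emits three study tables (estimates, diagnostics, strength), per-SNP
    scatter data with per-method fitted lines, forest data (per-method OR
    and CI), and a machine-readable JSON report.  Byte-identical across
    reruns with the same config and seed.
    """
    base = config.base_dir
    outcome = read_association_table(
        base / config.outcome.path,
        trait_name=config.outcome.name,
        trait_unit="log-odds",
        sample_size_default=config.outcome.n,
    )
    ld = LDMatrix.from_file(base / config.ld_matrix) if config.ld_matrix else None
    proxies = read_proxy_map(base / config.proxy_map) if config.proxy_map else None

    reports: list[ExposureReport] = []
    for idx, spec in enumerate(config.exposures):
        exposure = read_association_table(
            base / spec.path,
            trait_name=spec.name,
            trait_unit=spec.unit,
            sample_size_default=spec.n,
        )
        report = run_exposure(
            exposure, outcome, config, ld=ld, proxy_map=proxies,
            exposure_index=idx, sd=spec.sd,
        )
        if report.analyzable:
            sel = select_instruments(exposure, config.criteria)
            kept = sel.table.subset([i.snp_id for i in report.instruments])
            if len(kept) > 0:
                report.strength = strength_summary(kept, n=spec.n, sd=spec.sd)
        reports.append(report)

    k = sum(1 for r in reports if r.analyzable)
    if k == 0:
        raise RuntimeError("no analyzable exposures in this study")
    for r in reports:
        if r.analyzable and r.ivw_p is not None:
            r.tier = classify_tier(r.ivw_p, k, config.alpha)

    if out_dir is not None:
        export_study(reports, config, k, Path(out_dir))
    return reports


# ---------------------------------------------------------------------------
# report export

_FMT = "%.6g"


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "TRUE" if v else "FALSE"
    if isinstance(v, float):
        return _FMT % v
    return str(v)


def _estimates_frame(reports: list[ExposureReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        if not r.analyzable:
            rows.append({"exposure": r.name, "method": "NA", "n_snps": r.n_instruments,
                         "or": "NA", "ci_low": "NA", "ci_high": "NA", "p": "NA",
                         "tier": r.tier})
            continue
        for method, e in r.estimates.items():
            rows.append({
                "exposure": r.name, "method": method, "n_snps": e.n_snps,
                "or": _fmt(e.or_scale), "ci_low": _fmt(e.or_ci_low),
                "ci_high": _fmt(e.or_ci_high), "p": _fmt(e.pval), "tier": r.tier,
            })
    return pd.DataFrame(rows)


def _diagnostics_frame(reports: list[ExposureReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"exposure": r.name, "n_snps": r.n_instruments,
               "mean_f": "NA", "total_r2": "NA",
               "egger_intercept": "NA", "egger_intercept_p": "NA",
               "cochran_q": "NA", "cochran_q_p": "NA",
               "rss_obs": "NA", "p_global": "NA", "p_outlier_min": "NA",
               "p_global_corrected": "NA", "p_distortion": "NA",
               "correct_direction": "NA", "steiger_p": "NA",
               "fallback_threshold": _fmt(r.fallback_threshold)}
        if r.strength is not None:
            row["mean_f"] = _fmt(r.strength.mean_f)
            row["total_r2"] = _fmt(r.strength.total_r2)
        if r.egger_fit is not None:
            row["egger_intercept"] = _fmt(r.egger_fit.intercept)
            row["egger_intercept_p"] = _fmt(r.egger_fit.intercept_p)
        if r.heterogeneity is not None:
            row["cochran_q"] = _fmt(r.heterogeneity.q)
            row["cochran_q_p"] = _fmt(r.heterogeneity.pval)
        if r.presso is not None:
            row["rss_obs"] = _fmt(r.presso.rss_obs)
            row["p_global"] = r.presso.p_global_display
            row["p_outlier_min"] = _fmt(r.presso.p_outlier_min)
            row["p_global_corrected"] = _fmt(r.presso.p_global_corrected)
            row["p_distortion"] = _fmt(r.presso.p_distortion)
        if r.steiger is not None:
            row["correct_direction"] = _fmt(r.steiger.correct_direction)
            row["steiger_p"] = _fmt(r.steiger.pval)
        rows.append(row)
    return pd.DataFrame(rows)


def _scatter_frames(reports: list[ExposureReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    points, lines = [], []
    for r in reports:
        for inst in r.instruments:
            points.append({
                "exposure": r.name, "SNP": inst.snp_id,
                "gamma_x": _fmt(inst.gamma_x), "se_x": _fmt(inst.se_x),
                "gamma_y": _fmt(inst.gamma_y), "se_y": _fmt(inst.se_y),
            })
        for method, e in r.estimates.items():
            intercept = 0.0
            if method == "egger" and r.egger_fit is not None:
                intercept = r.egger_fit.intercept
            lines.append({
                "exposure": r.name, "method": method,
                "slope": _fmt(e.beta), "intercept": _fmt(intercept),
            })
    return pd.DataFrame(points), pd.DataFrame(lines)


def _report_json(reports: list[ExposureReport], config: StudyConfig, k: int) -> dict:
    def est_dict(e: est.MREstimate) -> dict:
        return {f: getattr(e, f) for f in
                ("method", "n_snps", "beta", "se", "ci_low", "ci_high", "pval",
                 "or_scale", "or_ci_low", "or_ci_high")}

    out = {
        "k": k,
        "alpha": config.alpha,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "n_sim": config.n_sim,
        "exposures": {},
    }
    for r in reports:
        entry: dict = {
            "n_instruments": r.n_instruments,
            "tier": r.tier,
            "fallback_threshold": r.fallback_threshold,
            "not_applicable": sorted(r.not_applicable),
            "estimates": {m: est_dict(e) for m, e in sorted(r.estimates.items())},
        }
        if r.heterogeneity:
            entry["cochran_q"] = dataclasses.asdict(r.heterogeneity)
        if r.egger_fit:
            entry["egger_intercept"] = {
                "value": r.egger_fit.intercept,
                "se": r.egger_fit.intercept_se,
                "p": r.egger_fit.intercept_p,
            }
        if r.presso:
            entry["mr_presso"] = {
                "rss_obs": r.presso.rss_obs,
                "p_global": r.presso.p_global,
                "p_global_display": r.presso.p_global_display,
                "outlier_ids": r.presso.outlier_ids,
                "p_outlier_min": r.presso.p_outlier_min,
                "p_global_corrected": r.presso.p_global_corrected,
                "beta_raw": r.presso.beta_raw,
                "beta_corrected": r.presso.beta_corrected,
                "p_distortion": r.presso.p_distortion,
                "n_sim": r.presso.n_sim,
            }
        if r.steiger:
            entry["steiger"] = dataclasses.asdict(r.steiger)
        if r.loo:
            entry["leave_one_out"] = [
                {"excluded_snp": rec.excluded_snp, "beta": rec.estimate.beta,
                 "pval": rec.estimate.pval, "influential": rec.influential}
                for rec in r.loo
            ]
        if r.strength:
            entry["strength"] = {
                "total_r2": r.strength.total_r2,
                "mean_f": r.strength.mean_f,
            }
        out["exposures"][r.name] = entry
    return out


def export_study(
    reports: list[ExposureReport], config: StudyConfig, k: int, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _estimates_frame(reports).to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    _diagnostics_frame(reports).to_csv(out_dir / "diagnostics.tsv", sep="\t", index=False)
    points, lines = _scatter_frames(reports)
    points.to_csv(out_dir / "scatter_points.tsv", sep="\t", index=False)
    lines.to_csv(out_dir / "scatter_lines.tsv", sep="\t", index=False)

    forest = _estimates_frame(reports)
    forest = forest[forest["method"] != "NA"]
    forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)

    payload = _report_json(reports, config, k)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("study report written to %s (k = %d)", out_dir, k)
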