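"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly on the summary-statistic level (no
individual-level genotypes): true SNP-exposure effects γ_j are drawn, true
SNP-outcome effects are Γ_j = β·γ_j + α_j where β is the causal effect and
α_j a per-SNP horizontal-pleiotropy term (absent, balanced around zero, or
directional with a nonzero mean; optionally correlated with γ_j to break
the InSIDE assumption), and observed effects add sampling noise with
standard errors derived from the allele frequency and sample size,
se ≈ (2·EAF·(1−EAF)·N)^(−1/2).  A fraction of SNPs can be planted as
outliers by displacing Γ_j by a multiple of its SE.  Everything is
deterministic given the seed, and the latent quantities are returned in a
truth record so estimator bias, coverage and detection power are directly
measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .summstats import AssociationTable, VariantAssociation, write_association_table


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one exposure/outcome pair.

    Defaults emulate a well-powered European-ancestry nutrient GWAS
    (N = 50,000) against a large case-control outcome GWAS (N ≈ 138,000,
    the ALS meta-analysis scale): common variants, per-SNP effects around
    0.05 SD per allele (single-SNP F broadly in the tens), no pleiotropy.
    """

    j_snps: int = 20
    beta_causal: float = 0.0
    n_exposure: int = 50_000
    n_outcome: int = 138_086
    eaf_range: tuple[float, float] = (0.05, 0.95)
    gamma_scale: float = 0.05
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    inside_violation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_snps < 1:
            raise ValueError("j_snps must be >= 1")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must be within (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outlier_fraction and not (0.0 < self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must be in (0, 1) when used")
        if not (0.0 < self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must be in (0, 1]")
        if self.n_exposure < 4 or self.n_outcome < 4:
            raise ValueError("sample sizes too small for the se approximation")


@dataclass
class TruthRecord:
    """Latent quantities behind one simulated pair."""

    beta_causal: float
    snp_ids: list[str]
    gamma_true: list[float]
    alpha: list[float]
    gamma_y_true: list[float]
    outlier: list[bool]
    config: SimulationConfig = field(repr=False, default=None)


def _se_from_freq(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _norm_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]  # non-palindromic


def simulate_pair(
    config: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, TruthRecord]:
    """Draw one exposure table, one outcome table, and their ground truth.

    True γ_j ~ U(0.5, 1.5)·gamma_scale, positive (summary rows are oriented
    to the exposure-increasing allele, as instrument lists conventionally
    are); Γ_j = beta_causal·γ_j + α_j with α_j per
    ``pleiotropy_mode`` applied to the first ``pleiotropy_fraction`` share
    of SNPs (with ``inside_violation`` the pleiotropic term gains a
    component proportional to γ_j).  Outlier SNPs (the first
    ``outlier_fraction`` share) have Γ_j displaced by
    ``outlier_shift``·se_y,j.  Observed effects are the truth plus normal
    noise at the analytic SE; p-values come from the z-score.
    """
    rng = np.random.default_rng(config.seed)
    j = config.j_snps
    lo, hi = config.eaf_range
    eaf = rng.uniform(lo, hi, size=j)
    gamma = rng.uniform(0.5, 1.5, size=j) * config.gamma_scale
    se_x = _se_from_freq(eaf, config.n_exposure)
    se_y = _se_from_freq(eaf, config.n_outcome)

    alpha = np.zeros(j)
    n_pleio = int(round(config.pleiotropy_fraction * j))
    if config.pleiotropy_mode == "balanced":
        alpha[:n_pleio] = rng.normal(0.0, config.pleiotropy_sd, size=n_pleio)
    elif config.pleiotropy_mode == "directional":
        alpha[:n_pleio] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=n_pleio
        )
    if config.inside_violation and config.pleiotropy_mode != "none":
        # tie the direct effect to instrument strength (breaks InSIDE)
        alpha[:n_pleio] += 0.5 * np.abs(gamma[:n_pleio])

    gamma_y = config.beta_causal * gamma + alpha
    outlier = np.zeros(j, dtype=bool)
    if config.outlier_fraction > 0.0:
        n_out = max(1, int(round(config.outlier_fraction * j)))
        outlier[:n_out] = True
        gamma_y = gamma_y + outlier * config.outlier_shift * se_y

    gx_obs = rng.normal(gamma, se_x)
    gy_obs = rng.normal(gamma_y, se_y)
    px = _norm_p(gx_obs / se_x)
    py = _norm_p(gy_obs / se_y)

    snp_ids = [f"rs{1000 + k}" for k in range(j)]
    alleles = [_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)] for k in range(j)]

    def table(name, unit, betas, ses, ps, n):
        recs = {}
        for k, sid in enumerate(snp_ids):
            ea, oa = alleles[k]
            recs[sid] = VariantAssociation(
                snp_id=sid, effect_allele=ea, other_allele=oa,
                eaf=float(eaf[k]), beta=float(betas[k]), se=float(ses[k]),
                pval=float(ps[k]), n=n,
            )
        return AssociationTable(
            trait_name=name, records=recs, trait_unit=unit, sample_size_default=n
        )

    exposure = table("exposure", "sd", gx_obs, se_x, px, config.n_exposure)
    outcome = table("outcome", "log-odds", gy_obs, se_y, py, config.n_outcome)
    truth = TruthRecord(
        beta_causal=config.beta_causal,
        snp_ids=snp_ids,
        gamma_true=gamma.tolist(),
        alpha=alpha.tolist(),
        gamma_y_true=gamma_y.tolist(),
        outlier=outlier.tolist(),
        config=config,
    )
    return exposure, outcome, truth


def simulate_study(
    configs: Sequence[SimulationConfig],
    names: Sequence[str],
    out_dir: str | Path,
    outcome_name: str = "outcome",
    seed: int | None = None,
    study_options: dict | None = None,
) -> Path:
    """Write a complete, runnable study bundle to ``out_dir``.

    Produces one exposure summary-statistics file per config, one shared
    outcome file (the union of the per-config outcome rows, each config's
    SNPs being distinct), an LD matrix file (no entries: all pairs
    independent by default), a YAML study config consumable by
    ``mrns run``, and a truth TSV with the latent per-SNP quantities.
    Returns the path of the study config.
    """
    if len(configs) != len(names):
        raise ValueError("configs and names must have equal length")
    if len(configs) == 0:
        raise ValueError("need at least one config")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    outcome_records = {}
    outcome_n = configs[0].n_outcome
    exposures_meta = []
    truth_rows = []
    for idx, (cfg, name) in enumerate(zip(configs, names)):
        # distinct SNP namespaces per exposure so the shared outcome file is well-defined
        prefix = f"e{idx}_"
        exposure, outcome, truth = simulate_pair(cfg)
        exposure = AssociationTable(
            trait_name=name,
            records={
                prefix + s: _relabel(r, prefix + s) for s, r in exposure.records.items()
            },
            trait_unit=exposure.trait_unit,
            sample_size_default=exposure.sample_size_default,
        )
        for s, r in outcome.records.items():
            outcome_records[prefix + s] = _relabel(r, prefix + s)
        path = out_dir / f"{name}.tsv"
        write_association_table(exposure, path)
        exposures_meta.append(
            {"name": name, "path": path.name, "unit": "sd", "n": cfg.n_exposure, "sd": 1.0}
        )
        for k, sid in enumerate(truth.snp_ids):
            truth_rows.append(
                {
                    "exposure": name,
                    "SNP": prefix + sid,
                    "beta_causal": truth.beta_causal,
                    "gamma_true": truth.gamma_true[k],
                    "alpha": truth.alpha[k],
                    "gamma_y_true": truth.gamma_y_true[k],
                    "outlier": truth.outlier[k],
                }
            )

    outcome_table = AssociationTable(
        trait_name=outcome_name,
        records=outcome_records,
        trait_unit="log-odds",
        sample_size_default=outcome_n,
    )
    outcome_path = out_dir / f"{outcome_name}.tsv"
    write_association_table(outcome_table, outcome_path)

    ld_path = out_dir / "ld_matrix.tsv"
    ld_path.write_text("SNP_A\tSNP_B\tR2\n")

    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)

    study = {
        "outcome": {"name": outcome_name, "path": outcome_path.name, "n": outcome_n},
        "exposures": exposures_meta,
        "ld_matrix": ld_path.name,
        "seed": int(seed if seed is not None else configs[0].seed),
    }
    if study_options:
        study.update(study_options)
    config_path = out_dir / "study.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(study, fh, sort_keys=True)
    return config_path


def _relabel(rec: VariantAssociation, new_id: str) -> VariantAssociation:
    from dataclasses import replace

    return replace(rec, snp_id=new_id)
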