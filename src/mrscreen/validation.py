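"""Monte-Carlo validation experiments for the estimators and diagnostics.

Each function runs a self-contained, seeded simulation study against the
generator in :mod:`mrscreen.simulate` and returns summary numbers: estimator
bias and confidence-interval coverage under a known causal effect, test size
(rejection rate under the null) for Cochran's Q and the PRESSO global test,
detection power for a planted outlier, the bias comparison that motivates
the weighted median, and the bookkeeping of a full multi-exposure screen.
They power both the test suite and ``scripts/acceptance.py``.

Per-replicate seeds derive from the experiment seed through
``numpy.random.SeedSequence(seed, spawn_key=(rep,))`` so replicates are
independent and the whole experiment is reproducible from one integer.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .diagnostics import cochran_q, mr_presso
from .estimators import ivw, weighted_median
from .pipeline import StudyConfig, run_study
from .simulate import SimulationConfig, simulate_pair, simulate_study
from .summstats import harmonize


def _rep_seed(seed: int, rep: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(salt, rep))
    return int(ss.generate_state(1)[0]) % 2**31


def _instruments(cfg: SimulationConfig):
    exposure, outcome, truth = simulate_pair(cfg)
    return harmonize(exposure, outcome), truth


def recovery_experiment(
    n_reps: int = 500,
    seed: int = 0,
    j_snps: int = 50,
    beta_causal: float = 0.1,
    n_exposure: int = 50_000,
    n_outcome: int = 100_000,
) -> dict:
    """Bias and 95% CI coverage of the random-effects IVW estimator under a
    known causal effect and no pleiotropy."""
    errors = np.empty(n_reps)
    covered = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            j_snps=j_snps, beta_causal=beta_causal,
            n_exposure=n_exposure, n_outcome=n_outcome,
            seed=_rep_seed(seed, r, salt=1),
        )
        insts, _ = _instruments(cfg)
        est = ivw(insts, model="mre")
        errors[r] = est.beta - beta_causal
        covered += est.ci_low <= beta_causal <= est.ci_high
    return {
        "mean_bias": float(np.mean(errors)),
        "mc_se": float(np.std(errors, ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def q_calibration(
    n_reps: int = 1000,
    seed: int = 0,
    j_snps: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of Cochran's Q under its homogeneous null.

    Instruments are simulated strong (gamma_scale 0.1 at N = 50,000) because
    the chi-square reference for Q treats the SNP-exposure effects as known;
    weak-instrument noise would inflate the statistic for every method alike.
    """
    hits = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            j_snps=j_snps, beta_causal=0.1, gamma_scale=0.1,
            seed=_rep_seed(seed, r, salt=2),
        )
        insts, _ = _instruments(cfg)
        hits += cochran_q(insts).pval < alpha
    return {"rejection_rate": hits / n_reps, "n_reps": n_reps}


def presso_calibration(
    n_reps: int = 500,
    n_sim: int = 1000,
    seed: int = 0,
    j_snps: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the PRESSO global test under its null (no
    pleiotropy, no outliers)."""
    hits = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            j_snps=j_snps, beta_causal=0.1, gamma_scale=0.1,
            seed=_rep_seed(seed, r, salt=3),
        )
        insts, _ = _instruments(cfg)
        res = mr_presso(insts, n_sim=n_sim, seed=_rep_seed(seed, r, salt=4))
        hits += res.p_global < alpha
    return {"rejection_rate": hits / n_reps, "n_reps": n_reps}


def outlier_detection(
    n_reps: int = 200,
    seed: int = 0,
    j_snps: int = 20,
    outlier_shift: float = 10.0,
    n_sim: int = 1000,
) -> dict:
    """Power to flag a single planted outlier (Γ displaced by
    ``outlier_shift``·se_y) and to rank it first among outlier p-values."""
    flagged = 0
    ranked_first = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            j_snps=j_snps, beta_causal=0.1,
            outlier_fraction=1.0 / j_snps, outlier_shift=outlier_shift,
            seed=_rep_seed(seed, r, salt=5),
        )
        insts, truth = _instruments(cfg)
        (outlier_id,) = [s for s, o in zip(truth.snp_ids, truth.outlier) if o]
        res = mr_presso(insts, n_sim=n_sim, seed=_rep_seed(seed, r, salt=6))
        hit = outlier_id in res.outlier_ids
        first = res.outlier_p[outlier_id] == min(res.outlier_p.values())
        flagged += hit
        ranked_first += hit and first
    return {
        "flag_rate": flagged / n_reps,
        "flag_and_min_p_rate": ranked_first / n_reps,
        "n_reps": n_reps,
    }


def pleiotropy_bias_comparison(
    n_reps: int = 500,
    seed: int = 0,
    j_snps: int = 20,
    beta_causal: float = 0.1,
    pleiotropy_fraction: float = 0.4,
    pleiotropy_mean: float = 0.05,
) -> dict:
    """Absolute bias of IVW versus the weighted median when a minority of
    instruments carry directional pleiotropy (the weighted median's design
    scenario: > 50% of the weight remains valid)."""
    ivw_est = np.empty(n_reps)
    wm_est = np.empty(n_reps)
    for r in range(n_reps):
        cfg = SimulationConfig(
            j_snps=j_snps, beta_causal=beta_causal,
            pleiotropy_mode="directional", pleiotropy_mean=pleiotropy_mean,
            pleiotropy_sd=0.01, pleiotropy_fraction=pleiotropy_fraction,
            seed=_rep_seed(seed, r, salt=7),
        )
        insts, _ = _instruments(cfg)
        ivw_est[r] = ivw(insts, model="mre").beta
        wm_est[r] = weighted_median(insts, n_boot=50, seed=_rep_seed(seed, r, salt=8)).beta
    return {
        "ivw_abs_bias": float(abs(np.mean(ivw_est) - beta_causal)),
        "weighted_median_abs_bias": float(abs(np.mean(wm_est) - beta_causal)),
        "n_reps": n_reps,
    }


def screen_bookkeeping(
    seed: int = 0,
    n_exposures: int = 35,
    n_under_instrumented: int = 6,
    out_dir: str | Path | None = None,
) -> dict:
    """Run a full synthetic multi-exposure screen and audit the bookkeeping:
    the analyzable count k and the method-applicability matrix (IVW-only at
    J = 2, no PRESSO below J = 4)."""
    n_strong = n_exposures - n_under_instrumented
    configs, names = [], []
    for i in range(n_strong):
        # spread instrument counts so every applicability branch occurs
        j = [2, 3, 4, 6, 8][i % 5]
        configs.append(SimulationConfig(
            j_snps=j, beta_causal=0.05, gamma_scale=0.15,
            seed=_rep_seed(seed, i, salt=9)))
        names.append(f"nutrient_{i:02d}")
    for i in range(n_under_instrumented):
        configs.append(SimulationConfig(
            j_snps=1, beta_causal=0.05, gamma_scale=0.15,
            seed=_rep_seed(seed, n_strong + i, salt=9)))
        names.append(f"sparse_{i:02d}")

    def run_in(dir_path: Path) -> dict:
        cfg_path = simulate_study(configs, names, dir_path, seed=seed)
        study = StudyConfig.from_yaml(cfg_path)
        study.n_sim, study.n_boot = 200, 100
        reports = run_study(study, out_dir=dir_path / "report")
        k = sum(1 for rep in reports if rep.analyzable)
        matrix_ok = True
        for rep in reports:
            j = rep.n_instruments
            has = set(rep.estimates)
            if j < 2:
                matrix_ok &= not rep.estimates and rep.tier == "unanalyzable"
                continue
            matrix_ok &= "ivw_mre" in has
            sens = {"egger", "simple_median", "weighted_median"}
            matrix_ok &= (sens <= has) if j >= 3 else not (sens & has)
            matrix_ok &= (rep.presso is not None) == (j >= 4)
        return {
            "n_exposures": len(reports),
            "k_analyzable": k,
            "n_unanalyzable": sum(1 for rep in reports if not rep.analyzable),
            "applicability_matrix_ok": matrix_ok,
        }

    if out_dir is not None:
        return run_in(Path(out_dir))
    with tempfile.TemporaryDirectory() as tmp:
        return run_in(Path(tmp))
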