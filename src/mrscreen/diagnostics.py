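"""Instrument-validity diagnostics for one exposure's harmonized set.

Covers heterogeneity (Cochran's Q on per-SNP Wald ratios), directional
pleiotropy (the MR–Egger intercept), simulation-based outlier detection
(an MR-PRESSO-style residual-sum-of-squares framework with global, per-SNP
outlier and distortion tests), directionality (a Steiger test comparing
instrument variance explained in exposure versus outcome), and per-SNP
influence (leave-one-out IVW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate, EggerFit, InsufficientInstruments, ivw, _arrays
from .instruments import variant_r2
from .summstats import HarmonizedInstrument

MIN_SNPS_PRESSO = 4


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square(J-1) upper-tail p."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


@dataclass(frozen=True)
class LooRecord:
    excluded_snp: str
    estimate: MREstimate
    influential: bool


@dataclass
class PressoResult:
    """Global, per-SNP outlier, and distortion tests.

    ``p_global`` is the fraction of simulated RSS values at or above the
    observed one; at zero exceedances it is censored at the simulation
    resolution and ``p_global_display`` reads "<1/n_sim".  ``outlier_p``
    are Bonferroni-adjusted per-SNP p-values.  ``p_global_corrected`` is
    the global test re-run after removing flagged outliers (one common
    reading of a per-exposure "P-outlier"); ``p_outlier_min`` is the other
    (the smallest adjusted per-SNP p).
    """

    rss_obs: float
    p_global: float
    p_global_display: str
    n_sim: int
    outlier_p: dict[str, float] = field(default_factory=dict)
    outlier_ids: list[str] = field(default_factory=list)
    beta_raw: float | None = None
    beta_corrected: float | None = None
    p_distortion: float | None = None
    p_global_corrected: float | None = None
    p_outlier_min: float | None = None


def _ratio_q(instruments: Sequence[HarmonizedInstrument], beta_ref: float) -> float:
    gx, _, gy, sy = _arrays(instruments)
    ratios = gy / gx
    w = gx**2 / sy**2  # inverse first-order ratio variance
    return float(np.sum(w * (ratios - beta_ref) ** 2))


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], beta_ref: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q = Σ w_j (β_j − β_ref)² over per-SNP Wald ratios.

    ``w_j`` is the inverse first-order ratio variance γ̂²/se_y²; ``beta_ref``
    defaults to the fixed-effect IVW estimate, at which Q(β) is minimized.
    Under homogeneity Q ~ chi-square with J−1 degrees of freedom.
    """
    j = len(instruments)
    if j < 2:
        raise InsufficientInstruments(f"Cochran's Q needs >= 2 instruments, got {j}")
    if beta_ref is None:
        beta_ref = ivw(instruments, model="fe").beta
    q = _ratio_q(instruments, beta_ref)
    df = j - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(fit: EggerFit, alpha: float = 0.05) -> tuple[bool, float]:
    """Flag directional pleiotropy when the Egger intercept p < alpha."""
    return fit.intercept_p < alpha, fit.intercept_p


def _loo_slopes(gx: np.ndarray, gy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for every SNP, vectorized.

    Works on 2-D input (replicates in rows) as well.
    """
    num = np.sum(w * gx * gy, axis=-1, keepdims=True) - w * gx * gy
    den = np.sum(w * gx * gx, axis=-1, keepdims=True) - w * gx * gx
    return num / den


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 5000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
) -> PressoResult:
    """Simulation-based pleiotropy residual-sum-of-squares and outlier test.

    The observed statistic is RSS = Σ_j w_j (Γ̂_j − β̂_{−j} γ̂_j)² with
    w_j = 1/se_y,j² and β̂_{−j} the leave-one-out fixed-effect IVW slope.
    The null distribution comes from ``n_sim`` parametric replicates
    (Γ*_j ~ N(β̂_{−j} γ̂_j, se_y,j), γ*_j ~ N(γ̂_j, se_x,j)) on which the
    same statistic is recomputed.  Per-SNP outlier p-values compare each
    observed weighted squared residual with its simulated distribution and
    are Bonferroni-multiplied by J; flagged SNPs feed an outlier-corrected
    IVW and a distortion test of the raw-vs-corrected difference against
    random removal of the same number of SNPs.  Deterministic given
    ``seed``.
    """
    j = len(instruments)
    if j < MIN_SNPS_PRESSO:
        raise InsufficientInstruments(f"MR-PRESSO needs >= {MIN_SNPS_PRESSO} instruments, got {j}")
    rng = np.random.default_rng(seed)
    gx, sx, gy, sy = _arrays(instruments)
    w = 1.0 / sy**2

    b_loo = _loo_slopes(gx, gy, w)
    resid2_obs = w * (gy - b_loo * gx) ** 2
    rss_obs = float(np.sum(resid2_obs))

    gxs = rng.normal(gx, sx, size=(n_sim, j))
    gys = rng.normal(b_loo * gx, sy, size=(n_sim, j))
    b_loo_sim = _loo_slopes(gxs, gys, w)
    resid2_sim = w * (gys - b_loo_sim * gxs) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    exceed = int(np.sum(rss_sim >= rss_obs))
    p_global = exceed / n_sim
    display = f"<{1 / n_sim:g}" if exceed == 0 else f"{p_global:g}"

    per_p_raw = np.mean(resid2_sim >= resid2_obs, axis=0)
    per_p_adj = np.minimum(per_p_raw * j, 1.0)
    ids = [inst.snp_id for inst in instruments]
    outlier_p = dict(zip(ids, per_p_adj.tolist()))
    flagged = [ids[k] for k in range(j) if per_p_adj[k] < outlier_alpha]

    result = PressoResult(
        rss_obs=rss_obs,
        p_global=p_global,
        p_global_display=display,
        n_sim=n_sim,
        outlier_p=outlier_p,
        outlier_ids=flagged,
        p_outlier_min=float(np.min(per_p_adj)),
    )

    beta_raw = ivw(instruments, model="mre").beta
    result.beta_raw = beta_raw
    if flagged:
        keep = [inst for inst in instruments if inst.snp_id not in flagged]
        if len(keep) < 2:
            raise InsufficientInstruments(
                "MR-PRESSO flagged all (or nearly all) instruments as outliers"
            )
        result.beta_corrected = ivw(keep, model="mre").beta
        if len(keep) >= MIN_SNPS_PRESSO:
            sub_seed = int(rng.integers(2**31))
            corrected = mr_presso(
                keep, n_sim=n_sim, seed=sub_seed, outlier_alpha=outlier_alpha, n_distortion=0
            )
            result.p_global_corrected = corrected.p_global
        # distortion: difference vs random removal of |flagged| SNPs
        if n_distortion > 0:
            d_obs = result.beta_corrected - beta_raw
            diffs = np.empty(n_distortion)
            idx = np.arange(j)
            for b in range(n_distortion):
                drop = rng.choice(idx, size=len(flagged), replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                num = float(np.sum(w[mask] * gx[mask] * gy[mask]))
                den = float(np.sum(w[mask] * gx[mask] ** 2))
                diffs[b] = num / den - beta_raw
            result.p_distortion = float(np.mean(np.abs(diffs) >= abs(d_obs)))
    return result


def _z2_r2(beta: float, se: float, n: float) -> float:
    """Per-SNP variance explained from the z-score: r² ≈ z²/(z² + N)."""
    z2 = (beta / se) ** 2
    return z2 / (z2 + n)


def steiger(
    instruments: Sequence[HarmonizedInstrument],
    n_exposure: int | None = None,
    n_outcome: int | None = None,
    sd_exposure: float = 1.0,
) -> SteigerResult:
    """Directionality test: does the instrument set explain more variance
    in the exposure than in the outcome?

    Exposure-side per-SNP R² uses 2γ̂²·EAF·(1−EAF)/SD² when the EAF is
    available and the z-score approximation z²/(z² + N) otherwise; the
    outcome side (log-odds scale, no defined EAF-based R²) always uses the
    z-score approximation.  The summed R² values are compared as
    correlation magnitudes via Fisher's z transformation with the
    respective sample sizes.
    """
    if not instruments:
        raise InsufficientInstruments("Steiger needs >= 1 instrument")
    r2x = 0.0
    r2y = 0.0
    for inst in instruments:
        nx = inst.n_x if inst.n_x is not None else n_exposure
        ny = inst.n_y if inst.n_y is not None else n_outcome
        if nx is None or ny is None:
            raise ValueError("Steiger needs exposure and outcome sample sizes")
        if inst.eaf is not None:
            r2x += variant_r2(inst.gamma_x, inst.eaf, sd_exposure)
        else:
            r2x += _z2_r2(inst.gamma_x, inst.se_x, nx)
        r2y += _z2_r2(inst.gamma_y, inst.se_y, ny)
    r2x = min(r2x, 1.0 - 1e-12)
    r2y = min(r2y, 1.0 - 1e-12)
    nx_eff = min(i.n_x if i.n_x is not None else n_exposure for i in instruments)
    ny_eff = min(i.n_y if i.n_y is not None else n_outcome for i in instruments)
    rx, ry = math.sqrt(r2x), math.sqrt(r2y)
    z = (math.atanh(rx) - math.atanh(ry)) / math.sqrt(
        1.0 / (nx_eff - 3) + 1.0 / (ny_eff - 3)
    )
    pval = float(max(2.0 * stats.norm.sf(abs(z)), 5e-324))
    return SteigerResult(
        r2_exposure=r2x, r2_outcome=r2y, correct_direction=r2x > r2y, pval=pval
    )


def leave_one_out(instruments: Sequence[HarmonizedInstrument]) -> list[LooRecord]:
    """Recompute the random-effects IVW excluding each instrument in turn.

    A record is flagged ``influential`` when removing its SNP flips the
    estimate's sign or its significance at 0.05 relative to the full-set
    estimate.
    """
    j = len(instruments)
    if j < 3:
        raise InsufficientInstruments(f"leave-one-out needs >= 3 instruments, got {j}")
    full = ivw(instruments, model="mre")
    records = []
    for k, inst in enumerate(instruments):
        subset = [x for i, x in enumerate(instruments) if i != k]
        est = ivw(subset, model="mre")
        influential = (est.significant != full.significant) or (
            math.copysign(1.0, est.beta) != math.copysign(1.0, full.beta)
        )
        records.append(LooRecord(excluded_snp=inst.snp_id, estimate=est, influential=influential))
    return records
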