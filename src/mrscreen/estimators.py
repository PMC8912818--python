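"""Causal-effect estimators for two-sample MR.

All estimators consume a collection of :class:`HarmonizedInstrument` with
SNP-exposure effects gamma_x (γ̂) and SNP-outcome effects gamma_y (Γ̂).  The
per-SNP Wald ratio Γ̂/γ̂ is the building block; the inverse variance–weighted
(IVW) estimator pools ratios as a zero-intercept weighted regression of Γ̂
on γ̂; MR–Egger frees the intercept to absorb directional pleiotropy; the
simple and weighted medians are robust to up to half of the instruments (or
half of the weight) being invalid.

Conventions: IVW p-values use the normal reference; the multiplicative
random-effects SE inflates the fixed-effect SE by sqrt(max(1, Q/(J-1))) and
never deflates it.  Egger uses a t reference with J-2 degrees of freedom and
orients instruments so that all γ̂ >= 0 before fitting (the estimate is not
invariant to allele orientation).  Median SEs come from a seeded parametric
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .summstats import HarmonizedInstrument

Z95 = 1.959963984540054  # Phi^{-1}(0.975)

#: minimum instrument counts per method
MIN_SNPS = {"wald": 1, "ivw": 2, "egger": 3, "simple_median": 3, "weighted_median": 3}


class InsufficientInstruments(ValueError):
    """Raised when a method is called with fewer instruments than it needs."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (or outcome-unit) scale."""

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_scale: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    @property
    def significant(self) -> bool:
        return self.pval < 0.05


@dataclass(frozen=True)
class EggerFit:
    """MR–Egger slope plus the pleiotropy-detecting intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    gx = np.array([i.gamma_x for i in instruments], dtype=float)
    sx = np.array([i.se_x for i in instruments], dtype=float)
    gy = np.array([i.gamma_y for i in instruments], dtype=float)
    sy = np.array([i.se_y for i in instruments], dtype=float)
    return gx, sx, gy, sy


def _normal_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), 5e-324))


def _estimate(method: str, j: int, beta: float, se: float, crit: float = Z95,
              pval: float | None = None) -> MREstimate:
    if pval is None:
        pval = _normal_p(beta / se) if se > 0 else 1.0
    return MREstimate(
        method=method, n_snps=j, beta=float(beta), se=float(se),
        ci_low=float(beta - crit * se), ci_high=float(beta + crit * se), pval=float(pval),
    )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate Γ̂/γ̂ with the first-order delta-method SE."""
    if inst.gamma_x == 0:
        raise ZeroDivisionError(f"{inst.snp_id}: gamma_x = 0, Wald ratio undefined")
    beta = inst.gamma_y / inst.gamma_x
    se = abs(inst.se_y / inst.gamma_x)
    return _estimate("wald", 1, beta, se)


def ivw(instruments: Sequence[HarmonizedInstrument], model: str = "mre") -> MREstimate:
    """Inverse variance–weighted estimate: zero-intercept WLS of Γ̂ on γ̂.

    Weights are 1/se_y².  ``model="fe"`` gives the fixed-effect SE
    (Σ γ̂²/se_y²)^(−1/2); ``model="mre"`` (multiplicative random effects)
    multiplies it by sqrt(max(1, Q/(J−1))), where Q is Cochran's
    heterogeneity statistic, so that excess dispersion widens — never
    narrows — the interval.
    """
    if model not in ("fe", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = len(instruments)
    if j < MIN_SNPS["ivw"]:
        raise InsufficientInstruments(f"IVW needs >= 2 instruments, got {j}")
    gx, _, gy, sy = _arrays(instruments)
    w = 1.0 / sy**2
    sww = float(np.sum(w * gx * gx))
    beta = float(np.sum(w * gx * gy)) / sww
    se_fe = sww ** -0.5
    se = se_fe
    if model == "mre":
        q = float(np.sum(w * (gy - beta * gx) ** 2))
        phi = q / (j - 1)  # residual dispersion, floored at 1 below
        se = se_fe * math.sqrt(max(1.0, phi))
    name = "ivw_mre" if model == "mre" else "ivw_fe"
    return _estimate(name, j, beta, se)


def egger(instruments: Sequence[HarmonizedInstrument]) -> EggerFit:
    """MR–Egger: weighted regression of Γ̂ on γ̂ with a free intercept.

    Instruments are first oriented so every γ̂ >= 0 (γ̂ and Γ̂ signs flip
    together).  Weights are 1/se_y²; coefficient SEs use a multiplicative
    dispersion floored at 1 and a t reference with J−2 degrees of freedom.
    A nonzero intercept indicates directional horizontal pleiotropy.
    """
    j = len(instruments)
    if j < MIN_SNPS["egger"]:
        raise InsufficientInstruments(f"MR-Egger needs >= 3 instruments, got {j}")
    gx, _, gy, sy = _arrays(instruments)
    sign = np.where(gx < 0, -1.0, 1.0)
    gx, gy = gx * sign, gy * sign
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), gx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * gy)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = gy - x @ coef
    dof = j - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / dof)
    cov = sigma2 * np.linalg.inv(xtwx)
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tcrit = float(stats.t.ppf(0.975, dof))
    p_slope = float(max(2.0 * stats.t.sf(abs(slope / se_slope), dof), 5e-324))
    p_inter = float(max(2.0 * stats.t.sf(abs(inter / se_inter), dof), 5e-324))
    slope_est = _estimate("egger", j, slope, se_slope, crit=tcrit, pval=p_slope)
    return EggerFit(slope=slope_est, intercept=inter, intercept_se=se_inter, intercept_p=p_inter)


def _wald_ratios(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    return gy / gx


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Order statistic at cumulative weight 0.5 with linear interpolation."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _ratio_weights(gx, sx, gy, sy, weighting: str) -> np.ndarray:
    if weighting == "first_order":
        return gx**2 / sy**2
    if weighting == "second_order":
        var = sy**2 / gx**2 + gy**2 * sx**2 / gx**4
        return 1.0 / var
    raise ValueError(f"unknown ratio weighting {weighting!r}")


def _median_bootstrap(
    gx, sx, gy, sy, n_boot: int, seed: int, weighting: str | None
) -> float:
    """SE of a median-type estimator via parametric resampling of (γ̂, Γ̂)."""
    rng = np.random.default_rng(seed)
    gxs = rng.normal(gx, sx, size=(n_boot, gx.size))
    gys = rng.normal(gy, sy, size=(n_boot, gy.size))
    ratios = gys / gxs
    est = np.empty(n_boot)
    for b in range(n_boot):
        if weighting is None:
            est[b] = np.median(ratios[b])
        else:
            wts = _ratio_weights(gxs[b], sx, gys[b], sy, weighting)
            est[b] = _weighted_median(ratios[b], wts)
    return float(np.std(est, ddof=1))


def simple_median(
    instruments: Sequence[HarmonizedInstrument], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Unweighted median of per-SNP Wald ratios; bootstrap SE.

    The point estimate uses midpoint interpolation for even J.  The SE is
    the standard deviation of the estimator over ``n_boot`` parametric
    bootstrap replicates (γ̂, Γ̂ resampled from their sampling
    distributions), deterministic given ``seed``.
    """
    j = len(instruments)
    if j < MIN_SNPS["simple_median"]:
        raise InsufficientInstruments(f"simple median needs >= 3 instruments, got {j}")
    gx, sx, gy, sy = _arrays(instruments)
    beta = float(np.median(_wald_ratios(gx, gy)))
    se = _median_bootstrap(gx, sx, gy, sy, n_boot, seed, weighting=None)
    return _estimate("simple_median", j, beta, se)


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
    weighting: str = "first_order",
) -> MREstimate:
    """Weighted median of Wald ratios; consistent when >= 50% of weight is valid.

    Ratios are sorted with weights w_j = γ̂²/se_y² (inverse first-order
    ratio variance; ``weighting="second_order"`` adds the γ̂-noise term)
    normalized to sum 1; the estimate is the ratio at cumulative weight 0.5
    with linear interpolation between bracketing order statistics.
    """
    j = len(instruments)
    if j < MIN_SNPS["weighted_median"]:
        raise InsufficientInstruments(f"weighted median needs >= 3 instruments, got {j}")
    gx, sx, gy, sy = _arrays(instruments)
    beta = _weighted_median(_wald_ratios(gx, gy), _ratio_weights(gx, sx, gy, sy, weighting))
    se = _median_bootstrap(gx, sx, gy, sy, n_boot, seed, weighting=weighting)
    return _estimate("weighted_median", j, beta, se)


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Populate the odds-ratio scale: exp(beta) with exponentiated CI."""
    return replace(
        est,
        or_scale=math.exp(est.beta),
        or_ci_low=math.exp(est.ci_low),
        or_ci_high=math.exp(est.ci_high),
    )
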