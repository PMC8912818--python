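"""Instrumental-variable selection and strength.

Eligible instruments are genome-wide significant (p < 5e-8), common
(MAF >= 0.01) and mutually independent (pairwise LD r^2 below a threshold,
greedy clumping on p-value).  Exposures with no genome-wide hit fall back
to the suggestive threshold p < 1e-5 and are flagged as such.  Strength is
summarized by the variance explained per SNP,

    R^2 = 2 * beta^2 * EAF * (1 - EAF) / SD^2,

and the per-SNP F statistic F = R^2 * (N - 2) / (1 - R^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .summstats import AssociationTable, SummStatsError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    """Instrument eligibility thresholds.

    ``clump_kb`` is retained as metadata only: independence is decided by
    the supplied r² lookup, not by genomic distance (no positions are
    modeled).
    """

    p_genomewide: float = 5e-8
    p_suggestive: float = 1e-5
    maf_min: float = 0.01
    clump_r2: float = 0.01
    clump_kb: int = 5000
    min_ivs: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.p_genomewide < self.p_suggestive < 1.0):
            raise ValueError("need 0 < p_genomewide < p_suggestive < 1")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("need 0 <= maf_min < 0.5")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.min_ivs < 1:
            raise ValueError("min_ivs must be >= 1")


@dataclass
class SelectionResult:
    """Selected instruments plus selection provenance."""

    table: AssociationTable
    fallback_used: bool = False
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)

    @property
    def analyzable(self) -> bool:
        return len(self.table) > 0


def select_instruments(table: AssociationTable, criteria: SelectionCriteria) -> SelectionResult:
    """Apply the p-value and MAF eligibility filters.

    Rows with p below the genome-wide threshold are retained; if none
    survive, the suggestive threshold is applied instead and the result is
    flagged ``fallback_used``.  Rows with MAF below ``maf_min`` are removed
    (rows with missing EAF are kept — frequency unknown is not rare).
    """
    dropped: list[tuple[str, str]] = []
    common = {}
    for rec in table:
        if rec.maf is not None and rec.maf < criteria.maf_min:
            dropped.append((rec.snp_id, f"MAF {rec.maf:.4g} < {criteria.maf_min}"))
        else:
            common[rec.snp_id] = rec

    def at_threshold(thr: float) -> dict:
        return {s: r for s, r in common.items() if r.pval < thr}

    kept = at_threshold(criteria.p_genomewide)
    fallback = False
    if not kept:
        kept = at_threshold(criteria.p_suggestive)
        fallback = bool(kept)
        if fallback:
            logger.info(
                "%s: no genome-wide hits; suggestive threshold %g applied",
                table.trait_name, criteria.p_suggestive,
            )
    for snp_id, rec in common.items():
        if snp_id not in kept:
            dropped.append((snp_id, f"p {rec.pval:.3g} above threshold"))
    out = AssociationTable(
        trait_name=table.trait_name,
        records=kept,
        trait_unit=table.trait_unit,
        sample_size_default=table.sample_size_default,
    )
    return SelectionResult(table=out, fallback_used=fallback, dropped=dropped)


class LDMatrix:
    """Sparse symmetric pairwise r² lookup; absent pairs are r² = 0."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if a == b:
            return
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self._r2[frozenset((a, b))] = r2

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        """Load from TSV columns SNP_A, SNP_B, R2 (symmetric closure applied)."""
        df = pd.read_csv(path, sep=sep)
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise SummStatsError(f"{path}: LD matrix column {col!r} missing")
        mat = cls()
        for _, row in df.iterrows():
            mat.set(str(row["SNP_A"]), str(row["SNP_B"]), float(row["R2"]))
        return mat


def ld_clump(
    table: AssociationTable, ld_r2: LDMatrix, criteria: SelectionCriteria
) -> AssociationTable:
    """Greedy LD clumping: keep the most significant SNP of each clump.

    Repeatedly takes the lowest-p remaining SNP as an index variant and
    removes every remaining SNP with r² > ``criteria.clump_r2`` against it;
    ties on p break lexicographically by snp_id.  Output is the index SNPs
    in selection order.
    """
    remaining = sorted(table, key=lambda r: (r.pval, r.snp_id))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r for r in remaining if ld_r2.get(index.snp_id, r.snp_id) <= criteria.clump_r2
        ]
    return AssociationTable(
        trait_name=table.trait_name,
        records={r.snp_id: r for r in kept},
        trait_unit=table.trait_unit,
        sample_size_default=table.sample_size_default,
    )


def variant_r2(beta: float, eaf: float, sd: float = 1.0) -> float:
    """Variance in the phenotype explained by one SNP: 2·β²·EAF·(1−EAF)/SD²."""
    if not (0.0 <= eaf <= 1.0):
        raise ValueError(f"eaf must be in [0, 1], got {eaf}")
    if not (sd > 0):
        raise ValueError(f"sd must be > 0, got {sd}")
    return 2.0 * beta * beta * eaf * (1.0 - eaf) / (sd * sd)


def f_statistic(r2: float, n: float) -> float:
    """Single-instrument F statistic: R²·(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must be > 2, got {n}")
    return r2 * (n - 2.0) / (1.0 - r2)


@dataclass
class InstrumentStrength:
    """Per-SNP and aggregate instrument strength for one exposure."""

    per_snp_r2: dict[str, float]
    per_snp_f: dict[str, float | None]
    total_r2: float
    mean_f: float | None


def strength_summary(
    instruments: AssociationTable, n: int | None = None, sd: float = 1.0
) -> InstrumentStrength:
    """Aggregate R² (sum) and F (mean over SNPs with a usable N).

    Per-SNP N falls back to ``n`` and then to the table-level default;
    when no N is available the SNP's F is reported missing, never zero.
    SNPs with missing EAF contribute no R² term and no F.
    """
    if len(instruments) == 0:
        raise ValueError("strength_summary needs a nonempty instrument table")
    per_r2: dict[str, float] = {}
    per_f: dict[str, float | None] = {}
    for rec in instruments:
        if rec.eaf is None:
            per_f[rec.snp_id] = None
            continue
        r2 = variant_r2(rec.beta, rec.eaf, sd)
        per_r2[rec.snp_id] = r2
        n_snp = rec.n if rec.n is not None else (n or instruments.sample_size_default)
        per_f[rec.snp_id] = f_statistic(r2, n_snp) if (n_snp and n_snp > 2) else None
    total = sum(per_r2.values())
    fs = [f for f in per_f.values() if f is not None]
    mean_f = sum(fs) / len(fs) if fs else None
    return InstrumentStrength(per_snp_r2=per_r2, per_snp_f=per_f, total_r2=total, mean_f=mean_f)
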