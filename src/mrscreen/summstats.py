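"""GWAS summary-statistics tables: reading, validation, writing, harmonization.

Two-sample MR consumes per-SNP association records from two independent
GWASs.  Before any estimator can run, the exposure and outcome records for
each shared SNP must be expressed relative to the same effect allele
("harmonization"): allele labels are compared, strand flips are resolved by
complementing, and palindromic (A/T, C/G) variants — whose strand cannot be
read off the labels — are oriented by allele frequency or dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the on-disk summary-statistics format
CANONICAL_COLUMNS = ("SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

#: EAF band within which a palindromic SNP's strand cannot be inferred
AMBIGUOUS_EAF_BAND = (0.42, 0.58)


class SummStatsError(ValueError):
    """Raised for unusable summary-statistics input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is per copy of ``effect_allele`` — SD units for continuous
    traits, log-odds for binary ones.  ``eaf`` and ``n`` may be ``None``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SummStatsError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise SummStatsError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise SummStatsError(f"{self.snp_id}: alleles identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise SummStatsError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise SummStatsError(f"{self.snp_id}: non-finite beta")
        if not (0.0 < self.pval <= 1.0):
            raise SummStatsError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummStatsError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise SummStatsError(f"{self.snp_id}: n must be positive, got {self.n}")

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class AssociationTable:
    """An ordered collection of :class:`VariantAssociation`, one trait.

    ``trait_unit`` is one of ``sd`` (standardized continuous), ``absolute``
    (natural continuous units) or ``log-odds`` (binary outcome).
    """

    trait_name: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    trait_unit: str = "sd"
    sample_size_default: int | None = None

    def __post_init__(self) -> None:
        if self.trait_unit not in ("sd", "absolute", "log-odds"):
            raise SummStatsError(f"unknown trait_unit {self.trait_unit!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> VariantAssociation:
        return self.records[snp_id]

    def add(self, rec: VariantAssociation) -> None:
        if rec.snp_id in self.records:
            raise SummStatsError(f"duplicate snp_id {rec.snp_id}")
        self.records[rec.snp_id] = rec

    def subset(self, snp_ids: Iterable[str]) -> "AssociationTable":
        keep = [s for s in snp_ids if s in self.records]
        return AssociationTable(
            trait_name=self.trait_name,
            records={s: self.records[s] for s in keep},
            trait_unit=self.trait_unit,
            sample_size_default=self.sample_size_default,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.snp_id,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pval,
                "N": r.n,
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned instrument pair.

    ``gamma_x``/``se_x`` are the SNP-exposure association, ``gamma_y``/
    ``se_y`` the SNP-outcome association, both per copy of the shared
    effect allele.  ``flipped`` records whether the outcome beta sign was
    reversed relative to its input orientation.
    """

    snp_id: str
    gamma_x: float
    se_x: float
    gamma_y: float
    se_y: float
    eaf: float | None = None
    palindromic: bool = False
    flipped: bool = False
    n_x: int | None = None
    n_y: int | None = None

    def __post_init__(self) -> None:
        if not (self.se_x > 0):
            raise SummStatsError(f"{self.snp_id}: se_x must be > 0")
        if not (self.se_y > 0):
            raise SummStatsError(f"{self.snp_id}: se_y must be > 0")


@dataclass
class ParseReport:
    """Per-row outcome of reading a summary-statistics file."""

    n_read: int = 0
    n_valid: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (row label, reason)
    duplicates_dropped: list[str] = field(default_factory=list)


_DEFAULT_COLUMN_MAP = {c: c for c in CANONICAL_COLUMNS}


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in (".", ""):
        return None
    return float(value)


def read_association_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_unit: str = "sd",
    sample_size_default: int | None = None,
    sep: str = "\t",
) -> AssociationTable:
    """Read a delimited summary-statistics file into an :class:`AssociationTable`.

    ``column_map`` maps canonical names (SNP, EA, OA, EAF, BETA, SE, P, N)
    to the file's column names.  ``'.'`` or empty cells are treated as
    missing.  Rows violating the per-record invariants are rejected and
    listed in the table's ``parse_report``; duplicate snp_ids keep the row
    with the smallest p-value.

    Raises
    ------
    SummStatsError
        If a mandatory column is absent or no row parses.
    """
    path = Path(path)
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mandatory = ("SNP", "EA", "OA", "BETA", "SE", "P")
    for canon in mandatory:
        if cmap[canon] not in df.columns:
            raise SummStatsError(f"{path}: mandatory column {cmap[canon]!r} missing")
    have_eaf = cmap["EAF"] in df.columns
    have_n = cmap["N"] in df.columns

    report = ParseReport(n_read=len(df))
    parsed: list[VariantAssociation] = []
    for i, row in df.iterrows():
        label = str(row[cmap["SNP"]]) or f"row {i}"
        try:
            n_val = _parse_optional_float(row[cmap["N"]]) if have_n else None
            rec = VariantAssociation(
                snp_id=str(row[cmap["SNP"]]).strip(),
                effect_allele=str(row[cmap["EA"]]).strip().upper(),
                other_allele=str(row[cmap["OA"]]).strip().upper(),
                eaf=_parse_optional_float(row[cmap["EAF"]]) if have_eaf else None,
                beta=float(row[cmap["BETA"]]),
                se=float(row[cmap["SE"]]),
                pval=float(row[cmap["P"]]),
                n=int(n_val) if n_val is not None else None,
            )
        except (SummStatsError, ValueError) as exc:
            report.rejected.append((label, str(exc)))
            logger.warning("%s: rejected row %s: %s", path, label, exc)
            continue
        parsed.append(rec)

    # duplicate snp_id: keep the smallest p-value, deterministic on ties
    best: dict[str, VariantAssociation] = {}
    for rec in parsed:
        prev = best.get(rec.snp_id)
        if prev is None:
            best[rec.snp_id] = rec
        else:
            report.duplicates_dropped.append(rec.snp_id)
            if rec.pval < prev.pval:
                best[rec.snp_id] = rec

    if not best:
        raise SummStatsError(f"{path}: zero valid rows")
    report.n_valid = len(best)
    table = AssociationTable(
        trait_name=trait_name or path.stem,
        records=best,
        trait_unit=trait_unit,
        sample_size_default=sample_size_default,
    )
    table.parse_report = report  # type: ignore[attr-defined]
    return table


def write_association_table(table: AssociationTable, path: str | Path, sep: str = "\t") -> Path:
    """Write ``table`` as delimited text, rows sorted by snp_id, '.' = missing."""
    if len(table) == 0:
        raise SummStatsError("refusing to write an empty table")
    path = Path(path)
    df = table.to_dataframe().sort_values("SNP", kind="mergesort").reset_index(drop=True)
    df["N"] = df["N"].map(lambda v: "." if pd.isna(v) else str(int(v)))
    df["EAF"] = df["EAF"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    for col in ("BETA", "SE", "P"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, sep=sep, index=False)
    return path


@dataclass
class HarmonizationLog:
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)
    n_flipped: int = 0
    n_palindromic_kept: int = 0


def _orient_outcome(
    ex: VariantAssociation, out: VariantAssociation
) -> tuple[float, float | None, bool] | None:
    """Align ``out`` to ``ex``'s effect allele by label / strand complement.

    Returns (oriented beta, oriented eaf, flipped) or ``None`` when the
    allele pairs are irreconcilable.  Palindromic pairs are *not* resolved
    here (labels match both orientations); the caller handles them.
    """
    ea_x, oa_x = ex.effect_allele, ex.other_allele
    pairs = [
        (out.effect_allele, out.other_allele, out.beta, out.eaf, False),
        (out.other_allele, out.effect_allele, -out.beta,
         None if out.eaf is None else 1.0 - out.eaf, True),
    ]
    for ea, oa, beta, eaf, flipped in pairs:
        if (ea, oa) == (ea_x, oa_x):
            return beta, eaf, flipped
    for ea, oa, beta, eaf, flipped in pairs:
        if (COMPLEMENT[ea], COMPLEMENT[oa]) == (ea_x, oa_x):
            return beta, eaf, flipped
    return None


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    palindrome_policy: str = "infer",
    ambiguous_band: tuple[float, float] = AMBIGUOUS_EAF_BAND,
    log: HarmonizationLog | None = None,
) -> list[HarmonizedInstrument]:
    """Align outcome associations to each exposure SNP's effect allele.

    Only SNPs present in both tables are returned, in exposure-table order.
    When the outcome's effect allele is the exposure's other allele, the
    outcome beta is sign-flipped and its EAF replaced by 1 − EAF; strand
    mismatches are resolved by complementing when unambiguous.

    Palindromic SNPs (A/T or C/G) are handled per ``palindrome_policy``:

    - ``"infer"`` (default): keep the SNP and orient by allele frequency,
      requiring both EAFs outside ``ambiguous_band``; drop otherwise, and
      drop when either EAF is missing.
    - ``"drop"``: drop all palindromic SNPs.

    Irreconcilable allele pairs are dropped (and logged), never fatal.
    """
    if palindrome_policy not in ("infer", "drop"):
        raise SummStatsError(f"unknown palindrome_policy {palindrome_policy!r}")
    if log is None:
        log = HarmonizationLog()
    lo, hi = ambiguous_band
    out: list[HarmonizedInstrument] = []
    for ex in exposure:
        rec = outcome.records.get(ex.snp_id)
        if rec is None:
            log.dropped.append((ex.snp_id, "absent from outcome"))
            continue
        if ex.palindromic:
            if palindrome_policy == "drop":
                log.dropped.append((ex.snp_id, "palindromic (drop-all policy)"))
                continue
            if {rec.effect_allele, rec.other_allele} != {ex.effect_allele, ex.other_allele}:
                log.dropped.append((ex.snp_id, "palindromic, outcome alleles differ"))
                continue
            if ex.eaf is None or rec.eaf is None:
                log.dropped.append((ex.snp_id, "palindromic, EAF missing"))
                continue
            # nominal label alignment first, then frequency check
            if rec.effect_allele == ex.effect_allele:
                beta_y, eaf_y, flipped = rec.beta, rec.eaf, False
            else:
                beta_y, eaf_y, flipped = -rec.beta, 1.0 - rec.eaf, True
            if not (ex.eaf < lo or ex.eaf > hi) or not (eaf_y < lo or eaf_y > hi):
                log.dropped.append((ex.snp_id, "palindromic, EAF ambiguous"))
                continue
            if (ex.eaf < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y, flipped = -beta_y, 1.0 - eaf_y, not flipped
            palindromic = True
            log.n_palindromic_kept += 1
        else:
            oriented = _orient_outcome(ex, rec)
            if oriented is None:
                log.dropped.append((ex.snp_id, "irreconcilable alleles"))
                continue
            beta_y, eaf_y, flipped = oriented
            palindromic = False
        if flipped:
            log.n_flipped += 1
        n_x = ex.n if ex.n is not None else exposure.sample_size_default
        n_y = rec.n if rec.n is not None else outcome.sample_size_default
        out.append(
            HarmonizedInstrument(
                snp_id=ex.snp_id,
                gamma_x=ex.beta,
                se_x=ex.se,
                gamma_y=beta_y,
                se_y=rec.se,
                eaf=ex.eaf if ex.eaf is not None else eaf_y,
                palindromic=palindromic,
                flipped=flipped,
                n_x=n_x,
                n_y=n_y,
            )
        )
    for snp_id, reason in log.dropped:
        logger.info("harmonize: dropped %s (%s)", snp_id, reason)
    return out


@dataclass
class ProxyLog:
    substituted: list[tuple[str, str, float]] = field(default_factory=list)  # (snp, proxy, r2)
    removed: list[str] = field(default_factory=list)


def read_proxy_map(path: str | Path, sep: str = "\t") -> dict[str, tuple[str, float]]:
    """Read a SNP → (proxy, r²) map from a TSV with columns SNP, PROXY, R2."""
    df = pd.read_csv(path, sep=sep)
    for col in ("SNP", "PROXY", "R2"):
        if col not in df.columns:
            raise SummStatsError(f"{path}: proxy map column {col!r} missing")
    out: dict[str, tuple[str, float]] = {}
    for _, row in df.iterrows():
        r2 = float(row["R2"])
        if not (0.0 < r2 <= 1.0):
            raise SummStatsError(f"{path}: proxy r2 must be in (0, 1], got {r2}")
        out[str(row["SNP"])] = (str(row["PROXY"]), r2)
    return out


def apply_proxies(
    instruments: AssociationTable,
    proxy_map: Mapping[str, tuple[str, float]],
    outcome: AssociationTable,
    r2_min: float = 0.8,
    log: ProxyLog | None = None,
) -> AssociationTable:
    """Substitute proxies for instrument SNPs absent from the outcome table.

    A SNP missing from ``outcome`` is replaced by its mapped proxy only when
    the map's r² exceeds ``r2_min`` and the proxy is present in ``outcome``
    (the exposure association is carried over under the proxy's id, which at
    r² > 0.8 is a near-identical signal).  SNPs with no admissible proxy are
    removed.  SNPs already present in the outcome pass through unchanged.
    """
    if log is None:
        log = ProxyLog()
    records: dict[str, VariantAssociation] = {}
    for rec in instruments:
        if rec.snp_id in outcome:
            records[rec.snp_id] = rec
            continue
        entry = proxy_map.get(rec.snp_id)
        if entry is not None:
            proxy_id, r2 = entry
            if r2 > r2_min and proxy_id in outcome and proxy_id not in records:
                records[proxy_id] = replace(rec, snp_id=proxy_id)
                log.substituted.append((rec.snp_id, proxy_id, r2))
                continue
        log.removed.append(rec.snp_id)
    logger.info(
        "apply_proxies: %d substituted, %d removed", len(log.substituted), len(log.removed)
    )
    return AssociationTable(
        trait_name=instruments.trait_name,
        records=records,
        trait_unit=instruments.trait_unit,
        sample_size_default=instruments.sample_size_default,
    )
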