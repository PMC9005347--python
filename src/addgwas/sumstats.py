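"""Per-study GWAS summary statistics: parsing, harmonization, QC and proxy correction.

A study's association records are held in a :class:`pandas.DataFrame` with the
canonical columns

    CHR  POS  REF  ALT  EA  BETA  SE  P  EAF  INFO  N_CASES  N_CONTROLS

where ``POS`` is 1-based on GRCh38, ``EA`` is the effect allele the signed
``BETA`` (log odds ratio) refers to, ``EAF`` its frequency, and ``INFO`` the
imputation quality in [0, 1].  Variants are identified by ``chr:pos:ref:alt``
strings (e.g. ``"6:32657066:G:A"``).

Two study designs are supported: ``case_control`` studies of clinically
diagnosed dementia, and ``proxy`` studies in which parental dementia stands in
for case status.  Proxy effects are estimated on a halved scale and are
rescaled to the case-control scale by multiplying beta and its standard error
by two (:func:`correct_proxy`); the z-statistic and p-value are unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "APOE_REGION",
    "GenomicRegion",
    "StudySumstats",
    "QCThresholds",
    "QCReport",
    "SumstatsFormatError",
    "ProxyCorrectionError",
    "variant_ids",
    "read_sumstats",
    "harmonize_to_alt",
    "apply_variant_qc",
    "correct_proxy",
    "genomic_lambda",
    "write_sumstats",
]

CANONICAL_COLUMNS = [
    "CHR", "POS", "REF", "ALT", "EA", "BETA", "SE", "P",
    "EAF", "INFO", "N_CASES", "N_CONTROLS",
]
#: columns a file must provide (P is recomputed from BETA/SE when absent)
MANDATORY_COLUMNS = ["CHR", "POS", "REF", "ALT", "EA", "BETA", "SE"]

_NUMERIC_COLUMNS = ["POS", "BETA", "SE", "P", "EAF", "INFO", "N_CASES", "N_CONTROLS"]

#: median of the chi-square distribution with one degree of freedom
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


class SumstatsFormatError(ValueError):
    """A summary-statistics file is missing mandatory columns or is unreadable."""


class ProxyCorrectionError(ValueError):
    """Proxy rescaling applied to a study it does not apply to."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: Sequence | np.ndarray, pos: Sequence | np.ndarray) -> np.ndarray:
        """Vectorized membership test for arrays of chromosome labels / positions."""
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == str(self.chrom)) & (pos >= self.start) & (pos <= self.end)

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            str(self.chrom) == str(other.chrom)
            and self.start <= other.end
            and other.start <= self.end
        )


#: the APOE region on GRCh38, excluded from genomic-control and locus definition
APOE_REGION = GenomicRegion("19", 44_000_000, 46_000_000)


def variant_ids(df: pd.DataFrame) -> pd.Series:
    """``chr:pos:ref:alt`` identifier for each record."""
    return (
        df["CHR"].astype(str)
        + ":" + df["POS"].astype(np.int64).astype(str)
        + ":" + df["REF"].astype(str)
        + ":" + df["ALT"].astype(str)
    )


@dataclass
class StudySumstats:
    """One study's per-variant association records plus design metadata."""

    study_id: str
    design: str  # "case_control" or "proxy"
    records: pd.DataFrame
    total_cases: int = 0
    proxy_corrected: bool = False
    parse_errors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.design not in ("case_control", "proxy"):
            raise ValueError(f"unknown study design {self.design!r}")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def copy_with(self, records: pd.DataFrame) -> "StudySumstats":
        return StudySumstats(
            study_id=self.study_id,
            design=self.design,
            records=records,
            total_cases=self.total_cases,
            proxy_corrected=self.proxy_corrected,
            parse_errors=list(self.parse_errors),
        )


def read_sumstats(
    path: str | Path,
    study_id: str | None = None,
    design: str = "case_control",
    dialect: Mapping[str, str] | None = None,
    total_cases: int | None = None,
) -> StudySumstats:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps canonical column names to the file's own header names,
    e.g. ``{"CHR": "chromosome", "BETA": "b"}``.  Rows whose mandatory numeric
    fields cannot be parsed are reported in ``parse_errors`` (row number and
    reason), never silently dropped.  A missing ``P`` column or value is
    recomputed from BETA/SE under the two-sided normal convention.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsFormatError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory column(s) {missing}")

    df = raw.copy()
    for col in _NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    errors: list[tuple[int, str]] = []
    bad = pd.Series(False, index=df.index)
    for col in ("POS", "BETA", "SE"):
        col_bad = df[col].isna()
        for idx in df.index[col_bad & ~bad]:
            errors.append((int(idx) + 2, f"unparseable or missing {col}"))  # +2: header + 1-based
        bad |= col_bad
    df = df[~bad].copy()

    df["POS"] = df["POS"].astype(np.int64)
    for col in ("CHR", "REF", "ALT", "EA"):
        df[col] = df[col].astype(str).str.upper().str.replace("CHR", "", regex=False)
    if "P" not in df.columns:
        df["P"] = np.nan
    need_p = df["P"].isna() & (df["SE"] > 0)
    df.loc[need_p, "P"] = 2.0 * stats.norm.sf(np.abs(df.loc[need_p, "BETA"] / df.loc[need_p, "SE"]))
    for col in ("EAF", "INFO", "N_CASES", "N_CONTROLS"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS].reset_index(drop=True)

    if total_cases is None:
        total_cases = int(np.nanmax(df["N_CASES"])) if df["N_CASES"].notna().any() else 0
    return StudySumstats(
        study_id=study_id or path.stem,
        design=design,
        records=df,
        total_cases=total_cases,
        parse_errors=errors,
    )


def write_sumstats(study: StudySumstats, path: str | Path) -> None:
    """Write a study's records in the canonical tab-delimited layout."""
    study.records.to_csv(path, sep="\t", index=False)


def harmonize_to_alt(study: StudySumstats) -> StudySumstats:
    """Re-orient every record so that the effect allele is the ALT allele.

    Records with ``EA == REF`` get ``BETA`` sign-flipped and ``EAF → 1−EAF``;
    records whose effect allele matches neither REF nor ALT are reported in
    ``parse_errors`` and dropped.
    """
    df = study.records.copy()
    is_ref = df["EA"] == df["REF"]
    is_alt = df["EA"] == df["ALT"]
    out = study.copy_with(df)
    neither = ~(is_ref | is_alt)
    if neither.any():
        for idx in df.index[neither]:
            out.parse_errors.append((int(idx), "effect allele matches neither REF nor ALT"))
        df = df[~neither]
        is_ref = is_ref[~neither]
    df = df.copy()
    df.loc[is_ref, "BETA"] = -df.loc[is_ref, "BETA"]
    df.loc[is_ref, "EAF"] = 1.0 - df.loc[is_ref, "EAF"]
    df.loc[is_ref, "EA"] = df.loc[is_ref, "ALT"]
    out.records = df.reset_index(drop=True)
    return out


@dataclass(frozen=True)
class QCThresholds:
    """Per-variant QC thresholds (defaults are the pipeline's standard values)."""

    max_abs_beta: float = 5.0
    min_info: float = 0.3
    min_mac_info: float = 20.0
    #: extra pre-filter applied to proxy-design studies (MAF > 0.01 %, MAC > 3)
    proxy_prefilter: bool = True
    proxy_min_maf: float = 1e-4
    proxy_min_mac: float = 3.0


@dataclass
class QCReport:
    """Per-rule removal counts for one study's QC pass."""

    study_id: str
    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert sum(self.removed.values()) == self.n_input - self.n_output


#: rule evaluation order used only to attribute a removed record to one rule
QC_RULE_ORDER = ["duplicate", "missing", "effect-size", "info", "mac-info",
                 "proxy-maf", "proxy-mac"]


def mac(df: pd.DataFrame) -> pd.Series:
    """Minor allele count: ``floor(2·N·min(EAF, 1−EAF))`` with N = cases + controls."""
    n = df["N_CASES"].fillna(0) + df["N_CONTROLS"].fillna(0)
    maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
    return np.floor(2.0 * n * maf)


def apply_variant_qc(
    study: StudySumstats, thresholds: QCThresholds | None = None
) -> tuple[StudySumstats, QCReport]:
    """Apply the per-variant QC rules and report per-rule removal counts.

    Rules: (duplicate) all records of a variant key appearing more than once
    are removed; (missing) records lacking BETA, SE or P; (effect-size)
    ``|BETA| > 5``; (info) imputation quality below 0.3; (mac-info) the
    product of minor allele count and imputation quality below 20.  Proxy
    studies additionally drop MAF ≤ 0.01 % and MAC ≤ 3 when the proxy
    pre-filter is on.  The retained set is independent of rule order; a record
    violating several rules is counted once, under the first rule in
    :data:`QC_RULE_ORDER`.  Records where EAF or INFO is unavailable are not
    assessable by the frequency-based rules and pass them.
    """
    thresholds = thresholds or QCThresholds()
    df = study.records
    ids = variant_ids(df)
    violations: dict[str, pd.Series] = {}
    violations["duplicate"] = ids.duplicated(keep=False)
    violations["missing"] = df["BETA"].isna() | df["SE"].isna() | df["P"].isna()
    violations["effect-size"] = df["BETA"].abs() > thresholds.max_abs_beta
    violations["info"] = df["INFO"].notna() & (df["INFO"] < thresholds.min_info)
    mac_info = mac(df) * df["INFO"]
    violations["mac-info"] = mac_info.notna() & (mac_info < thresholds.min_mac_info)
    if study.design == "proxy" and thresholds.proxy_prefilter:
        maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
        violations["proxy-maf"] = maf.notna() & (maf <= thresholds.proxy_min_maf)
        violations["proxy-mac"] = mac(df).notna() & (mac(df) <= thresholds.proxy_min_mac)

    removed_any = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    for rule in QC_RULE_ORDER:
        if rule not in violations:
            continue
        newly = violations[rule] & ~removed_any
        counts[rule] = int(newly.sum())
        removed_any |= violations[rule]

    kept = df[~removed_any].reset_index(drop=True)
    report = QCReport(
        study_id=study.study_id,
        n_input=len(df),
        n_output=len(kept),
        removed=counts,
    )
    return study.copy_with(kept), report


def correct_proxy(study: StudySumstats) -> StudySumstats:
    """Rescale a proxy study's effects to the case-control scale.

    Proxy (parental-history) effects are estimated on a halved scale, so beta
    and its standard error are both multiplied by two; z-statistics and
    p-values are unchanged.  Guarded against double application.
    """
    if study.design != "proxy":
        raise ProxyCorrectionError(
            f"study {study.study_id!r} has design {study.design!r}; "
            "proxy correction applies only to proxy studies"
        )
    if study.proxy_corrected:
        raise ProxyCorrectionError(
            f"study {study.study_id!r} has already been proxy-corrected"
        )
    df = study.records.copy()
    df["BETA"] = 2.0 * df["BETA"]
    df["SE"] = 2.0 * df["SE"]
    out = study.copy_with(df)
    out.proxy_corrected = True
    return out


def genomic_lambda(
    pvalues: Sequence | np.ndarray | pd.Series,
    chrom: Sequence | None = None,
    pos: Sequence | None = None,
    exclude: GenomicRegion | None = APOE_REGION,
) -> float:
    """Genomic inflation factor by the median method.

    ``λ = median(χ²) / 0.4549364`` where ``χ² = [Φ⁻¹(1 − p/2)]²``.  When
    coordinates are supplied, variants inside ``exclude`` (default the APOE
    region, chr19:44–46 Mb on GRCh38) are removed first.
    """
    p = np.asarray(pvalues, dtype=float)
    if chrom is not None and pos is not None and exclude is not None:
        inside = exclude.contains(np.asarray(chrom), np.asarray(pos))
        p = p[~inside]
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values remain after exclusion")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def pvalue_from_z(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value (underflows to 0 below ~1e-308; see log10_pvalue_from_z)."""
    return 2.0 * stats.norm.sf(np.abs(z))


def log10_pvalue_from_z(z: np.ndarray | float) -> np.ndarray | float:
    """log10 of the two-sided normal p-value, computed in log space.

    Survives |z| far beyond the double-precision underflow point, which the
    strongest dementia association signals exceed.
    """
    return (np.log(2.0) + stats.norm.logsf(np.abs(z))) / math.log(10.0)
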