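"""Fixed-effect inverse-variance-weighted (IVW) meta-analysis across studies.

For one variant with per-study estimates (βᵢ, seᵢ) and weights wᵢ = 1/seᵢ²::

    β = Σ wᵢ βᵢ / Σ wᵢ          se = 1 / sqrt(Σ wᵢ)
    Q = Σ wᵢ (βᵢ − β)²          het_p = P[χ²_{k−1} ≥ Q]

p-values are two-sided normal on z = β/se and are additionally carried in
log10 space so that associations far below the double-precision underflow
point remain ordered.

After meta-analysis, variants are filtered on (1) heterogeneity p-value,
(2) the fraction of total cases contributed by the analyzing studies,
(3) the frequency amplitude (max − min effect-allele frequency across
studies) and (4) presence in a designated reference study.  Stage I and
stage II estimates combine by the same IVW rule, which is algebraically
identical to pooling all underlying studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    StudySumstats,
    log10_pvalue_from_z,
    variant_ids,
)

__all__ = [
    "MetaVariant",
    "MetaFilterThresholds",
    "FilterDecision",
    "HarmonizationError",
    "ivw_meta",
    "meta_analyze",
    "post_meta_filter",
    "apply_meta_filters",
    "combine_stages",
    "combine_stage_frames",
]

META_COLUMNS = [
    "CHR", "POS", "REF", "ALT", "BETA", "SE", "Z", "P", "LOG10_P",
    "Q", "HET_P", "N_STUDIES", "CASE_FRACTION", "FREQ_AMP", "IN_REFERENCE",
]


class HarmonizationError(ValueError):
    """Per-study records for one variant disagree on key or effect allele."""


@dataclass
class MetaVariant:
    """Combined effect, heterogeneity and filter diagnostics for one variant."""

    key: str
    beta: float
    se: float
    p: float
    log10_p: float
    q_stat: float
    het_p: float
    n_studies: int
    case_fraction: float = float("nan")
    freq_amplitude: float = float("nan")
    in_reference: bool = True

    @property
    def z(self) -> float:
        return self.beta / self.se


def _finalize(beta: np.ndarray, se: np.ndarray, q: np.ndarray, k: np.ndarray):
    z = beta / se
    log10_p = log10_pvalue_from_z(z)
    p = np.power(10.0, np.maximum(log10_p, -323.0))  # floor at smallest subnormal decade
    het_p = np.where(k > 1, stats.chi2.sf(q, np.maximum(k - 1, 1)), 1.0)
    return z, p, log10_p, het_p


def ivw_meta(per_study: pd.DataFrame) -> MetaVariant:
    """IVW meta-analysis of one variant's per-study records.

    ``per_study`` holds one row per study with at least BETA and SE (plus
    optionally CHR/POS/REF/ALT/EA for key checks, EAF for the frequency
    amplitude and N_CASES for the case fraction numerator).  Alleles must be
    harmonized beforehand; disagreement raises :class:`HarmonizationError`.
    """
    if len(per_study) == 0:
        raise ValueError("no study records supplied")
    df = per_study
    key = ""
    if {"CHR", "POS", "REF", "ALT"}.issubset(df.columns):
        ids = variant_ids(df)
        if ids.nunique() > 1:
            raise HarmonizationError(f"records span several variants: {sorted(ids.unique())}")
        key = ids.iloc[0]
        if "EA" in df.columns and df["EA"].nunique() > 1:
            raise HarmonizationError(f"effect alleles disagree for {key}")
    w = 1.0 / df["SE"].to_numpy() ** 2
    b = df["BETA"].to_numpy()
    sumw = w.sum()
    beta = float((w * b).sum() / sumw)
    se = float(1.0 / np.sqrt(sumw))
    q = float((w * (b - beta) ** 2).sum())
    k = len(df)
    z, p, log10_p, het_p = _finalize(
        np.array([beta]), np.array([se]), np.array([q]), np.array([k])
    )
    eaf = df["EAF"].to_numpy(dtype=float) if "EAF" in df.columns else np.array([np.nan])
    freq_amp = float(np.nanmax(eaf) - np.nanmin(eaf)) if np.isfinite(eaf).any() else float("nan")
    return MetaVariant(
        key=key,
        beta=beta,
        se=se,
        p=float(p[0]),
        log10_p=float(log10_p[0]),
        q_stat=q,
        het_p=float(het_p[0]),
        n_studies=k,
        freq_amplitude=freq_amp,
    )


def meta_analyze(
    studies: list[StudySumstats],
    total_cases: int | None = None,
    reference_study: str | None = None,
) -> pd.DataFrame:
    """Meta-analyze all variants across a collection of harmonized studies.

    Returns one row per variant with the IVW estimate, heterogeneity
    statistics, the fraction of ``total_cases`` (default: the sum of the
    studies' case counts) contributed by the studies analyzing the variant,
    the cross-study frequency amplitude, and — when ``reference_study``
    names one of the studies — a flag for presence in that study.
    """
    if not studies:
        raise ValueError("no studies supplied")
    if total_cases is None:
        total_cases = sum(s.total_cases for s in studies)

    frames = []
    for s in studies:
        df = s.records
        part = pd.DataFrame({
            "ID": variant_ids(df),
            "CHR": df["CHR"].astype(str),
            "POS": df["POS"].astype(np.int64),
            "REF": df["REF"],
            "ALT": df["ALT"],
            "W": 1.0 / df["SE"].to_numpy() ** 2,
            "B": df["BETA"].to_numpy(),
            "EAF": df["EAF"].to_numpy(dtype=float),
            "CASES": df["N_CASES"].fillna(float(s.total_cases)).to_numpy(dtype=float),
            "IS_REF": s.study_id == reference_study,
        })
        frames.append(part)
    allrows = pd.concat(frames, ignore_index=True)
    allrows["WB"] = allrows["W"] * allrows["B"]
    allrows["WB2"] = allrows["W"] * allrows["B"] ** 2

    g = allrows.groupby("ID", sort=False)
    agg = g.agg(
        CHR=("CHR", "first"),
        POS=("POS", "first"),
        REF=("REF", "first"),
        ALT=("ALT", "first"),
        SUMW=("W", "sum"),
        SUMWB=("WB", "sum"),
        SUMWB2=("WB2", "sum"),
        N_STUDIES=("B", "size"),
        EAF_MIN=("EAF", "min"),
        EAF_MAX=("EAF", "max"),
        CASES=("CASES", "sum"),
        IN_REFERENCE=("IS_REF", "any"),
    )
    beta = (agg["SUMWB"] / agg["SUMW"]).to_numpy()
    se = (1.0 / np.sqrt(agg["SUMW"])).to_numpy()
    # Q = Σwβ² − (Σwβ)²/Σw, numerically clipped at zero
    q = np.maximum((agg["SUMWB2"] - agg["SUMWB"] ** 2 / agg["SUMW"]).to_numpy(), 0.0)
    k = agg["N_STUDIES"].to_numpy()
    z, p, log10_p, het_p = _finalize(beta, se, q, k)

    out = pd.DataFrame({
        "CHR": agg["CHR"],
        "POS": agg["POS"],
        "REF": agg["REF"],
        "ALT": agg["ALT"],
        "BETA": beta,
        "SE": se,
        "Z": z,
        "P": p,
        "LOG10_P": log10_p,
        "Q": q,
        "HET_P": het_p,
        "N_STUDIES": k,
        "CASE_FRACTION": (agg["CASES"] / total_cases if total_cases else np.nan),
        "FREQ_AMP": (agg["EAF_MAX"] - agg["EAF_MIN"]).to_numpy(),
        "IN_REFERENCE": agg["IN_REFERENCE"] if reference_study is not None else True,
    })
    out.index.name = "ID"
    return out.reset_index()


@dataclass(frozen=True)
class MetaFilterThresholds:
    """Post-meta variant filters; defaults are the pipeline's standard values."""

    het_p_min: float = 5e-8
    case_fraction_min: float = 0.20
    freq_amplitude_max: float = 0.40
    require_reference: bool = True


@dataclass
class FilterDecision:
    """Outcome of the post-meta filters for one variant."""

    key: str
    kept: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.kept == (len(self.reasons) == 0)


def post_meta_filter(
    mv: MetaVariant, thresholds: MetaFilterThresholds | None = None
) -> FilterDecision:
    """Evaluate every post-meta filter rule for one variant.

    A variant is removed when its heterogeneity p-value is below the
    threshold, when it was analyzed in less than the required fraction of
    total cases, when its frequency amplitude exceeds the maximum, or when it
    is absent from the designated reference study.  All violated rules are
    listed.
    """
    t = thresholds or MetaFilterThresholds()
    reasons = []
    if np.isfinite(mv.het_p) and mv.het_p < t.het_p_min:
        reasons.append("heterogeneity")
    if np.isfinite(mv.case_fraction) and mv.case_fraction < t.case_fraction_min:
        reasons.append("case-fraction")
    if np.isfinite(mv.freq_amplitude) and mv.freq_amplitude > t.freq_amplitude_max:
        reasons.append("frequency-amplitude")
    if t.require_reference and not mv.in_reference:
        reasons.append("not-in-reference")
    return FilterDecision(key=mv.key, kept=not reasons, reasons=reasons)


def apply_meta_filters(
    meta_df: pd.DataFrame, thresholds: MetaFilterThresholds | None = None
) -> pd.DataFrame:
    """Vectorized post-meta filters; adds KEPT and REASONS columns."""
    t = thresholds or MetaFilterThresholds()
    df = meta_df.copy()
    rules = {
        "heterogeneity": df["HET_P"].notna() & (df["HET_P"] < t.het_p_min),
        "case-fraction": df["CASE_FRACTION"].notna() & (df["CASE_FRACTION"] < t.case_fraction_min),
        "frequency-amplitude": df["FREQ_AMP"].notna() & (df["FREQ_AMP"] > t.freq_amplitude_max),
    }
    if t.require_reference:
        rules["not-in-reference"] = ~df["IN_REFERENCE"].astype(bool)
    reasons = pd.Series([[] for _ in range(len(df))], index=df.index)
    for name, mask in rules.items():
        for idx in df.index[mask]:
            reasons.loc[idx].append(name)
    df["REASONS"] = reasons.map(";".join)
    df["KEPT"] = df["REASONS"] == ""
    return df


def _row_to_mv(row: pd.Series) -> MetaVariant:
    return MetaVariant(
        key=str(row.get("ID", "")),
        beta=float(row["BETA"]),
        se=float(row["SE"]),
        p=float(row["P"]),
        log10_p=float(row["LOG10_P"]),
        q_stat=float(row["Q"]),
        het_p=float(row["HET_P"]),
        n_studies=int(row["N_STUDIES"]),
        case_fraction=float(row.get("CASE_FRACTION", np.nan)),
        freq_amplitude=float(row.get("FREQ_AMP", np.nan)),
        in_reference=bool(row.get("IN_REFERENCE", True)),
    )


def combine_stages(stage1: MetaVariant, stage2: MetaVariant) -> MetaVariant:
    """IVW combination of stage-level estimates for the same variant.

    Because IVW is associative, this equals the IVW of all underlying studies
    when each stage estimate is itself an IVW of its studies.  The
    heterogeneity statistic reported here is the between-stage Q (1 df); the
    frequency amplitude carries the larger of the two stages'.
    """
    if stage1.key and stage2.key and stage1.key != stage2.key:
        raise HarmonizationError(f"stage keys differ: {stage1.key} vs {stage2.key}")
    w = np.array([1.0 / stage1.se**2, 1.0 / stage2.se**2])
    b = np.array([stage1.beta, stage2.beta])
    sumw = w.sum()
    beta = float((w * b).sum() / sumw)
    se = float(1.0 / np.sqrt(sumw))
    q = float((w * (b - beta) ** 2).sum())
    z, p, log10_p, het_p = _finalize(
        np.array([beta]), np.array([se]), np.array([q]), np.array([2])
    )
    amps = [a for a in (stage1.freq_amplitude, stage2.freq_amplitude) if np.isfinite(a)]
    return MetaVariant(
        key=stage1.key or stage2.key,
        beta=beta,
        se=se,
        p=float(p[0]),
        log10_p=float(log10_p[0]),
        q_stat=q,
        het_p=float(het_p[0]),
        n_studies=stage1.n_studies + stage2.n_studies,
        case_fraction=float("nan"),
        freq_amplitude=max(amps) if amps else float("nan"),
        in_reference=stage1.in_reference and stage2.in_reference,
    )


def combine_stage_frames(stage1: pd.DataFrame, stage2: pd.DataFrame) -> pd.DataFrame:
    """Row-wise IVW combination of two stage-level meta frames, joined on ID.

    Only variants present in both stages are combined (follow-up covers a
    subset of stage I variants).
    """
    merged = stage1.merge(stage2, on="ID", suffixes=("_1", "_2"))
    w1 = 1.0 / merged["SE_1"].to_numpy() ** 2
    w2 = 1.0 / merged["SE_2"].to_numpy() ** 2
    sumw = w1 + w2
    beta = (w1 * merged["BETA_1"].to_numpy() + w2 * merged["BETA_2"].to_numpy()) / sumw
    se = 1.0 / np.sqrt(sumw)
    q = w1 * (merged["BETA_1"].to_numpy() - beta) ** 2 + w2 * (merged["BETA_2"].to_numpy() - beta) ** 2
    k = np.full(len(merged), 2)
    z, p, log10_p, het_p = _finalize(beta, se, q, k)
    return pd.DataFrame({
        "ID": merged["ID"],
        "CHR": merged["CHR_1"],
        "POS": merged["POS_1"],
        "REF": merged["REF_1"],
        "ALT": merged["ALT_1"],
        "BETA": beta,
        "SE": se,
        "Z": z,
        "P": p,
        "LOG10_P": log10_p,
        "Q": q,
        "HET_P": het_p,
        "N_STUDIES": merged["N_STUDIES_1"].to_numpy() + merged["N_STUDIES_2"].to_numpy(),
        "CASE_FRACTION": np.nan,
        "FREQ_AMP": np.nanmax(
            np.column_stack([merged["FREQ_AMP_1"], merged["FREQ_AMP_2"]]), axis=1
        ),
        "IN_REFERENCE": merged["IN_REFERENCE_1"].astype(bool)
        & merged["IN_REFERENCE_2"].astype(bool),
    })
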