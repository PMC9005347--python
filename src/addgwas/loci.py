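"""Locus definition: candidate regions, iterative LD clumping, significance calls.

A candidate region is the merge of ±500 kb windows around every variant with a
stage I p-value below 1e-5; regions overlapping the APOE region are dropped.
Within a region, clumping is greedy: the unassigned variant with the lowest
stage I p-value becomes an index, and every unassigned qualifying variant
within 500 kb of it and in LD with it (r² > 0.001) joins its clump, until all
qualifying variants are clumped.

A clump's signal is genome-wide significant when the lead variant has the same
direction of effect in stages I and II, a stage II p ≤ 0.05, and a combined
stage I + II p ≤ 5e-8.  Signals reaching 5e-8 combined without stage II
support are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import math

import numpy as np
import pandas as pd

from .meta import MetaVariant, combine_stages, _row_to_mv
from .sumstats import APOE_REGION, GenomicRegion

__all__ = [
    "Region",
    "LDProvider",
    "Clump",
    "LocusCall",
    "GENOME_WIDE_SIGNIFICANT",
    "STAGE2_UNSUPPORTED",
    "NOT_SIGNIFICANT",
    "merge_regions",
    "build_regions",
    "select_followup",
    "clump",
    "clump_regions",
    "call_locus",
    "call_loci",
]

#: re-export: regions are plain 1-based inclusive genomic intervals
Region = GenomicRegion

GENOME_WIDE_SIGNIFICANT = "genome_wide_significant"
STAGE2_UNSUPPORTED = "stage2_unsupported"
NOT_SIGNIFICANT = "not_significant"

DEFAULT_P1 = 1e-5
DEFAULT_WINDOW = 500_000
DEFAULT_R2 = 0.001
GWS_P = 5e-8
STAGE2_P = 0.05


class LDProvider(Protocol):
    """Pairwise r² lookup between variants identified by ``chr:pos:ref:alt``."""

    def r2(self, a: str, b: str) -> float: ...


@dataclass
class Clump:
    """A group of associated variants represented by an index (lead) variant."""

    index_variant: str
    members: list[str]
    index_p: float
    index_log10_p: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class LocusCall:
    """A clump's lead variant with its stage I/II/combined evidence and class."""

    clump: Clump
    lead: str
    stage1: MetaVariant
    stage2: MetaVariant | None
    combined: MetaVariant | None
    classification: str
    deferred: bool = False  # stage II missing: classification pending


def merge_regions(regions: Iterable[Region]) -> list[Region]:
    """Merge overlapping or exactly-adjacent (bookended) intervals per chromosome."""
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(str(r.chrom), []).append(r)
    merged: list[Region] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end + 1:  # bookended intervals merge
                cur_end = max(cur_end, r.end)
            else:
                merged.append(Region(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(Region(chrom, cur_start, cur_end))
    return merged


def _chrom_sort_key(c: str) -> tuple:
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def _log10_threshold(p_threshold: float) -> float:
    return math.log10(p_threshold)


def _qualifying(variants: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Variants strictly below the p threshold, compared in log10 space."""
    if "LOG10_P" in variants.columns:
        return variants[variants["LOG10_P"] < _log10_threshold(p_threshold)]
    return variants[variants["P"] < p_threshold]


def build_regions(
    variants: pd.DataFrame,
    p_threshold: float = DEFAULT_P1,
    window: int = DEFAULT_WINDOW,
    exclusions: Sequence[Region] = (APOE_REGION,),
) -> list[Region]:
    """±window regions around sub-threshold variants, merged; exclusions dropped.

    A merged region overlapping any exclusion region (by default the APOE
    region) is removed entirely.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    hits = _qualifying(variants, p_threshold)
    # the variant occupies [pos, pos]; the window extends it by `window` bp on
    # each side of its single base, giving a 2·window-long interval
    raw = [
        Region(str(chrom), max(1, int(pos) - window + 1), int(pos) + window)
        for chrom, pos in zip(hits["CHR"], hits["POS"])
    ]
    merged = merge_regions(raw) if raw else []
    return [r for r in merged if not any(r.overlaps(x) for x in exclusions)]


def select_followup(
    stage1: pd.DataFrame,
    p_threshold: float = DEFAULT_P1,
    exclusions: Sequence[Region] = (APOE_REGION,),
) -> list[str]:
    """Variant ids with stage I p strictly below threshold, outside exclusions."""
    hits = _qualifying(stage1, p_threshold)
    if len(hits) == 0:
        return []
    keep = np.ones(len(hits), dtype=bool)
    for x in exclusions:
        keep &= ~x.contains(hits["CHR"].to_numpy(), hits["POS"].to_numpy())
    return hits.loc[keep, "ID"].tolist()


def _order_key(row) -> tuple:
    # lowest p first; ties broken by chromosome, position, then alleles
    return (row.LOG10_P, _chrom_sort_key(row.CHR), row.POS, row.REF, row.ALT)


def clump(
    region_variants: pd.DataFrame,
    ld: LDProvider,
    p_threshold: float = DEFAULT_P1,
    window: int = DEFAULT_WINDOW,
    r2_threshold: float = DEFAULT_R2,
) -> list[Clump]:
    """Greedy iterative clumping of one region's variants.

    Repeatedly takes the unassigned variant with the lowest stage I p-value as
    an index and assigns to its clump every unassigned variant with p below
    ``p_threshold``, within ``window`` bp of the index (inclusive) and with
    r² with the index strictly above ``r2_threshold``.  Ties on p are broken
    by chromosome, position, then alleles, so the partition is deterministic.
    """
    qual = _qualifying(region_variants, p_threshold)
    if len(qual) == 0:
        return []
    if "LOG10_P" not in qual.columns:
        qual = qual.assign(LOG10_P=np.log10(qual["P"]))
    rows = sorted(qual.itertuples(index=False), key=_order_key)
    unassigned = {r.ID: r for r in rows}
    clumps: list[Clump] = []
    for row in rows:
        if row.ID not in unassigned:
            continue
        members = [
            other.ID
            for other in unassigned.values()
            if abs(other.POS - row.POS) <= window
            and (other.ID == row.ID or ld.r2(row.ID, other.ID) > r2_threshold)
        ]
        for m in members:
            del unassigned[m]
        clumps.append(
            Clump(
                index_variant=row.ID,
                members=members,
                index_p=float(row.P),
                index_log10_p=float(row.LOG10_P),
            )
        )
    return clumps


def clump_regions(
    stage1: pd.DataFrame,
    ld: LDProvider,
    p_threshold: float = DEFAULT_P1,
    window: int = DEFAULT_WINDOW,
    r2_threshold: float = DEFAULT_R2,
    exclusions: Sequence[Region] = (APOE_REGION,),
) -> list[tuple[Region, list[Clump]]]:
    """Build merged regions, then clump each region's variants."""
    regions = build_regions(stage1, p_threshold, window, exclusions)
    out = []
    for region in regions:
        inside = region.contains(stage1["CHR"].to_numpy(), stage1["POS"].to_numpy())
        out.append((region, clump(stage1[inside], ld, p_threshold, window, r2_threshold)))
    return out


def call_locus(
    stage1: MetaVariant,
    stage2: MetaVariant | None,
    combined: MetaVariant | None,
    gws_p: float = GWS_P,
    stage2_p: float = STAGE2_P,
) -> str:
    """Two-stage significance classification for one lead variant.

    genome_wide_significant: same effect direction in both stages, stage II
    p ≤ 0.05 and combined p ≤ 5e-8.  stage2_unsupported: combined p ≤ 5e-8
    but the stage II criteria fail.  Otherwise not_significant.  A missing
    stage II estimate defers classification (raises ValueError; callers flag
    the locus instead).
    """
    if stage2 is None or combined is None:
        raise ValueError("stage II estimate missing; classification deferred")
    combined_sig = combined.p <= gws_p or combined.log10_p <= math.log10(gws_p)
    supported = (np.sign(stage1.beta) == np.sign(stage2.beta)) and stage2.p <= stage2_p
    if combined_sig and supported:
        return GENOME_WIDE_SIGNIFICANT
    if combined_sig:
        return STAGE2_UNSUPPORTED
    return NOT_SIGNIFICANT


def call_loci(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame,
    ld: LDProvider,
    p_threshold: float = DEFAULT_P1,
    window: int = DEFAULT_WINDOW,
    r2_threshold: float = DEFAULT_R2,
    exclusions: Sequence[Region] = (APOE_REGION,),
    gws_p: float = GWS_P,
    stage2_p: float = STAGE2_P,
) -> list[LocusCall]:
    """End-to-end locus calling over stage I and stage II meta frames.

    In each clump the reported lead is the member with positive follow-up
    (same direction in both stages, stage II p ≤ 0.05) and the lowest
    combined p; when no member has positive follow-up the clump's index
    variant is reported and classified on its own evidence.  Clumps whose
    lead lacks a stage II estimate are returned with a deferred flag.
    """
    s1 = stage1.set_index("ID", drop=False)
    s2 = stage2.set_index("ID", drop=False)
    calls: list[LocusCall] = []
    for _, clumps in clump_regions(stage1, ld, p_threshold, window, r2_threshold, exclusions):
        for cl in clumps:
            best_lead, best_combined, best_log10p = None, None, np.inf
            followed = [m for m in cl.members if m in s2.index]
            for m in followed:
                mv1 = _row_to_mv(s1.loc[m])
                mv2 = _row_to_mv(s2.loc[m])
                comb = combine_stages(mv1, mv2)
                positive = (np.sign(mv1.beta) == np.sign(mv2.beta)) and mv2.p <= stage2_p
                if positive and comb.log10_p < best_log10p:
                    best_lead, best_combined, best_log10p = m, comb, comb.log10_p
            lead = best_lead or cl.index_variant
            mv1 = _row_to_mv(s1.loc[lead])
            if lead in s2.index:
                mv2 = _row_to_mv(s2.loc[lead])
                comb = best_combined if lead == best_lead else combine_stages(mv1, mv2)
                cls = call_locus(mv1, mv2, comb, gws_p, stage2_p)
                calls.append(LocusCall(cl, lead, mv1, mv2, comb, cls))
            else:
                calls.append(LocusCall(cl, lead, mv1, None, None, NOT_SIGNIFICANT, deferred=True))
    return calls


def locus_table(calls: list[LocusCall]) -> pd.DataFrame:
    """Tab-delimited-friendly report of locus calls."""
    rows = []
    for c in calls:
        rows.append({
            "LEAD": c.lead,
            "INDEX_VARIANT": c.clump.index_variant,
            "CLUMP_SIZE": c.clump.size,
            "BETA_STAGE1": c.stage1.beta,
            "SE_STAGE1": c.stage1.se,
            "P_STAGE1": c.stage1.p,
            "BETA_STAGE2": c.stage2.beta if c.stage2 else np.nan,
            "P_STAGE2": c.stage2.p if c.stage2 else np.nan,
            "BETA_COMBINED": c.combined.beta if c.combined else np.nan,
            "SE_COMBINED": c.combined.se if c.combined else np.nan,
            "P_COMBINED": c.combined.p if c.combined else np.nan,
            "LOG10_P_COMBINED": c.combined.log10_p if c.combined else np.nan,
            "CLASSIFICATION": c.classification,
            "DEFERRED": c.deferred,
        })
    return pd.DataFrame(rows)
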