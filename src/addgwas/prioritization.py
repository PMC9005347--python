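"""Evidence-weighted gene prioritization with tier classification.

Candidate protein-coding genes within ±1 Mb of a locus lead variant are scored
by a weighted sum of prioritization evidence across seven domains — variant
annotation, eQTL-, sQTL-, pQTL-, mQTL- and haQTL-GWAS integration, and an APP
metabolism siRNA screen.  Replicated hits outweigh single hits and
brain-derived evidence outweighs peripheral evidence.  Per locus, the ranked
scores and their relative differences classify genes as tier 1 (a single
clearly leading gene with a minimum absolute score), tier 2 (the leading gene
without that margin, or close runners-up), or unranked.

Evidence catalogs are tab-delimited with columns::

    LOCUS_ID  GENE_ID  DOMAIN  CATEGORY  SUBCATEGORY  UNIT_ID  DATASET_ID  BLOOD_BRAIN_CORR

Gene annotations are BED-like tables with columns
``GENE_ID SYMBOL CHR START END PROTEIN_CODING`` (1-based inclusive
coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DOMAINS",
    "WeightConfig",
    "WeightConfigError",
    "GeneScore",
    "TIER1",
    "TIER2",
    "UNRANKED",
    "load_weights",
    "default_weights",
    "select_candidates",
    "assign_candidates",
    "annotate_variant_domain",
    "aggregate_evidence",
    "score_gene",
    "classify_tiers",
    "prioritize_locus",
    "prioritize_loci",
]

DOMAINS = ["variant_annotation", "eqtl", "sqtl", "pqtl", "mqtl", "haqtl", "app_metabolism"]

EVIDENCE_COLUMNS = [
    "LOCUS_ID", "GENE_ID", "DOMAIN", "CATEGORY", "SUBCATEGORY",
    "UNIT_ID", "DATASET_ID", "BLOOD_BRAIN_CORR",
]

TIER1 = "tier1"
TIER2 = "tier2"
UNRANKED = "unranked"

DEFAULT_CANDIDATE_WINDOW = 1_000_000
RARE_MAF = 0.01


class WeightConfigError(KeyError):
    """An evidence item has no configured weight, or the config is malformed."""


@dataclass
class WeightConfig:
    """Evidence weights keyed by (domain, tissue class, subcategory, replication)."""

    weights: dict
    max_score: float
    brain_categories: frozenset
    peripheral_categories: frozenset

    def tissue_class(self, category: str) -> str:
        if category in self.brain_categories:
            return "brain"
        if category in self.peripheral_categories:
            return "peripheral"
        return "na"

    def weight(self, domain: str, category: str, subcategory: str, replicated: bool) -> float:
        cls = self.tissue_class(category)
        try:
            entry = self.weights[domain][subcategory][cls]
            return float(entry["replicated" if replicated else "single"])
        except KeyError:
            raise WeightConfigError(
                f"no weight configured for (domain={domain!r}, category={category!r} "
                f"[class={cls!r}], subcategory={subcategory!r}, "
                f"replicated={replicated})"
            ) from None

    def validate(self) -> None:
        """Check the ordering constraints: replicated ≥ single, brain ≥ peripheral."""
        if self.max_score <= 0:
            raise WeightConfigError("max_score must be positive")
        for domain, subs in self.weights.items():
            for sub, classes in subs.items():
                for cls, entry in classes.items():
                    single = float(entry["single"])
                    rep = float(entry.get("replicated", entry["single"]))
                    if rep < single or single < 0:
                        raise WeightConfigError(
                            f"replicated weight below single for {domain}/{sub}/{cls}"
                        )
                if "brain" in classes and "peripheral" in classes:
                    for kind in ("single", "replicated"):
                        b = float(classes["brain"].get(kind, classes["brain"]["single"]))
                        p = float(classes["peripheral"].get(kind, classes["peripheral"]["single"]))
                        if b < p:
                            raise WeightConfigError(
                                f"brain weight below peripheral for {domain}/{sub} ({kind})"
                            )

    def scaled(self, c: float) -> "WeightConfig":
        """All weights and the normalizer multiplied by c (scale invariance)."""
        scaled = {
            d: {s: {k: {m: float(v) * c for m, v in e.items()} for k, e in cl.items()}
                for s, cl in subs.items()}
            for d, subs in self.weights.items()
        }
        return WeightConfig(scaled, self.max_score * c,
                            self.brain_categories, self.peripheral_categories)


def load_weights(path: str | Path) -> WeightConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = WeightConfig(
        weights=raw["weights"],
        max_score=float(raw["max_score"]),
        brain_categories=frozenset(raw.get("brain_categories", [])),
        peripheral_categories=frozenset(raw.get("peripheral_categories", [])),
    )
    cfg.validate()
    return cfg


def default_weights() -> WeightConfig:
    """The packaged exemplar weight table (see data/weights.yaml)."""
    ref = resources.files("addgwas").joinpath("data/weights.yaml")
    with resources.as_file(ref) as path:
        return load_weights(path)


# ---------------------------------------------------------------------------
# candidate selection

def select_candidates(
    lead_chrom: str,
    lead_pos: int,
    genes: pd.DataFrame,
    window: int = DEFAULT_CANDIDATE_WINDOW,
) -> list[str]:
    """Protein-coding genes whose interval intersects lead ± window."""
    g = genes[genes["PROTEIN_CODING"].astype(bool)]
    g = g[g["CHR"].astype(str) == str(lead_chrom)]
    hit = (g["END"] >= lead_pos - window) & (g["START"] <= lead_pos + window)
    return g.loc[hit, "GENE_ID"].tolist()


def _gene_distance(lead_pos: int, start: int, end: int) -> int:
    """bp from the lead to the nearest gene edge; 0 if the lead lies inside."""
    if start <= lead_pos <= end:
        return 0
    return int(min(abs(lead_pos - start), abs(lead_pos - end)))


def assign_candidates(
    leads: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_CANDIDATE_WINDOW,
) -> pd.DataFrame:
    """Candidate genes per locus, with shared genes resolved by proximity.

    ``leads`` has columns LOCUS_ID, CHR, POS.  A gene falling in several
    loci's windows is assigned only to the locus with the nearer lead
    (distance to the nearest gene edge, 0 inside; ties go to the
    lower-position lead).  Returns LOCUS_ID, GENE_ID, DISTANCE.
    """
    rows = []
    for lead in leads.itertuples(index=False):
        for gid in select_candidates(lead.CHR, lead.POS, genes, window):
            g = genes.loc[genes["GENE_ID"] == gid].iloc[0]
            rows.append({
                "LOCUS_ID": lead.LOCUS_ID,
                "GENE_ID": gid,
                "DISTANCE": _gene_distance(int(lead.POS), int(g["START"]), int(g["END"])),
                "_LEAD_POS": int(lead.POS),
            })
    if not rows:
        return pd.DataFrame(columns=["LOCUS_ID", "GENE_ID", "DISTANCE"])
    df = pd.DataFrame(rows).sort_values(["GENE_ID", "DISTANCE", "_LEAD_POS"], kind="stable")
    df = df.drop_duplicates("GENE_ID", keep="first")
    return df.drop(columns="_LEAD_POS").sort_values(["LOCUS_ID", "GENE_ID"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# variant-annotation domain

def annotate_variant_domain(
    locus_id: str,
    lead_pos: int,
    lead_maf: float,
    candidates: pd.DataFrame,
    vep_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Variant-annotation evidence for one locus.

    Emits a nearest-gene item for exactly one candidate (nearest edge
    distance; ties broken by lower gene start), rare-variant items when the
    lead's MAF is below 1 % (attached to the genes the consequence table
    links to the lead, or to the nearest gene when no table is supplied) and
    protein-altering items per the consequence table.  ``vep_table`` columns:
    GENE_ID, PROTEIN_ALTERING.
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=EVIDENCE_COLUMNS)
    cand = candidates.copy()
    cand["_DIST"] = [
        _gene_distance(lead_pos, int(s), int(e)) for s, e in zip(cand["START"], cand["END"])
    ]
    cand = cand.sort_values(["_DIST", "START"], kind="stable")
    nearest = cand.iloc[0]["GENE_ID"]

    def item(gene, subcategory):
        return {
            "LOCUS_ID": locus_id, "GENE_ID": gene, "DOMAIN": "variant_annotation",
            "CATEGORY": "n/a", "SUBCATEGORY": subcategory,
            "UNIT_ID": "lead", "DATASET_ID": "annotation", "BLOOD_BRAIN_CORR": np.nan,
        }

    items = [item(nearest, "nearest_gene")]
    linked = (
        vep_table["GENE_ID"].tolist()
        if vep_table is not None and len(vep_table)
        else [nearest]
    )
    if lead_maf < RARE_MAF:
        for gene in linked:
            if gene in set(cand["GENE_ID"]):
                items.append(item(gene, "rare_variant"))
    if vep_table is not None and "PROTEIN_ALTERING" in vep_table.columns:
        for gene in vep_table.loc[vep_table["PROTEIN_ALTERING"].astype(bool), "GENE_ID"]:
            if gene in set(cand["GENE_ID"]):
                items.append(item(gene, "protein_altering"))
    return pd.DataFrame(items, columns=EVIDENCE_COLUMNS)


# ---------------------------------------------------------------------------
# aggregation (anti-inflation rules)

def aggregate_evidence(items: pd.DataFrame) -> pd.DataFrame:
    """Collapse correlated evidence before weighting.

    Three rules, applied in order: (3) for genes with MetaMeth CpGs on both
    sides of the 75th percentile of the blood–brain correlation distribution
    (computed over the catalog), the low-correlation CpGs are dropped;
    (2) when a gene has a fine-mapped TWAS association in a domain, its plain
    TWAS associations in that domain are dropped; (1) multiple measured units
    (splice junctions, CpGs, peaks) for the same gene, domain, category,
    subcategory and dataset collapse to one item.  The output carries one row
    per (locus, gene, domain, category, subcategory) with a REPLICATED flag:
    evidence observed in ≥2 distinct datasets of the same
    (gene, domain, subcategory).
    """
    if len(items) == 0:
        out = pd.DataFrame(columns=EVIDENCE_COLUMNS + ["REPLICATED"])
        return out
    df = items.copy()

    # rule 3: blood–brain correlation screen for MetaMeth CpGs
    mm = df["SUBCATEGORY"] == "metameth"
    if mm.any() and df.loc[mm, "BLOOD_BRAIN_CORR"].notna().any():
        p75 = float(np.nanpercentile(df.loc[mm, "BLOOD_BRAIN_CORR"].astype(float), 75))
        high = mm & (df["BLOOD_BRAIN_CORR"] >= p75)
        low = mm & (df["BLOOD_BRAIN_CORR"] < p75)
        genes_high = set(df.loc[high, "GENE_ID"])
        drop = low & df["GENE_ID"].isin(genes_high)
        df = df[~drop]

    # rule 2: fine-mapped TWAS supersedes plain TWAS per gene and domain
    fm = df[df["SUBCATEGORY"] == "fine_mapped_twas"][["GENE_ID", "DOMAIN"]].drop_duplicates()
    if len(fm):
        fm_keys = set(map(tuple, fm.to_numpy()))
        plain = df["SUBCATEGORY"] == "twas"
        drop = plain & np.array(
            [(g, d) in fm_keys for g, d in zip(df["GENE_ID"], df["DOMAIN"])]
        )
        df = df[~drop]

    # rule 1: collapse measured units within one dataset
    df = df.drop_duplicates(
        subset=["LOCUS_ID", "GENE_ID", "DOMAIN", "CATEGORY", "SUBCATEGORY", "DATASET_ID"]
    )

    # replication across datasets, assessed per (gene, domain, subcategory)
    n_datasets = df.groupby(["GENE_ID", "DOMAIN", "SUBCATEGORY"])["DATASET_ID"].transform(
        "nunique"
    )
    df = df.assign(REPLICATED=(n_datasets >= 2))
    df = df.drop_duplicates(subset=["LOCUS_ID", "GENE_ID", "DOMAIN", "CATEGORY", "SUBCATEGORY"])
    return df.sort_values(
        ["LOCUS_ID", "GENE_ID", "DOMAIN", "CATEGORY", "SUBCATEGORY"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# scoring and tiers

@dataclass
class GeneScore:
    """A gene's weighted prioritization score within one locus."""

    gene_id: str
    locus_id: str
    raw_score: float
    rescaled_score: float
    per_domain: dict[str, float] = field(default_factory=dict)
    tier: str = UNRANKED


def score_gene(
    gene_id: str,
    items: pd.DataFrame,
    cfg: WeightConfig,
    locus_id: str = "",
) -> GeneScore:
    """Weighted sum of a gene's aggregated evidence, rescaled to 0–100."""
    mine = items[items["GENE_ID"] == gene_id]
    per_domain: dict[str, float] = {}
    for row in mine.itertuples(index=False):
        w = cfg.weight(row.DOMAIN, row.CATEGORY, row.SUBCATEGORY, bool(row.REPLICATED))
        per_domain[row.DOMAIN] = per_domain.get(row.DOMAIN, 0.0) + w
    raw = float(sum(per_domain.values()))
    rescaled = float(np.clip(100.0 * raw / cfg.max_score, 0.0, 100.0))
    lid = locus_id or (str(mine["LOCUS_ID"].iloc[0]) if len(mine) else "")
    return GeneScore(gene_id, lid, raw, rescaled, per_domain)


def classify_tiers(
    scores: list[GeneScore],
    min_top_score: float = 4.0,
    rel_threshold: float = 0.20,
    tier2_band: float = 0.50,
) -> list[GeneScore]:
    """Tier classification of one locus's gene scores (in place; also returned).

    With S₁ the top raw score and rel(g) = (S₁ − S_g)/S₁: the top gene is
    tier 1 when S₁ ≥ ``min_top_score`` and every other gene has
    rel ≥ ``rel_threshold``; then genes with rel in
    [``rel_threshold``, ``tier2_band``] (both inclusive) are tier 2 and the
    rest unranked.  When another gene sits within the rel threshold, the top
    gene and all such close genes are tier 2.  When S₁ misses the absolute
    minimum, the top gene is tier 2 and the close band joins it.  Loci where
    every score is zero are left unranked.
    """
    if not scores:
        return scores
    for s in scores:
        s.tier = UNRANKED
    ranked = sorted(scores, key=lambda s: (-s.raw_score, s.gene_id))
    top = ranked[0]
    if top.raw_score <= 0:
        return scores
    # round to 12 decimals so boundary cases (rel exactly 0.20 or 0.50) are
    # classified by value, not by floating-point representation noise
    rel = {
        s.gene_id: round((top.raw_score - s.raw_score) / top.raw_score, 12)
        for s in ranked
    }
    close = [s for s in ranked[1:] if rel[s.gene_id] < rel_threshold]
    if top.raw_score >= min_top_score and not close:
        top.tier = TIER1
        for s in ranked[1:]:
            if rel_threshold <= rel[s.gene_id] <= tier2_band:
                s.tier = TIER2
    else:
        top.tier = TIER2
        for s in close:
            s.tier = TIER2
    return scores


def prioritize_locus(
    locus_id: str,
    candidates: list[str],
    items: pd.DataFrame,
    cfg: WeightConfig,
    **tier_kwargs,
) -> list[GeneScore]:
    """Aggregate, score and tier-classify one locus's candidate genes."""
    agg = aggregate_evidence(items[items["LOCUS_ID"] == locus_id])
    scores = [score_gene(g, agg, cfg, locus_id=locus_id) for g in candidates]
    return classify_tiers(scores, **tier_kwargs)


def prioritize_loci(
    candidates: pd.DataFrame,
    items: pd.DataFrame,
    cfg: WeightConfig | None = None,
    exclude_loci: set[str] | None = None,
    **tier_kwargs,
) -> pd.DataFrame:
    """Score every locus in a candidate table (LOCUS_ID, GENE_ID).

    ``exclude_loci`` skips loci where prioritization is not attempted (for
    example structurally complex gene clusters).  Returns a long table with
    per-domain contributions, raw and rescaled scores and tiers.
    """
    cfg = cfg or default_weights()
    exclude_loci = exclude_loci or set()
    rows = []
    for locus_id, group in candidates.groupby("LOCUS_ID", sort=True):
        if str(locus_id) in exclude_loci:
            continue
        scores = prioritize_locus(
            str(locus_id), group["GENE_ID"].tolist(), items, cfg, **tier_kwargs
        )
        for s in scores:
            row = {
                "LOCUS_ID": s.locus_id,
                "GENE_ID": s.gene_id,
                "RAW_SCORE": s.raw_score,
                "SCORE": s.rescaled_score,
                "TIER": s.tier,
            }
            for d in DOMAINS:
                row[f"W_{d.upper()}"] = s.per_domain.get(d, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"LOCUS_ID": str, "GENE_ID": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns and c != "BLOOD_BRAIN_CORR"]
    if missing:
        raise ValueError(f"evidence catalog missing column(s) {missing}")
    if "BLOOD_BRAIN_CORR" not in df.columns:
        df["BLOOD_BRAIN_CORR"] = np.nan
    return df


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"GENE_ID": str, "SYMBOL": str, "CHR": str})
    need = {"GENE_ID", "CHR", "START", "END", "PROTEIN_CODING"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise ValueError(f"gene table missing column(s) {missing}")
    return df
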