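"""Synthetic-data generators for every pipeline input.

All generators share a :class:`SimConfig` and a single global seed.  The seed
cascades to per-generator streams through ``numpy.random.SeedSequence`` with
fixed stream ids (0: summary statistics, 1: evidence catalogs, 2: cohorts,
3: auxiliary draws), so each stage is individually reproducible.

The generative model:

* **Summary statistics.**  Variants sit on a block-diagonal LD grid
  (consecutive variants on a chromosome form blocks of ``ld_block_size`` with
  a single within-block r²).  A handful of blocks are causal: one variant per
  causal block carries a true log-OR drawn from ``true_beta_range`` (random
  sign), and its block-mates carry the LD-attenuated marginal effect
  ``sqrt(r²)·β``.  Each study observes ``β̂ ~ N(β, se²)`` with the standard
  GWAS sampling approximation ``se = 1/sqrt(2·N_eff·f(1−f))``,
  ``N_eff = 4/(1/cases + 1/controls)``; sampling noise is correlated within
  LD blocks with correlation ``sqrt(r²)``.  Proxy studies observe effects on
  the halved scale, ``β̂ ~ N(β/2, se²)``, before any downstream correction.
* **Evidence catalogs.**  Each locus gets one designated causal gene that
  receives brain-weighted, replicated evidence across several domains, plus
  decoy genes with sparse peripheral evidence; the designated truth is
  recorded for recovery tests.
* **Cohorts.**  Event times are exponential under a proportional-hazards
  model with linear predictor
  ``per_allele_log_hr·(GRS − mean) + covariate effects``; non-AD dementia is
  a competing exponential event and censoring is an independent exponential
  dropout calibrated to ``censor_rate`` plus administrative end of follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grs import GRSModel, compute_grs_frame
from .loci import LDProvider, LocusCall
from .prioritization import EVIDENCE_COLUMNS
from .sumstats import StudySumstats, log10_pvalue_from_z

__all__ = [
    "SimConfig",
    "BlockLD",
    "EvidenceCatalog",
    "gen_sumstats",
    "gen_ld",
    "gen_evidence",
    "gen_cohort",
    "gen_grs_model",
    "simulate_fixture",
]

_STREAMS = {"sumstats": 0, "evidence": 1, "cohort": 2, "aux": 3}


class SimConfigError(ValueError):
    """A simulation parameter violates its domain."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic pipeline inputs.

    Defaults are desk-scale versions of a two-stage dementia GWAS design:
    several case-control discovery studies plus proxy (parental-history)
    studies on a halved effect scale, a follow-up stage, block LD, and
    longitudinal cohorts with a per-average-risk-allele hazard ratio of
    1.076.
    """

    n_studies: int = 8                      # stage I case-control studies
    n_proxy_studies: int = 2                # stage I proxy-design studies
    n_stage2_studies: int = 4               # stage II (follow-up) studies
    n_variants: int = 20_000
    n_causal_loci: int = 20
    chrom_lengths: dict = field(
        default_factory=lambda: {"1": 100_000_000, "2": 100_000_000,
                                 "3": 100_000_000, "4": 100_000_000}
    )
    true_beta_range: tuple = (0.04, 0.18)   # |log-OR| of causal variants
    per_study_n_cases: int = 5_000
    per_study_n_controls: int = 10_000
    ld_block_size: int = 10
    within_block_r2: float = 0.5
    # cohort model
    cohort_n: int = 2_000
    per_allele_log_hr: float = math.log(1.076)
    censor_rate: float = 0.3
    max_follow_years: float = 10.0
    base_ad_rate: float = 0.03              # events/year at the covariate mean
    other_dementia_rate: float = 0.005
    # fixed covariate effects (log-hazard scale)
    beta_age: float = 0.05                  # per year, centered at mean_age
    mean_age: float = 70.0
    beta_sex: float = 0.2
    beta_pc: float = 0.02                   # per PC, all four
    beta_apoe4: float = math.log(2.0)
    beta_apoe2: float = -0.35
    apoe4_freq: float = 0.15
    apoe2_freq: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_studies, self.n_variants, self.n_causal_loci,
                  self.per_study_n_cases, self.per_study_n_controls,
                  self.ld_block_size, self.cohort_n)
        if any(c <= 0 for c in counts):
            raise SimConfigError("all counts must be positive")
        if self.n_proxy_studies < 0 or self.n_stage2_studies < 0:
            raise SimConfigError("study counts must be non-negative")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise SimConfigError("within_block_r2 must lie in [0, 1]")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise SimConfigError("censor_rate must lie in [0, 1]")
        if not all(v > 0 for v in self.chrom_lengths.values()):
            raise SimConfigError("chromosome lengths must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Per-generator random stream: SeedSequence([seed, stream_id])."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, _STREAMS[stream]]))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["true_beta_range"] = list(d["true_beta_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "true_beta_range" in d:
            d["true_beta_range"] = tuple(d["true_beta_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# variant grid and truth

def _variant_grid(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant positions, alleles, base frequencies, LD blocks and true effects."""
    chroms = list(config.chrom_lengths)
    per_chrom = np.full(len(chroms), config.n_variants // len(chroms))
    per_chrom[: config.n_variants % len(chroms)] += 1
    frames = []
    block_offset = 0
    alleles = np.array(list("ACGT"))
    for chrom, n in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(config.chrom_lengths[chrom] - 1, size=n, replace=False)) + 1
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        block = block_offset + np.arange(n) // config.ld_block_size
        block_offset = int(block[-1]) + 1 if n else block_offset
        frames.append(pd.DataFrame({
            "CHR": chrom,
            "POS": pos,
            "REF": alleles[ref_idx],
            "ALT": alleles[alt_idx],
            "FREQ": rng.uniform(0.05, 0.95, size=n),
            "BLOCK": block,
        }))
    truth = pd.concat(frames, ignore_index=True)
    truth["ID"] = (truth["CHR"] + ":" + truth["POS"].astype(str)
                   + ":" + truth["REF"] + ":" + truth["ALT"])
    truth["BETA_TRUE"] = 0.0
    truth["CAUSAL"] = False

    lo, hi = config.true_beta_range
    if hi > 0 and config.n_causal_loci > 0:
        blocks = truth["BLOCK"].unique()
        causal_blocks = rng.choice(blocks, size=min(config.n_causal_loci, len(blocks)),
                                   replace=False)
        r = math.sqrt(config.within_block_r2)
        for b in causal_blocks:
            members = truth.index[truth["BLOCK"] == b]
            causal = rng.choice(members)
            beta = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            truth.loc[members, "BETA_TRUE"] = r * beta  # LD-attenuated marginal effect
            truth.loc[causal, "BETA_TRUE"] = beta
            truth.loc[causal, "CAUSAL"] = True
    return truth


def _draw_study(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    study_id: str,
    design: str,
) -> StudySumstats:
    n = len(truth)
    n_cases, n_controls = config.per_study_n_cases, config.per_study_n_controls
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    eaf = np.clip(truth["FREQ"].to_numpy() + rng.normal(0.0, 0.01, size=n), 0.01, 0.99)
    se = 1.0 / np.sqrt(2.0 * n_eff * eaf * (1.0 - eaf))
    scale = 0.5 if design == "proxy" else 1.0
    # sampling noise correlated within LD blocks (correlation sqrt(r2))
    r = math.sqrt(config.within_block_r2)
    blocks = truth["BLOCK"].to_numpy()
    shared = rng.standard_normal(blocks.max() + 1)[blocks]
    indep = rng.standard_normal(n)
    z_noise = r * shared + math.sqrt(1.0 - r**2) * indep
    beta_hat = scale * truth["BETA_TRUE"].to_numpy() + se * z_noise
    z = beta_hat / se
    p = np.power(10.0, np.maximum(log10_pvalue_from_z(z), -323.0))
    records = pd.DataFrame({
        "CHR": truth["CHR"], "POS": truth["POS"],
        "REF": truth["REF"], "ALT": truth["ALT"], "EA": truth["ALT"],
        "BETA": beta_hat, "SE": se, "P": p, "EAF": eaf,
        "INFO": rng.uniform(0.7, 1.0, size=n),
        "N_CASES": n_cases, "N_CONTROLS": n_controls,
    })
    return StudySumstats(study_id=study_id, design=design, records=records,
                         total_cases=n_cases)


def gen_sumstats(
    config: SimConfig,
) -> tuple[list[StudySumstats], list[StudySumstats], pd.DataFrame]:
    """Generate stage I and stage II per-study summary statistics plus the truth table.

    Stage I comprises ``n_studies`` case-control and ``n_proxy_studies``
    proxy-design studies (the latter drawn around β/2 on the pre-correction
    scale); stage II comprises ``n_stage2_studies`` case-control studies.
    Deterministic under a fixed (config, seed).
    """
    rng = config.rng("sumstats")
    truth = _variant_grid(config, rng)
    stage1 = [
        _draw_study(truth, config, rng, f"S1_CC{i+1}", "case_control")
        for i in range(config.n_studies)
    ]
    stage1 += [
        _draw_study(truth, config, rng, f"S1_PROXY{i+1}", "proxy")
        for i in range(config.n_proxy_studies)
    ]
    stage2 = [
        _draw_study(truth, config, rng, f"S2_CC{i+1}", "case_control")
        for i in range(config.n_stage2_studies)
    ]
    return stage1, stage2, truth


# ---------------------------------------------------------------------------
# LD

class BlockLD(LDProvider):
    """Block-diagonal LD: r²=1 on the diagonal, a single within-block r², else 0."""

    def __init__(self, block_of: dict[str, int], within_block_r2: float):
        self.block_of = block_of
        self.within_block_r2 = float(within_block_r2)

    def r2(self, a: str, b: str) -> float:
        try:
            ba, bb = self.block_of[a], self.block_of[b]
        except KeyError as exc:
            raise KeyError(f"unknown variant {exc.args[0]!r}") from None
        if a == b:
            return 1.0
        return self.within_block_r2 if ba == bb else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ID": list(self.block_of), "BLOCK": list(self.block_of.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, within_block_r2: float) -> "BlockLD":
        return cls(dict(zip(df["ID"], df["BLOCK"].astype(int))), within_block_r2)


def gen_ld(config: SimConfig, truth: pd.DataFrame) -> BlockLD:
    """LD lookup for the simulated variant grid (block assignment from the truth table)."""
    return BlockLD(dict(zip(truth["ID"], truth["BLOCK"].astype(int))),
                   config.within_block_r2)


# ---------------------------------------------------------------------------
# evidence catalogs

@dataclass
class EvidenceCatalog:
    """Synthetic prioritization inputs with the designated causal genes recorded."""

    genes: pd.DataFrame
    items: pd.DataFrame
    leads: pd.DataFrame           # LOCUS_ID, CHR, POS, MAF
    truth: dict[str, str]         # locus id -> designated causal gene


def _leads_frame(loci) -> pd.DataFrame:
    """Accept LocusCall lists or ready-made lead tables."""
    if isinstance(loci, pd.DataFrame):
        df = loci.copy()
        if "MAF" not in df.columns:
            df["MAF"] = 0.2
        return df[["LOCUS_ID", "CHR", "POS", "MAF"]]
    rows = []
    for i, call in enumerate(loci):
        chrom, pos, _, _ = call.lead.split(":")
        rows.append({"LOCUS_ID": f"L{i+1}", "CHR": chrom, "POS": int(pos), "MAF": 0.2})
    return pd.DataFrame(rows)


def gen_evidence(
    config: SimConfig,
    loci: "pd.DataFrame | list[LocusCall]",
    n_decoys: int = 4,
) -> EvidenceCatalog:
    """Generate gene annotations and an evidence catalog for a set of loci.

    Each locus gets ``n_decoys``+1 protein-coding candidate genes within the
    prioritization window; the designated causal gene spans the lead variant
    (so it is also the nearest gene) and receives replicated brain evidence
    in the eQTL domain, a brain sQTL TWAS hit and an APP-metabolism screen
    hit — at least three domains.  Decoy genes receive at most one weak
    peripheral hit.  Deterministic under a fixed (config, seed).
    """
    rng = config.rng("evidence")
    leads = _leads_frame(loci)
    gene_rows, item_rows, truth = [], [], {}
    for lead in leads.itertuples(index=False):
        lid = str(lead.LOCUS_ID)
        causal = f"{lid}_G1"
        truth[lid] = causal
        pos = int(lead.POS)
        gene_rows.append({
            "GENE_ID": causal, "SYMBOL": causal, "CHR": str(lead.CHR),
            "START": max(1, pos - 10_000), "END": pos + 10_000, "PROTEIN_CODING": True,
        })
        for j in range(n_decoys):
            offset = int(rng.integers(50_000, 450_000)) * (1 if j % 2 == 0 else -1)
            start = max(1, pos + offset)
            gene_rows.append({
                "GENE_ID": f"{lid}_G{j+2}", "SYMBOL": f"{lid}_G{j+2}",
                "CHR": str(lead.CHR), "START": start, "END": start + 20_000,
                "PROTEIN_CODING": True,
            })
        base = {"LOCUS_ID": lid, "GENE_ID": causal, "BLOOD_BRAIN_CORR": np.nan}
        item_rows += [
            {**base, "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
             "SUBCATEGORY": "colocalization", "UNIT_ID": causal, "DATASET_ID": "brain_ds1"},
            {**base, "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
             "SUBCATEGORY": "colocalization", "UNIT_ID": causal, "DATASET_ID": "brain_ds2"},
            {**base, "DOMAIN": "sqtl", "CATEGORY": "brain_bulk",
             "SUBCATEGORY": "twas", "UNIT_ID": f"{causal}_j1", "DATASET_ID": "brain_ds1"},
            {**base, "DOMAIN": "app_metabolism", "CATEGORY": "n/a",
             "SUBCATEGORY": "sirna_hit", "UNIT_ID": causal, "DATASET_ID": "sirna_screen"},
        ]
        for j in range(n_decoys):
            if rng.random() < 0.5:
                decoy = f"{lid}_G{j+2}"
                item_rows.append({
                    "LOCUS_ID": lid, "GENE_ID": decoy, "DOMAIN": "eqtl",
                    "CATEGORY": "lcl", "SUBCATEGORY": "lead_qtl_hit",
                    "UNIT_ID": decoy, "DATASET_ID": "lcl_ds1", "BLOOD_BRAIN_CORR": np.nan,
                })
    genes = pd.DataFrame(gene_rows)
    items = pd.DataFrame(item_rows, columns=EVIDENCE_COLUMNS)
    return EvidenceCatalog(genes=genes, items=items, leads=leads, truth=truth)


# ---------------------------------------------------------------------------
# GRS models and cohorts

def gen_grs_model(config: SimConfig, n_variants: int = 20) -> GRSModel:
    """A synthetic risk-score model with positive log-OR weights and RAFs."""
    rng = config.rng("aux")
    alleles = np.array(list("ACGT"))
    chroms = list(config.chrom_lengths)
    rows = []
    for i in range(n_variants):
        chrom = chroms[i % len(chroms)]
        pos = int(rng.integers(1, config.chrom_lengths[chrom]))
        ref, alt = rng.choice(alleles, size=2, replace=False)
        weight = float(rng.uniform(0.03, 0.3))
        risk_is_alt = bool(rng.random() < 0.5)
        rows.append({
            "ID": f"{chrom}:{pos}:{ref}:{alt}", "CHR": chrom, "POS": pos,
            "REF": ref, "ALT": alt,
            "RISK_ALLELE": alt if risk_is_alt else ref,
            "WEIGHT": weight,
            "RAF": float(rng.uniform(0.1, 0.9)),
        })
    return GRSModel(pd.DataFrame(rows), name="GRS_synthetic")


def gen_cohort(
    config: SimConfig,
    model: GRSModel,
    cohort_id: str = "COHORT1",
    stream_offset: int = 0,
) -> pd.DataFrame:
    """Simulate one longitudinal cohort under a proportional-hazards model.

    Dosages are Binomial(2, RAF) per model variant; the AD hazard is
    ``base_ad_rate·exp(lp)`` with
    ``lp = per_allele_log_hr·(GRS − mean GRS) + covariate effects``.
    Non-AD dementia is an independent competing exponential event and
    censoring combines an exponential dropout calibrated so that roughly
    ``censor_rate`` of subjects are censored before any event, with
    administrative end of follow-up at ``max_follow_years``.
    ``stream_offset`` separates the random streams of multiple cohorts.
    """
    if model.n_variants == 0:
        raise ValueError("empty GRS model")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAMS["cohort"], stream_offset])
    )
    n = config.cohort_n
    entries = model.entries
    raf = (entries["RAF"].to_numpy(dtype=float)
           if "RAF" in entries.columns and entries["RAF"].notna().all()
           else np.full(model.n_variants, 0.3))
    risk_dosage = rng.binomial(2, raf, size=(n, model.n_variants)).astype(float)
    # stored dosages count ALT copies; flip back where the risk allele is REF
    flip = (entries["RISK_ALLELE"] != entries["ALT"]).to_numpy()
    alt_dosage = np.where(flip, 2.0 - risk_dosage, risk_dosage)

    cohort = pd.DataFrame({
        "SUBJECT_ID": [f"{cohort_id}_{i+1}" for i in range(n)],
        "COHORT_ID": cohort_id,
        "AGE": rng.normal(config.mean_age, 5.0, size=n),
        "SEX": rng.integers(0, 2, size=n).astype(float),
        "PC1": rng.standard_normal(n), "PC2": rng.standard_normal(n),
        "PC3": rng.standard_normal(n), "PC4": rng.standard_normal(n),
    })
    # APOE genotype: two alleles, each e4/e2/e3
    allele_p = [config.apoe4_freq, config.apoe2_freq,
                1.0 - config.apoe4_freq - config.apoe2_freq]
    draws = rng.choice(3, size=(n, 2), p=allele_p)
    cohort["APOE4"] = (draws == 0).sum(axis=1).astype(float)
    cohort["APOE2"] = (draws == 1).sum(axis=1).astype(float)
    for j, vid in enumerate(entries["ID"]):
        cohort[vid] = alt_dosage[:, j]

    grs = compute_grs_frame(cohort, model).to_numpy()
    lp = (
        config.per_allele_log_hr * (grs - grs.mean())
        + config.beta_age * (cohort["AGE"].to_numpy() - config.mean_age)
        + config.beta_sex * cohort["SEX"].to_numpy()
        + config.beta_pc * (cohort[["PC1", "PC2", "PC3", "PC4"]].sum(axis=1).to_numpy())
        + config.beta_apoe4 * cohort["APOE4"].to_numpy()
        + config.beta_apoe2 * cohort["APOE2"].to_numpy()
    )
    t_ad = rng.exponential(1.0 / (config.base_ad_rate * np.exp(lp)))
    t_other = rng.exponential(1.0 / config.other_dementia_rate, size=n)

    if config.censor_rate >= 1.0:
        time = rng.uniform(0.01, config.max_follow_years, size=n)
        event = np.full(n, "CENSORED")
    else:
        total_rate = config.base_ad_rate + config.other_dementia_rate
        if config.censor_rate > 0:
            cens_rate = total_rate * config.censor_rate / (1.0 - config.censor_rate)
            t_cens = rng.exponential(1.0 / cens_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        t_admin = np.full(n, config.max_follow_years)
        stacked = np.column_stack([t_ad, t_other, t_cens, t_admin])
        which = stacked.argmin(axis=1)
        time = stacked.min(axis=1)
        event = np.array(["AD", "OTHER_DEM", "CENSORED", "CENSORED"])[which]
    cohort["TIME"] = np.maximum(time, 1e-6)
    cohort["EVENT"] = event
    return cohort


# ---------------------------------------------------------------------------
# fixture directories

def simulate_fixture(config: SimConfig, outdir: str | Path, n_cohorts: int = 2) -> dict:
    """Write a complete fixture directory with every pipeline input.

    Emits per-study summary-statistics TSVs (stage1/, stage2/), the LD block
    table, gene annotations, the GRS model, per-cohort CSVs and the config
    itself; returns a manifest of the written paths.
    """
    outdir = Path(outdir)
    (outdir / "stage1").mkdir(parents=True, exist_ok=True)
    (outdir / "stage2").mkdir(exist_ok=True)
    (outdir / "cohorts").mkdir(exist_ok=True)

    stage1, stage2, truth = gen_sumstats(config)
    paths: dict[str, object] = {"stage1": [], "stage2": [], "cohorts": []}
    for s in stage1:
        p = outdir / "stage1" / f"{s.study_id}.tsv"
        s.records.to_csv(p, sep="\t", index=False)
        paths["stage1"].append({"path": str(p), "study_id": s.study_id,
                                "design": s.design, "total_cases": s.total_cases})
    for s in stage2:
        p = outdir / "stage2" / f"{s.study_id}.tsv"
        s.records.to_csv(p, sep="\t", index=False)
        paths["stage2"].append({"path": str(p), "study_id": s.study_id,
                                "design": s.design, "total_cases": s.total_cases})
    ld = gen_ld(config, truth)
    ld.to_frame().to_csv(outdir / "ld_blocks.tsv", sep="\t", index=False)
    paths["ld"] = str(outdir / "ld_blocks.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")

    # prioritization inputs, keyed to the true causal loci
    causal = truth[truth["CAUSAL"]].reset_index(drop=True)
    leads = pd.DataFrame({
        "LOCUS_ID": [f"L{i+1}" for i in range(len(causal))],
        "CHR": causal["CHR"].astype(str),
        "POS": causal["POS"].astype(int),
        "MAF": np.minimum(causal["FREQ"], 1.0 - causal["FREQ"]),
    })
    catalog = gen_evidence(config, leads)
    leads.to_csv(outdir / "locus_leads.tsv", sep="\t", index=False)
    catalog.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    catalog.items.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    pd.Series(catalog.truth, name="GENE_ID").rename_axis("LOCUS_ID").reset_index().to_csv(
        outdir / "causal_genes.tsv", sep="\t", index=False
    )
    paths["locus_leads"] = str(outdir / "locus_leads.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    paths["evidence"] = str(outdir / "evidence.tsv")
    paths["causal_genes"] = str(outdir / "causal_genes.tsv")

    model = gen_grs_model(config)
    model.write(outdir / "grs_model.tsv")
    paths["grs_model"] = str(outdir / "grs_model.tsv")
    for i in range(n_cohorts):
        cohort = gen_cohort(config, model, cohort_id=f"COHORT{i+1}", stream_offset=i)
        p = outdir / "cohorts" / f"COHORT{i+1}.csv"
        cohort.to_csv(p, index=False)
        paths["cohorts"].append(str(p))

    config.to_yaml(outdir / "sim_config.yaml")
    paths["config"] = str(outdir / "sim_config.yaml")

    # a ready-to-run pipeline config pointing at everything above
    rel = lambda p: str(Path(p).relative_to(outdir))
    pipeline_cfg = {
        "seed": config.seed,
        "outdir": "out",
        "stage1": [{**{k: v for k, v in e.items() if k != "path"},
                    "path": rel(e["path"])} for e in paths["stage1"]],
        "stage2": [{**{k: v for k, v in e.items() if k != "path"},
                    "path": rel(e["path"])} for e in paths["stage2"]],
        "ld": {"path": rel(paths["ld"]),
               "within_block_r2": config.within_block_r2},
        "genes": rel(paths["genes"]),
        "evidence": rel(paths["evidence"]),
        "grs_model": rel(paths["grs_model"]),
        "cohorts": [rel(c) for c in paths["cohorts"]],
    }
    with open(outdir / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)
    paths["pipeline_config"] = str(outdir / "pipeline_config.yaml")
    return paths
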