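"""End-to-end orchestration: QC → meta-analysis → loci → prioritization → GRS.

A single structured config drives the run; every stage threshold is echoed
into the run manifest together with input checksums and per-stage record
counts, so a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grs import GRSModel, fit_progression, meta_hr
from .loci import call_loci, locus_table
from .meta import MetaFilterThresholds, apply_meta_filters, meta_analyze
from .prioritization import (
    DOMAINS,
    assign_candidates,
    default_weights,
    load_weights,
    prioritize_loci,
    read_evidence,
    read_genes,
)
from .sumstats import (
    APOE_REGION,
    QCThresholds,
    apply_variant_qc,
    correct_proxy,
    genomic_lambda,
    harmonize_to_alt,
    read_sumstats,
)
from .synthetic import BlockLD

__all__ = ["PipelineConfig", "PipelineError", "ValidationFailure",
           "validate_inputs", "run_pipeline"]

log = logging.getLogger("addgwas")

_ALLOWED_KEYS = {
    "seed", "outdir", "stage1", "stage2", "ld", "genes", "evidence",
    "grs_model", "cohorts", "reference_study", "thresholds", "weights",
}
_ALLOWED_THRESHOLDS = {"qc", "meta", "loci", "tiers"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class ValidationFailure:
    source: str
    check: str
    detail: str


@dataclass
class PipelineConfig:
    """Paths to inputs plus every stage threshold (defaults: the standard values)."""

    outdir: Path
    stage1: list[dict]
    stage2: list[dict] = field(default_factory=list)
    ld: dict | None = None
    genes: str | None = None
    evidence: str | None = None
    grs_model: str | None = None
    cohorts: list[str] = field(default_factory=list)
    reference_study: str | None = None
    seed: int = 0
    weights: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    meta: MetaFilterThresholds = field(default_factory=MetaFilterThresholds)
    loci: dict = field(default_factory=lambda: {
        "p1": 1e-5, "window": 500_000, "r2": 0.001,
        "gws_p": 5e-8, "stage2_p": 0.05,
    })
    tiers: dict = field(default_factory=lambda: {
        "min_top_score": 4.0, "rel_threshold": 0.20, "tier2_band": 0.50,
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        thresholds = raw.get("thresholds", {}) or {}
        bad = set(thresholds) - _ALLOWED_THRESHOLDS
        if bad:
            raise PipelineError(f"unknown threshold group(s): {sorted(bad)}")
        base = path.parent

        def resolve(p):
            return str((base / p) if not Path(p).is_absolute() else Path(p))

        def resolve_entries(entries):
            out = []
            for e in entries or []:
                e = dict(e)
                e["path"] = resolve(e["path"])
                out.append(e)
            return out

        cfg = cls(
            outdir=Path(resolve(raw.get("outdir", "out"))),
            stage1=resolve_entries(raw.get("stage1")),
            stage2=resolve_entries(raw.get("stage2")),
            ld=(
                {**raw["ld"], "path": resolve(raw["ld"]["path"])}
                if raw.get("ld") else None
            ),
            genes=resolve(raw["genes"]) if raw.get("genes") else None,
            evidence=resolve(raw["evidence"]) if raw.get("evidence") else None,
            grs_model=resolve(raw["grs_model"]) if raw.get("grs_model") else None,
            cohorts=[resolve(c) for c in raw.get("cohorts", [])],
            reference_study=raw.get("reference_study"),
            seed=int(raw.get("seed", 0)),
            weights=resolve(raw["weights"]) if raw.get("weights") else None,
        )
        if "qc" in thresholds:
            cfg.qc = QCThresholds(**thresholds["qc"])
        if "meta" in thresholds:
            cfg.meta = MetaFilterThresholds(**thresholds["meta"])
        if "loci" in thresholds:
            cfg.loci.update(thresholds["loci"])
        if "tiers" in thresholds:
            cfg.tiers.update(thresholds["tiers"])
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[ValidationFailure]:
    """Schema, allele and coordinate checks across every input, pre-computation."""
    failures: list[ValidationFailure] = []

    def check_study(entry):
        p = Path(entry["path"])
        if not p.exists():
            failures.append(ValidationFailure(str(p), "exists", "file not found"))
            return
        df = pd.read_csv(p, sep="\t", nrows=1000)
        for col in ("CHR", "POS", "REF", "ALT", "EA", "BETA", "SE"):
            if col not in df.columns:
                failures.append(ValidationFailure(str(p), "schema", f"missing column {col}"))
        if "POS" in df.columns:
            pos = pd.to_numeric(df["POS"], errors="coerce")
            if (pos < 1).any() or pos.isna().any():
                failures.append(ValidationFailure(str(p), "coordinates",
                                                  "positions must be >= 1"))
        for col in ("REF", "ALT"):
            if col in df.columns:
                ok = df[col].astype(str).str.fullmatch(r"[ACGT]+")
                if not ok.all():
                    failures.append(ValidationFailure(str(p), "alleles",
                                                      f"non-ACGT {col} allele"))
        if entry.get("design", "case_control") not in ("case_control", "proxy"):
            failures.append(ValidationFailure(str(p), "design",
                                              f"unknown design {entry.get('design')!r}"))

    for entry in config.stage1 + config.stage2:
        check_study(entry)
    if config.evidence:
        try:
            ev = read_evidence(config.evidence)
            bad = set(ev["DOMAIN"]) - set(DOMAINS)
            if bad:
                failures.append(ValidationFailure(config.evidence, "schema",
                                                  f"unknown domain(s) {sorted(bad)}"))
        except ValueError as exc:
            failures.append(ValidationFailure(config.evidence, "schema", str(exc)))
    if config.genes:
        try:
            g = read_genes(config.genes)
            if (g["START"] > g["END"]).any():
                failures.append(ValidationFailure(config.genes, "coordinates",
                                                  "gene START > END"))
        except ValueError as exc:
            failures.append(ValidationFailure(config.genes, "schema", str(exc)))
    return failures


def _load_stage(entries: list[dict], qc: QCThresholds, counts: dict) -> list:
    studies = []
    for entry in entries:
        study = read_sumstats(
            entry["path"],
            study_id=entry.get("study_id"),
            design=entry.get("design", "case_control"),
            total_cases=entry.get("total_cases"),
        )
        study = harmonize_to_alt(study)
        n_in = study.n_variants
        study, report = apply_variant_qc(study, qc)
        if study.design == "proxy":
            study = correct_proxy(study)
        counts[study.study_id] = {
            "input": n_in, "after_qc": study.n_variants, "removed": report.removed,
        }
        studies.append(study)
    return studies


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order and write outputs plus a run manifest.

    Stages: per-study QC and proxy correction → stage I and II IVW
    meta-analysis with post-meta filters and genomic-control λ → region
    building, clumping and two-stage locus calls → gene prioritization (when
    gene/evidence inputs are configured) → per-cohort GRS Cox fits and HR
    meta-analysis (when a GRS model and cohorts are configured).  Any stage
    error aborts with the stage name in the exception.
    """
    t0 = time.time()
    failures = validate_inputs(config)
    if failures:
        raise PipelineError(
            "validation failed: "
            + "; ".join(f"{f.source}: {f.check}: {f.detail}" for f in failures)
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "qc": vars(config.qc).copy(),
            "meta": vars(config.meta).copy(),
            "loci": dict(config.loci),
            "tiers": dict(config.tiers),
        },
        "inputs": {},
        "counts": {},
        "timings": {},
    }
    for entry in config.stage1 + config.stage2:
        manifest["inputs"][entry["path"]] = _sha256(entry["path"])
    for extra in (config.genes, config.evidence, config.grs_model, *config.cohorts):
        if extra:
            manifest["inputs"][str(extra)] = _sha256(extra)

    # --- stage I: QC + meta ---
    stage = "sumstats"
    try:
        qc_counts: dict = {}
        stage1_studies = _load_stage(config.stage1, config.qc, qc_counts)
        stage2_studies = _load_stage(config.stage2, config.qc, qc_counts)
        manifest["counts"]["qc"] = qc_counts
        manifest["timings"][stage] = round(time.time() - t0, 3)

        stage = "meta"
        t1 = time.time()
        s1 = meta_analyze(stage1_studies, reference_study=config.reference_study)
        s1 = apply_meta_filters(s1, config.meta)
        lam = genomic_lambda(
            s1.loc[s1["KEPT"], "P"],
            s1.loc[s1["KEPT"], "CHR"],
            s1.loc[s1["KEPT"], "POS"],
        )
        manifest["lambda_gc"] = lam
        s1_kept = s1[s1["KEPT"]].reset_index(drop=True)
        manifest["counts"]["meta_stage1"] = {
            "input": len(s1), "kept": len(s1_kept),
            "removed_by_rule": {
                rule: int((s1["REASONS"].str.contains(rule, regex=False)).sum())
                for rule in ("heterogeneity", "case-fraction",
                             "frequency-amplitude", "not-in-reference")
            },
        }
        s1.to_csv(outdir / "stage1_meta.tsv", sep="\t", index=False)
        s2 = None
        if stage2_studies:
            s2 = meta_analyze(stage2_studies)
            s2.to_csv(outdir / "stage2_meta.tsv", sep="\t", index=False)
            manifest["counts"]["meta_stage2"] = {"input": len(s2)}
        manifest["timings"][stage] = round(time.time() - t1, 3)

        # --- loci ---
        stage = "loci"
        t1 = time.time()
        calls = []
        if s2 is not None and config.ld:
            ld_df = pd.read_csv(config.ld["path"], sep="\t")
            ld = BlockLD.from_frame(ld_df, float(config.ld.get("within_block_r2", 0.0)))
            calls = call_loci(
                s1_kept, s2, ld,
                p_threshold=float(config.loci["p1"]),
                window=int(config.loci["window"]),
                r2_threshold=float(config.loci["r2"]),
                gws_p=float(config.loci["gws_p"]),
                stage2_p=float(config.loci["stage2_p"]),
            )
            table = locus_table(calls)
            table.to_csv(outdir / "locus_calls.tsv", sep="\t", index=False)
            manifest["counts"]["loci"] = {
                "clumps": len(calls),
                "genome_wide_significant": int(
                    (table["CLASSIFICATION"] == "genome_wide_significant").sum()
                ),
                "stage2_unsupported": int(
                    (table["CLASSIFICATION"] == "stage2_unsupported").sum()
                ),
            }
        manifest["timings"][stage] = round(time.time() - t1, 3)

        # --- prioritization ---
        stage = "prioritization"
        t1 = time.time()
        if calls and config.genes and config.evidence:
            genes = read_genes(config.genes)
            evidence = read_evidence(config.evidence)
            cfg_w = load_weights(config.weights) if config.weights else default_weights()
            gws = [c for c in calls if c.classification == "genome_wide_significant"]
            lead_rows = []
            ev_leads = evidence.groupby("LOCUS_ID").first().reset_index()
            for c in gws:
                chrom, pos = c.lead.split(":")[0], int(c.lead.split(":")[1])
                lead_rows.append({"LOCUS_ID": "", "CHR": chrom, "POS": pos})
            leads = pd.DataFrame(lead_rows)
            # map detected leads onto the evidence catalog's locus ids by proximity
            if len(leads):
                cat_leads = _catalog_leads(evidence, genes)
                leads["LOCUS_ID"] = [
                    _nearest_locus(cat_leads, r.CHR, r.POS)
                    for r in leads.itertuples(index=False)
                ]
                leads = leads[leads["LOCUS_ID"] != ""].drop_duplicates("LOCUS_ID")
            if len(leads):
                candidates = assign_candidates(leads, genes)
                scores = prioritize_loci(candidates, evidence, cfg_w, **config.tiers)
                scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
                manifest["counts"]["prioritization"] = {
                    "loci": int(scores["LOCUS_ID"].nunique()),
                    "tier1": int((scores["TIER"] == "tier1").sum()),
                    "tier2": int((scores["TIER"] == "tier2").sum()),
                }
            del ev_leads
        manifest["timings"][stage] = round(time.time() - t1, 3)

        # --- GRS ---
        stage = "grs"
        t1 = time.time()
        if config.grs_model and config.cohorts:
            model = GRSModel.read(config.grs_model)
            results = []
            for cpath in config.cohorts:
                cohort = pd.read_csv(cpath)
                results.append(fit_progression(cohort, model))
            if len(results) >= 2:
                mh = meta_hr(results)
                manifest["grs"] = {
                    "n_variants": model.n_variants,
                    "fixed_hr": mh.fixed_hr,
                    "fixed_ci95": list(mh.fixed_ci95),
                    "i2": mh.i2,
                }
            else:
                manifest["grs"] = {
                    "n_variants": model.n_variants,
                    "fixed_hr": results[0].hr,
                    "fixed_ci95": list(results[0].ci95),
                }
        manifest["timings"][stage] = round(time.time() - t1, 3)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["elapsed"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    log.info("pipeline complete in %.1fs; manifest at %s", manifest["elapsed"],
             outdir / "manifest.json")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _catalog_leads(evidence: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Approximate each catalog locus's position by its genes' midpoint span."""
    locus_genes = evidence[["LOCUS_ID", "GENE_ID"]].drop_duplicates().merge(
        genes, on="GENE_ID", how="inner"
    )
    agg = locus_genes.groupby("LOCUS_ID").agg(
        CHR=("CHR", "first"), START=("START", "min"), END=("END", "max")
    )
    agg["POS"] = ((agg["START"] + agg["END"]) // 2).astype(int)
    return agg.reset_index()[["LOCUS_ID", "CHR", "POS"]]


def _nearest_locus(cat_leads: pd.DataFrame, chrom: str, pos: int,
                   max_dist: int = 2_000_000) -> str:
    same = cat_leads[cat_leads["CHR"].astype(str) == str(chrom)]
    if len(same) == 0:
        return ""
    dist = (same["POS"] - pos).abs()
    if dist.min() > max_dist:
        return ""
    return str(same.loc[dist.idxmin(), "LOCUS_ID"])
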