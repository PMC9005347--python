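"""Candidate selection, evidence aggregation, weighted scoring and tier rules."""

import numpy as np
import pandas as pd
import pytest

from addgwas.prioritization import (
    TIER1,
    TIER2,
    UNRANKED,
    GeneScore,
    WeightConfig,
    WeightConfigError,
    aggregate_evidence,
    annotate_variant_domain,
    assign_candidates,
    classify_tiers,
    default_weights,
    score_gene,
    select_candidates,
)


def genes_frame(rows):
    """rows: (gene_id, chrom, start, end, protein_coding)."""
    return pd.DataFrame(
        [{"GENE_ID": g, "SYMBOL": g, "CHR": str(c), "START": s, "END": e,
          "PROTEIN_CODING": pc} for g, c, s, e, pc in rows]
    )


def items_frame(rows):
    """rows: dicts with at least GENE_ID, DOMAIN, CATEGORY, SUBCATEGORY."""
    defaults = {"LOCUS_ID": "L1", "UNIT_ID": "u1", "DATASET_ID": "ds1",
                "BLOOD_BRAIN_CORR": np.nan}
    return pd.DataFrame([{**defaults, **r} for r in rows])


# ---------------------------------------------------------------------------
# candidate selection

def test_candidate_window_and_coding_filter():
    genes = genes_frame([
        ("COD_IN", "1", 2_500_000, 2_600_000, True),
        ("NONCOD", "1", 2_500_000, 2_600_000, False),
        ("COD_EDGE", "1", 900_000, 1_000_000, True),        # ends exactly at window edge
        ("COD_OUT", "1", 3_000_001, 3_100_000, True),       # 1,000,001 bp away
        ("OTHER_CHR", "2", 2_500_000, 2_600_000, True),
    ])
    got = select_candidates("1", 2_000_000, genes)
    assert got == ["COD_IN", "COD_EDGE"]


def test_shared_gene_assigned_to_nearer_lead():
    genes = genes_frame([("SHARED", "1", 1_450_000, 1_500_000, True)])
    leads = pd.DataFrame([
        {"LOCUS_ID": "L1", "CHR": "1", "POS": 1_000_000},
        {"LOCUS_ID": "L2", "CHR": "1", "POS": 1_600_000},   # 100 kb vs 450 kb
    ])
    out = assign_candidates(leads, genes)
    assert out["LOCUS_ID"].tolist() == ["L2"]


def test_equidistant_gene_goes_to_lower_position_lead():
    genes = genes_frame([("MID", "1", 1_490_000, 1_510_000, True)])
    leads = pd.DataFrame([
        {"LOCUS_ID": "LB", "CHR": "1", "POS": 1_700_000},
        {"LOCUS_ID": "LA", "CHR": "1", "POS": 1_300_000},
    ])
    out = assign_candidates(leads, genes)
    assert out["LOCUS_ID"].tolist() == ["LA"]


# ---------------------------------------------------------------------------
# variant-annotation domain

def test_nearest_gene_item_unique_with_tiebreak():
    cand = genes_frame([
        ("G_FAR", "1", 500_000, 600_000, True),
        ("G_B", "1", 1_100_000, 1_200_000, True),   # 100 kb away
        ("G_A", "1", 800_000, 900_000, True),       # 100 kb away, lower start
    ])
    items = annotate_variant_domain("L1", 1_000_000, lead_maf=0.2, candidates=cand)
    nearest = items[items["SUBCATEGORY"] == "nearest_gene"]
    assert nearest["GENE_ID"].tolist() == ["G_A"]


@pytest.mark.parametrize("maf, expect_rare", [(0.004, True), (0.02, False)])
def test_rare_variant_item_follows_maf_rule(maf, expect_rare):
    cand = genes_frame([("G1", "1", 990_000, 1_010_000, True)])
    items = annotate_variant_domain("L1", 1_000_000, lead_maf=maf, candidates=cand)
    assert ("rare_variant" in set(items["SUBCATEGORY"])) == expect_rare


def test_protein_altering_items_from_consequence_table():
    cand = genes_frame([("G1", "1", 990_000, 1_010_000, True),
                        ("G2", "1", 1_200_000, 1_300_000, True)])
    vep = pd.DataFrame([{"GENE_ID": "G2", "PROTEIN_ALTERING": True}])
    items = annotate_variant_domain("L1", 1_000_000, 0.2, cand, vep)
    pa = items[items["SUBCATEGORY"] == "protein_altering"]
    assert pa["GENE_ID"].tolist() == ["G2"]


# ---------------------------------------------------------------------------
# aggregation rules

def test_splice_junctions_collapse_to_one_item():
    items = items_frame([
        {"GENE_ID": "G1", "DOMAIN": "sqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "twas", "UNIT_ID": f"junc{i}"} for i in range(3)
    ])
    agg = aggregate_evidence(items)
    assert len(agg) == 1
    assert not agg["REPLICATED"].iloc[0]


def test_fine_mapped_twas_supersedes_plain_twas():
    items = items_frame([
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "fine_mapped_twas"},
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "twas", "UNIT_ID": "t1"},
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "lcl",
         "SUBCATEGORY": "twas", "UNIT_ID": "t2"},
        # another gene's plain TWAS is untouched
        {"GENE_ID": "G2", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "twas"},
    ])
    agg = aggregate_evidence(items)
    kept = set(zip(agg["GENE_ID"], agg["SUBCATEGORY"]))
    assert ("G1", "fine_mapped_twas") in kept
    assert ("G1", "twas") not in kept
    assert ("G2", "twas") in kept


def test_low_blood_brain_correlation_cpgs_dropped_when_high_exist():
    items = items_frame([
        {"GENE_ID": "G1", "DOMAIN": "mqtl", "CATEGORY": "blood",
         "SUBCATEGORY": "metameth", "UNIT_ID": "cpg1", "BLOOD_BRAIN_CORR": 0.9},
        {"GENE_ID": "G1", "DOMAIN": "mqtl", "CATEGORY": "blood",
         "SUBCATEGORY": "metameth", "UNIT_ID": "cpg2", "BLOOD_BRAIN_CORR": 0.1},
        # G2 has only low-correlation CpGs: kept (rule fires only alongside high)
        {"GENE_ID": "G2", "DOMAIN": "mqtl", "CATEGORY": "blood",
         "SUBCATEGORY": "metameth", "UNIT_ID": "cpg3", "BLOOD_BRAIN_CORR": 0.0},
    ])
    agg = aggregate_evidence(items)
    g1 = agg[agg["GENE_ID"] == "G1"]
    assert len(g1) == 1 and g1["BLOOD_BRAIN_CORR"].iloc[0] == pytest.approx(0.9)
    assert (agg["GENE_ID"] == "G2").sum() == 1


def test_replication_requires_two_datasets():
    items = items_frame([
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "colocalization", "DATASET_ID": "ds1"},
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "colocalization", "DATASET_ID": "ds2"},
        {"GENE_ID": "G2", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "colocalization", "DATASET_ID": "ds1"},
    ])
    agg = aggregate_evidence(items).set_index("GENE_ID")
    assert bool(agg.loc["G1", "REPLICATED"])
    assert not bool(agg.loc["G2", "REPLICATED"])


# ---------------------------------------------------------------------------
# scoring

def unit_config(mapping, max_score=10.0):
    """WeightConfig with explicit single==replicated weights for test arithmetic."""
    weights = {}
    for (domain, subcat), w in mapping.items():
        weights.setdefault(domain, {})[subcat] = {
            "na": {"single": w, "replicated": w},
            "brain": {"single": w, "replicated": w},
            "peripheral": {"single": w, "replicated": w},
        }
    return WeightConfig(weights, max_score, frozenset({"brain_bulk", "microglia", "dlpfc"}),
                        frozenset({"lcl", "monocyte_macrophage", "blood"}))


def test_score_sums_configured_weights():
    cfg = unit_config({
        ("eqtl", "colocalization"): 2.0,
        ("sqtl", "twas"): 3.0,
        ("mqtl", "metameth"): 1.0,
        ("app_metabolism", "sirna_hit"): 4.0,
    })
    items = aggregate_evidence(items_frame([
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "colocalization"},
        {"GENE_ID": "G1", "DOMAIN": "sqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "twas"},
        {"GENE_ID": "G1", "DOMAIN": "mqtl", "CATEGORY": "blood",
         "SUBCATEGORY": "metameth"},
        {"GENE_ID": "G1", "DOMAIN": "app_metabolism", "CATEGORY": "n/a",
         "SUBCATEGORY": "sirna_hit"},
    ]))
    score = score_gene("G1", items, cfg)
    assert score.raw_score == pytest.approx(10.0)
    assert score.rescaled_score == pytest.approx(100.0)
    assert sum(score.per_domain.values()) == pytest.approx(score.raw_score)
    assert score.per_domain["eqtl"] == pytest.approx(2.0)


def test_no_evidence_scores_zero():
    cfg = default_weights()
    score = score_gene("GX", aggregate_evidence(items_frame([])), cfg)
    assert score.raw_score == 0.0 and score.rescaled_score == 0.0


def test_missing_weight_names_the_key():
    cfg = unit_config({("eqtl", "colocalization"): 2.0})
    items = aggregate_evidence(items_frame([
        {"GENE_ID": "G1", "DOMAIN": "haqtl", "CATEGORY": "dlpfc",
         "SUBCATEGORY": "lead_qtl_hit"},
    ]))
    with pytest.raises(WeightConfigError, match="haqtl"):
        score_gene("G1", items, cfg)


def test_default_weights_satisfy_ordering_constraints():
    cfg = default_weights()
    cfg.validate()
    # brain beats peripheral, replication beats single, for a representative key
    assert cfg.weight("eqtl", "brain_bulk", "colocalization", True) > cfg.weight(
        "eqtl", "lcl", "colocalization", True
    )
    assert cfg.weight("eqtl", "brain_bulk", "colocalization", True) > cfg.weight(
        "eqtl", "brain_bulk", "colocalization", False
    )


# ---------------------------------------------------------------------------
# tiers

def scores(pairs):
    return [GeneScore(g, "L1", raw, raw, {}) for g, raw in pairs]


def test_clear_top_gene_is_tier1_with_band_rule():
    out = {s.gene_id: s.tier for s in classify_tiers(scores([("A", 10), ("B", 7), ("C", 4)]))}
    assert out == {"A": TIER1, "B": TIER2, "C": UNRANKED}  # rel 0.30 / 0.60


def test_close_runner_up_demotes_both_to_tier2():
    out = {s.gene_id: s.tier for s in classify_tiers(scores([("A", 10), ("B", 9)]))}
    assert out == {"A": TIER2, "B": TIER2}


def test_sole_gene_below_minimum_score_is_tier2():
    out = classify_tiers(scores([("A", 3.5)]))
    assert out[0].tier == TIER2


def test_all_zero_locus_stays_unranked():
    out = classify_tiers(scores([("A", 0.0), ("B", 0.0)]))
    assert {s.tier for s in out} == {UNRANKED}


TRUTH_TABLE = []
for rel in (0.19, 0.20, 0.21, 0.49, 0.50, 0.51):
    for s1 in (3.9, 4.0, 4.1):
        if s1 >= 4.0 and rel >= 0.20:
            expected = (TIER1, TIER2 if rel <= 0.50 else UNRANKED)
        elif rel < 0.20:
            expected = (TIER2, TIER2)
        else:  # s1 < 4.0 and runner-up not close
            expected = (TIER2, UNRANKED)
        TRUTH_TABLE.append((s1, rel, expected))


@pytest.mark.parametrize("s1, rel, expected", TRUTH_TABLE)
def test_tier_rule_truth_table(s1, rel, expected):
    """Every boundary of the relative-difference and minimum-score rules."""
    out = classify_tiers(scores([("TOP", s1), ("OTHER", s1 * (1 - rel))]))
    by_gene = {s.gene_id: s.tier for s in out}
    assert (by_gene["TOP"], by_gene["OTHER"]) == expected


def test_at_most_one_tier1_and_minimum_score(rng):
    for _ in range(200):
        n = rng.integers(1, 6)
        out = classify_tiers(scores([(f"G{i}", float(rng.uniform(0, 12))) for i in range(n)]))
        tier1 = [s for s in out if s.tier == TIER1]
        assert len(tier1) <= 1
        if tier1:
            assert tier1[0].raw_score >= 4.0
            assert tier1[0].raw_score == max(s.raw_score for s in out)


def test_scale_invariance_of_rescaled_scores_and_tiers():
    cfg = default_weights()
    items = aggregate_evidence(items_frame([
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "colocalization", "DATASET_ID": "d1"},
        {"GENE_ID": "G1", "DOMAIN": "eqtl", "CATEGORY": "brain_bulk",
         "SUBCATEGORY": "colocalization", "DATASET_ID": "d2"},
        {"GENE_ID": "G1", "DOMAIN": "app_metabolism", "CATEGORY": "n/a",
         "SUBCATEGORY": "sirna_hit"},
        {"GENE_ID": "G2", "DOMAIN": "eqtl", "CATEGORY": "lcl",
         "SUBCATEGORY": "lead_qtl_hit"},
    ]))
    for c in (1.0, 3.0, 0.25):
        cfg_c = cfg.scaled(c)
        s1 = score_gene("G1", items, cfg_c)
        s2 = score_gene("G2", items, cfg_c)
        base1 = score_gene("G1", items, cfg)
        assert s1.rescaled_score == pytest.approx(base1.rescaled_score)
        tiers = classify_tiers([s1, s2], min_top_score=4.0 * c)
        assert tiers[0].tier == TIER1
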