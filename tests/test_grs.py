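"""GRS construction, Cox progression fits, HR meta-analysis, decile rescaling, indices."""

import math

import numpy as np
import pandas as pd
import pytest

from addgwas.grs import (
    CoxResult,
    DegenerateWeightError,
    FittingError,
    GRSModel,
    compute_grs,
    compute_grs_frame,
    conversion_probabilities,
    decile_contrast_hr,
    fit_progression,
    grs_model_from_table,
    meta_hr,
    pooled_deciles,
    predictive_indices,
    published_grs_variants,
)
from addgwas.synthetic import SimConfig, gen_cohort, gen_grs_model
from oracles import dersimonian_laird, wls_ivw


def model_from(entries):
    """entries: (chrom, pos, ref, alt, risk_allele, weight)."""
    rows = [{"ID": f"{c}:{p}:{r}:{a}", "CHR": str(c), "POS": p, "REF": r,
             "ALT": a, "RISK_ALLELE": k, "WEIGHT": w}
            for c, p, r, a, k, w in entries]
    return GRSModel(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# model building

def test_protective_minor_allele_flips_to_major_risk():
    table = pd.DataFrame([{"CHR": "2", "POS": 100, "MINOR": "T", "MAJOR": "C",
                           "MAF": 0.2, "OR": 0.93}])
    model = grs_model_from_table(table)
    entry = model.entries.iloc[0]
    assert entry["RISK_ALLELE"] == "C"  # the major allele
    assert entry["WEIGHT"] == pytest.approx(-math.log(0.93))
    assert entry["RAF"] == pytest.approx(0.8)


def test_apoe_region_variants_excluded():
    table = pd.DataFrame([
        {"CHR": "19", "POS": 44_500_000, "MINOR": "A", "MAJOR": "G", "MAF": 0.1, "OR": 3.0},
        {"CHR": "19", "POS": 1_050_875, "MINOR": "A", "MAJOR": "G", "MAF": 0.3, "OR": 1.1},
    ])
    model = grs_model_from_table(table)
    assert model.n_variants == 1
    assert model.entries["POS"].iloc[0] == 1_050_875


def test_or_of_exactly_one_is_degenerate():
    table = pd.DataFrame([{"CHR": "1", "POS": 100, "MINOR": "A", "MAJOR": "G",
                           "MAF": 0.3, "OR": 1.0}])
    with pytest.raises(DegenerateWeightError):
        grs_model_from_table(table)


def test_published_catalog_partitions():
    known = published_grs_variants("known")
    novel = published_grs_variants("novel")
    assert len(known) == 39 and len(novel) == 44
    combined = published_grs_variants()
    assert len(combined) == 83
    # none of the published lead variants fall in the APOE exclusion window
    assert grs_model_from_table(combined).n_variants == 83


# ---------------------------------------------------------------------------
# scoring

def test_equal_weights_give_average_dosage_times_n():
    model = model_from([
        ("1", 1, "A", "G", "G", 0.1),
        ("1", 2, "A", "G", "G", 0.1),
        ("1", 3, "A", "G", "G", 0.1),
    ])
    grs = compute_grs({"1:1:A:G": 0.0, "1:2:A:G": 1.0, "1:3:A:G": 2.0}, model)
    assert grs == pytest.approx(3.0)


def test_weighted_average_arithmetic():
    model = model_from([("1", 1, "A", "G", "G", 0.1), ("1", 2, "A", "G", "G", 0.3)])
    grs = compute_grs({"1:1:A:G": 2.0, "1:2:A:G": 1.0}, model)
    assert grs == pytest.approx((0.2 + 0.3) / 0.4 * 2)


def test_risk_allele_orientation_flips_dosage():
    model = model_from([("1", 1, "A", "G", "A", 0.2)])  # risk allele is REF
    assert compute_grs({"1:1:A:G": 0.0}, model) == pytest.approx(2.0 * 0.2 / 0.2)


def test_weight_rescaling_and_order_invariance(rng):
    entries = [("1", i, "A", "G", "G", float(w))
               for i, w in enumerate(rng.uniform(0.05, 0.4, 8), start=1)]
    dosages = {f"1:{i}:A:G": float(d) for i, d in
               enumerate(rng.integers(0, 3, 8), start=1)}
    base = compute_grs(dosages, model_from(entries))
    scaled = compute_grs(dosages, model_from([(c, p, r, a, k, 10 * w)
                                              for c, p, r, a, k, w in entries]))
    shuffled = compute_grs(dosages, model_from(entries[::-1]))
    assert scaled == pytest.approx(base)
    assert shuffled == pytest.approx(base)


def test_missing_variants_renormalize_and_zero_available_errors():
    model = model_from([("1", 1, "A", "G", "G", 0.1), ("1", 2, "A", "G", "G", 0.3)])
    only_first = compute_grs({"1:1:A:G": 2.0}, model)
    assert only_first == pytest.approx(1 * (0.1 * 2.0) / 0.1)
    with pytest.raises(ValueError, match="no dosages"):
        compute_grs({}, model)


def test_frame_scoring_matches_scalar_route(rng):
    cfg = SimConfig(cohort_n=50, seed=11)
    model = gen_grs_model(cfg, 6)
    cohort = gen_cohort(cfg, model)
    frame_scores = compute_grs_frame(cohort, model)
    for i in rng.choice(len(cohort), 10, replace=False):
        row = cohort.iloc[int(i)]
        dosages = {vid: row[vid] for vid in model.entries["ID"]}
        assert frame_scores.iloc[int(i)] == pytest.approx(compute_grs(dosages, model))


# ---------------------------------------------------------------------------
# decile rescaling

def test_decile_contrast_identities():
    assert decile_contrast_hr(1.0, 10.0, 99.0) == pytest.approx(1.0)
    # log-linearity: contrast(a,b)·contrast(b,c) == contrast(a,c)
    h = 1.076
    ab = decile_contrast_hr(h, 50.0, 55.0)
    bc = decile_contrast_hr(h, 55.0, 60.0)
    ac = decile_contrast_hr(h, 50.0, 60.0)
    assert ab * bc == pytest.approx(ac, rel=1e-12)
    with pytest.raises(ValueError):
        decile_contrast_hr(-1.0, 0, 1)
    with pytest.raises(ValueError):
        decile_contrast_hr(1.1, 5, 1)


def test_pooled_deciles_linear_interpolation():
    cuts = pooled_deciles(np.arange(1, 101, dtype=float))
    assert cuts[0] == pytest.approx(10.9)
    assert cuts[-1] == pytest.approx(90.1)
    assert len(cuts) == 9
    const = pooled_deciles(np.full(50, 7.0))
    assert np.allclose(const, 7.0)


# ---------------------------------------------------------------------------
# Cox fits

def test_null_per_allele_effect_recovered_within_3se():
    cfg = SimConfig(cohort_n=4000, per_allele_log_hr=0.0, seed=21)
    model = gen_grs_model(cfg)
    result = fit_progression(gen_cohort(cfg, model), model)
    assert abs(result.log_hr) <= 3 * result.se


def test_positive_effect_recovered_within_3se():
    cfg = SimConfig(cohort_n=8000, seed=22)
    model = gen_grs_model(cfg)
    result = fit_progression(gen_cohort(cfg, model), model)
    assert abs(result.log_hr - cfg.per_allele_log_hr) <= 3 * result.se
    lo, hi = result.ci95
    assert lo == pytest.approx(math.exp(result.log_hr - 1.96 * result.se))
    assert hi == pytest.approx(math.exp(result.log_hr + 1.96 * result.se))


def test_all_dementia_outcome_has_more_events():
    cfg = SimConfig(cohort_n=3000, other_dementia_rate=0.01, seed=23)
    model = gen_grs_model(cfg)
    cohort = gen_cohort(cfg, model)
    ad = fit_progression(cohort, model, outcome="AD")
    alld = fit_progression(cohort, model, outcome="all_dementia")
    assert alld.n_events > ad.n_events


def test_too_few_events_refused():
    cfg = SimConfig(cohort_n=40, seed=24, base_ad_rate=0.001)
    model = gen_grs_model(cfg)
    cohort = gen_cohort(cfg, model)
    with pytest.raises(ValueError, match="events"):
        fit_progression(cohort, model, min_events=1000)


def test_apoe4_interaction_term_reported():
    cfg = SimConfig(cohort_n=3000, seed=25)
    model = gen_grs_model(cfg)
    result = fit_progression(gen_cohort(cfg, model), model, interaction_apoe4=True)
    assert result.interaction is not None
    assert result.interaction.term == "GRS_x_APOE4"
    assert result.interaction.se > 0


# ---------------------------------------------------------------------------
# HR meta-analysis

def cox(log_hr, se, cid="C"):
    return CoxResult(log_hr=log_hr, se=se, p=0.5, n=100, n_events=20, cohort_id=cid)


def test_identical_cohorts_shrink_se_without_heterogeneity():
    k = 4
    mh = meta_hr([cox(0.07, 0.02)] * k)
    assert mh.fixed_log_hr == pytest.approx(0.07)
    assert mh.fixed_se == pytest.approx(0.02 / math.sqrt(k))
    assert mh.i2 == 0.0 and mh.tau2 == 0.0
    assert mh.random_log_hr == pytest.approx(mh.fixed_log_hr)


def test_meta_hr_matches_closed_form_oracles(rng):
    for _ in range(30):
        k = int(rng.integers(2, 8))
        b = rng.normal(0.05, 0.1, k)
        s = rng.uniform(0.01, 0.1, k)
        mh = meta_hr([cox(float(bi), float(si)) for bi, si in zip(b, s)])
        beta_o, se_o, _ = wls_ivw(b, s)
        assert mh.fixed_log_hr == pytest.approx(beta_o, abs=1e-12)
        assert mh.fixed_se == pytest.approx(se_o, abs=1e-12)
        dl_b, dl_se, dl_tau2 = dersimonian_laird(b, s)
        assert mh.random_log_hr == pytest.approx(dl_b, abs=1e-12)
        assert mh.random_se == pytest.approx(dl_se, abs=1e-12)
        assert mh.tau2 == pytest.approx(dl_tau2, abs=1e-12)
        assert mh.random_se >= mh.fixed_se - 1e-12
        assert min(b) - 1e-12 <= mh.fixed_log_hr <= max(b) + 1e-12


def test_single_cohort_passthrough_warns():
    with pytest.warns(UserWarning, match="single cohort"):
        mh = meta_hr([cox(0.08, 0.03)])
    assert mh.fixed_log_hr == pytest.approx(0.08)
    assert mh.n_cohorts == 1


# ---------------------------------------------------------------------------
# predictive indices and conversion probabilities

@pytest.fixture(scope="module")
def indexed_cohort():
    cfg = SimConfig(cohort_n=1500, per_allele_log_hr=math.log(1.25), seed=31,
                    base_ad_rate=0.05)
    model = gen_grs_model(cfg, 10)
    return cfg, model, gen_cohort(cfg, model)


def test_strong_grs_improves_all_indices(indexed_cohort):
    cfg, model, cohort = indexed_cohort
    report = predictive_indices(cohort, model, horizon=5.0, bootstrap_n=0)
    assert report.c_index_delta > 0
    assert report.nri > 0
    assert report.ipa_delta > 0


def test_noise_grs_delta_ci_covers_zero(indexed_cohort):
    cfg, model, cohort = indexed_cohort
    noise = pd.Series(np.random.default_rng(5).standard_normal(len(cohort)),
                      index=cohort.index)
    report = predictive_indices(cohort, horizon=5.0, bootstrap_n=60, seed=9, grs=noise)
    lo, hi = report.ci95["c_index_delta"]
    assert lo <= 0.0 <= hi


def test_bootstrap_is_seeded(indexed_cohort):
    cfg, model, cohort = indexed_cohort
    a = predictive_indices(cohort, model, horizon=5.0, bootstrap_n=20, seed=7)
    b = predictive_indices(cohort, model, horizon=5.0, bootstrap_n=20, seed=7)
    assert a.ci95 == b.ci95


def test_collinear_added_covariate_is_rejected(indexed_cohort):
    """A GRS duplicating an existing covariate makes the full model singular."""
    cfg, model, cohort = indexed_cohort
    with pytest.raises(FittingError):
        predictive_indices(cohort, horizon=5.0, bootstrap_n=0,
                           grs=cohort["AGE"].copy())


def test_no_events_before_horizon_errors(indexed_cohort):
    cfg, model, cohort = indexed_cohort
    early = cohort["TIME"].min() / 2
    with pytest.raises(ValueError, match="horizon"):
        predictive_indices(cohort, model, horizon=early, bootstrap_n=0)


def test_conversion_probabilities_monotone_under_strong_effect(indexed_cohort):
    cfg, model, cohort = indexed_cohort
    table, diff = conversion_probabilities(cohort, model, horizon=5.0)
    assert diff > 0
    probs = table.sort_values("DECILE_GROUP")["MEAN_PROB"].to_numpy()
    # top group clearly exceeds bottom; interior wiggle is sampling noise
    assert probs[-1] > probs[0]
    assert diff == pytest.approx(probs[-1] - probs[0])


def test_conversion_probabilities_vanish_at_tiny_horizon(indexed_cohort):
    cfg, model, cohort = indexed_cohort
    table5, _ = conversion_probabilities(cohort, model, horizon=5.0)
    table, diff = conversion_probabilities(cohort, model, horizon=1e-4)
    assert (table["MEAN_PROB"] < 0.01).all()
    assert table["MEAN_PROB"].max() < 0.05 * table5["MEAN_PROB"].max()
    assert abs(diff) < 0.01
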