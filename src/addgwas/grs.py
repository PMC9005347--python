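"""Genetic risk score (GRS) construction and progression-to-AD analysis.

The GRS is the weighted average of risk-increasing allele dosages, multiplied
by the number of included variants::

    GRS = n · Σ wᵢ dᵢ / Σ wᵢ

with wᵢ the stage II log(OR) oriented to the risk-increasing allele and dᵢ the
risk-allele dosage in [0, 2].  A hazard ratio estimated on this scale measures
the effect of carrying one additional average risk allele.  APOE variants are
excluded from the model; APOE ε4/ε2 allele counts enter the Cox models as
covariates instead, together with age, sex and the first four principal
components.

Cohort tables are CSV/DataFrames with columns::

    SUBJECT_ID  COHORT_ID  TIME  EVENT  AGE  SEX  PC1..PC4  APOE4  APOE2  <dosage columns>

``EVENT`` is one of AD, OTHER_DEM, CENSORED; dosage columns are named by
variant id (``chr:pos:ref:alt``) and count ALT-allele copies.

Per-cohort hazard ratios are combined by fixed-effect IVW and
DerSimonian–Laird random-effects meta-analysis, rescaled to the contrast
between the first and ninth deciles of the pooled GRS distribution via
``exp(log(HR)·(GRS₉ − GRS₁))``, and evaluated with three predictive indices:
the truncated IPCW concordance index, the continuous net reclassification
improvement and the index of prediction accuracy (1 − Brier/Brier_null).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .loci import LocusCall
from .sumstats import APOE_REGION, GenomicRegion

__all__ = [
    "GRSModel",
    "CoxResult",
    "MetaHR",
    "IndexReport",
    "DegenerateWeightError",
    "FittingError",
    "build_grs_model",
    "grs_model_from_table",
    "published_grs_variants",
    "published_grs_model",
    "compute_grs",
    "compute_grs_frame",
    "fit_progression",
    "meta_hr",
    "pooled_deciles",
    "decile_contrast_hr",
    "predictive_indices",
    "conversion_probabilities",
]

BASE_COVARIATES = ["AGE", "SEX", "PC1", "PC2", "PC3", "PC4", "APOE4", "APOE2"]
EVENT_AD = "AD"
EVENT_OTHER = "OTHER_DEM"
EVENT_CENSORED = "CENSORED"


class DegenerateWeightError(ValueError):
    """A model variant has an odds ratio of exactly 1 (zero log-OR weight)."""


class FittingError(RuntimeError):
    """A Cox model failed to converge; diagnostics in the message."""


@dataclass
class GRSModel:
    """Risk-score definition: variants, risk alleles and positive log-OR weights.

    ``entries`` columns: ID, CHR, POS, REF, ALT, RISK_ALLELE, WEIGHT and
    optionally RAF (risk-allele frequency, used when imputing missing
    dosages).  Weights are strictly positive after orientation to the
    risk-increasing allele.
    """

    entries: pd.DataFrame
    name: str = "GRS"

    def __post_init__(self) -> None:
        if (self.entries["WEIGHT"] <= 0).any():
            bad = self.entries.loc[self.entries["WEIGHT"] <= 0, "ID"].tolist()
            raise DegenerateWeightError(f"non-positive weight after orientation: {bad}")

    @property
    def n_variants(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()

    def write(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, name: str = "GRS") -> "GRSModel":
        return cls(pd.read_csv(path, sep="\t", dtype={"CHR": str}), name=name)


def _orient(chrom, pos, ref, alt, beta) -> dict:
    """Orient a signed ALT-allele log(OR) to the risk-increasing allele."""
    if beta == 0:
        raise DegenerateWeightError(f"variant {chrom}:{pos}:{ref}:{alt} has OR exactly 1")
    risk = alt if beta > 0 else ref
    return {
        "ID": f"{chrom}:{pos}:{ref}:{alt}",
        "CHR": str(chrom), "POS": int(pos), "REF": ref, "ALT": alt,
        "RISK_ALLELE": risk, "WEIGHT": abs(float(beta)),
    }


def build_grs_model(
    calls: Sequence[LocusCall],
    apoe_region: GenomicRegion = APOE_REGION,
    name: str = "GRS",
) -> GRSModel:
    """Build a GRS from genome-wide-significant locus calls.

    One entry per qualifying lead variant, weighted by the absolute stage II
    log(OR) with the risk allele set to the OR-increasing allele.  Variants
    inside the APOE region are excluded.  Partitioned models (known-only,
    novel-only) are built by passing the corresponding subset of calls.
    """
    rows = []
    for call in calls:
        if call.classification != "genome_wide_significant" or call.stage2 is None:
            continue
        chrom, pos, ref, alt = call.lead.split(":")
        if apoe_region is not None and bool(apoe_region.contains([chrom], [int(pos)])[0]):
            continue
        rows.append(_orient(chrom, pos, ref, alt, call.stage2.beta))
    return GRSModel(pd.DataFrame(rows), name=name)


def grs_model_from_table(
    table: pd.DataFrame,
    apoe_region: GenomicRegion | None = APOE_REGION,
    name: str = "GRS",
) -> GRSModel:
    """Build a GRS from a lead-variant table with MINOR/MAJOR alleles and OR.

    The odds ratio is taken with respect to the minor allele: the risk allele
    is the minor allele when OR > 1 and the major allele when OR < 1, with
    weight |log(OR)|.  The major allele is used as REF, the minor as ALT, so
    dosage columns count minor-allele copies.  RAF (risk-allele frequency) is
    derived from MAF when present.
    """
    rows = []
    for r in table.itertuples(index=False):
        beta = math.log(float(r.OR))
        entry = _orient(r.CHR, r.POS, r.MAJOR, r.MINOR, beta)
        if apoe_region is not None and bool(
            apoe_region.contains([entry["CHR"]], [entry["POS"]])[0]
        ):
            continue
        if hasattr(r, "MAF"):
            maf = float(r.MAF)
            entry["RAF"] = maf if entry["RISK_ALLELE"] == entry["ALT"] else 1.0 - maf
        rows.append(entry)
    return GRSModel(pd.DataFrame(rows), name=name)


def published_grs_variants(subset: str | None = None) -> pd.DataFrame:
    """The packaged catalog of genome-wide-significant lead variants.

    83 lead variants from the two-stage dementia GWAS: 39 in previously known
    loci and 44 in newly identified loci, with GRCh38 coordinates,
    minor/major alleles, weighted-average minor-allele frequency and the
    approximate odds ratio with respect to the minor allele.  ``subset`` may
    be ``"known"`` or ``"novel"``.
    """
    ref = resources.files("addgwas").joinpath("data/published_grs_variants.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, comment="#")
    if subset is not None:
        if subset not in ("known", "novel"):
            raise ValueError("subset must be 'known', 'novel' or None")
        df = df[df["SET"] == subset].reset_index(drop=True)
    return df


def published_grs_model(subset: str | None = None) -> GRSModel:
    """GRS model built from the packaged lead-variant catalog."""
    name = {"known": "GRS_known", "novel": "GRS_novel", None: "GRS"}[subset]
    return grs_model_from_table(published_grs_variants(subset), name=name)


# ---------------------------------------------------------------------------
# scoring

def compute_grs(dosages: Mapping[str, float], model: GRSModel) -> float:
    """GRS for one subject from ALT-dosage mapping keyed by variant id.

    Dosages are oriented to the risk allele, averaged with the model weights
    over the entries the subject has data for, and multiplied by the number
    of available entries (per-subject renormalization for missing variants).
    """
    w_sum = 0.0
    wd_sum = 0.0
    n_avail = 0
    for e in model.entries.itertuples(index=False):
        d = dosages.get(e.ID)
        if d is None or (isinstance(d, float) and math.isnan(d)):
            continue
        d_risk = float(d) if e.RISK_ALLELE == e.ALT else 2.0 - float(d)
        w_sum += e.WEIGHT
        wd_sum += e.WEIGHT * d_risk
        n_avail += 1
    if n_avail == 0:
        raise ValueError("subject has no dosages for any model variant")
    return n_avail * wd_sum / w_sum


def compute_grs_frame(
    cohort: pd.DataFrame,
    model: GRSModel,
    missing: str = "renormalize",
) -> pd.Series:
    """Vectorized GRS over a cohort table with dosage columns named by variant id.

    ``missing="renormalize"`` computes each subject's score over their
    available entries with the available count as the multiplier;
    ``missing="impute_raf"`` substitutes 2·RAF for missing dosages (requires
    a RAF column in the model).
    """
    entries = model.entries
    present = entries[entries["ID"].isin(cohort.columns)]
    if len(present) == 0:
        raise ValueError("cohort has no dosage columns for any model variant")
    d = cohort[present["ID"]].to_numpy(dtype=float)
    flip = (present["RISK_ALLELE"] != present["ALT"]).to_numpy()
    d = np.where(flip, 2.0 - d, d)
    w = present["WEIGHT"].to_numpy()
    if missing == "impute_raf":
        if "RAF" not in present.columns or present["RAF"].isna().any():
            raise ValueError("impute_raf requires RAF for every model variant")
        fill = 2.0 * present["RAF"].to_numpy()
        d = np.where(np.isnan(d), fill, d)
    elif missing != "renormalize":
        raise ValueError(f"unknown missing policy {missing!r}")
    avail = ~np.isnan(d)
    n_avail = avail.sum(axis=1)
    if (n_avail == 0).any():
        raise ValueError("some subjects have no dosages for any model variant")
    w_mat = np.where(avail, w, 0.0)
    score = n_avail * np.nansum(d * w_mat, axis=1) / w_mat.sum(axis=1)
    return pd.Series(score, index=cohort.index, name=model.name)


# ---------------------------------------------------------------------------
# Cox progression models

@dataclass
class CoxResult:
    """A proportional-hazards estimate for the GRS term."""

    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    term: str = "GRS"
    cohort_id: str = ""
    interaction: "CoxResult | None" = None

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.log_hr - 1.96 * self.se),
            math.exp(self.log_hr + 1.96 * self.se),
        )


def _event_indicator(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """1 for the modelled event; other-dementia conversions censor the AD outcome."""
    if outcome == "AD":
        return (cohort["EVENT"] == EVENT_AD).astype(int)
    if outcome == "all_dementia":
        return cohort["EVENT"].isin([EVENT_AD, EVENT_OTHER]).astype(int)
    raise ValueError(f"unknown outcome {outcome!r}")


def _fit_cox(df: pd.DataFrame, duration: str, event: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration, event_col=event)
    except ConvergenceError as exc:
        raise FittingError(f"Cox model failed to converge: {exc}") from exc
    return cph


def fit_progression(
    cohort: pd.DataFrame,
    model: GRSModel | None = None,
    outcome: str = "AD",
    interaction_apoe4: bool = False,
    covariates: Sequence[str] = tuple(BASE_COVARIATES),
    min_events: int = 10,
    grs: pd.Series | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit of progression on the GRS.

    The GRS (computed from ``model`` unless supplied directly) enters with
    the covariates age, sex, four PCs and the APOE ε4/ε2 allele counts.  With
    ``outcome="AD"``, conversions to other dementias are censored at
    conversion time; ``outcome="all_dementia"`` counts them as events.  An
    optional multiplicative GRS × APOE-ε4 interaction is reported on the
    result's ``interaction`` field.
    """
    if grs is None:
        if model is None:
            raise ValueError("either a GRS model or precomputed scores are required")
        grs = compute_grs_frame(cohort, model)
    df = cohort[list(covariates)].copy()
    df["GRS"] = np.asarray(grs, dtype=float)
    df["T"] = cohort["TIME"].astype(float)
    df["E"] = _event_indicator(cohort, outcome)
    n_events = int(df["E"].sum())
    if n_events < min_events:
        raise ValueError(f"only {n_events} events (< {min_events}); refusing to fit")
    if interaction_apoe4:
        df["GRS_x_APOE4"] = df["GRS"] * df["APOE4"]
    cph = _fit_cox(df, "T", "E")
    cohort_id = str(cohort["COHORT_ID"].iloc[0]) if "COHORT_ID" in cohort.columns else ""
    result = CoxResult(
        log_hr=float(cph.params_["GRS"]),
        se=float(cph.standard_errors_["GRS"]),
        p=float(cph.summary.loc["GRS", "p"]),
        n=len(df),
        n_events=n_events,
        cohort_id=cohort_id,
    )
    if interaction_apoe4:
        result.interaction = CoxResult(
            log_hr=float(cph.params_["GRS_x_APOE4"]),
            se=float(cph.standard_errors_["GRS_x_APOE4"]),
            p=float(cph.summary.loc["GRS_x_APOE4", "p"]),
            n=len(df),
            n_events=n_events,
            term="GRS_x_APOE4",
            cohort_id=cohort_id,
        )
    return result


# ---------------------------------------------------------------------------
# meta-analysis of hazard ratios

@dataclass
class MetaHR:
    """Fixed- and random-effects meta-analysis of per-cohort log hazard ratios."""

    fixed_log_hr: float
    fixed_se: float
    fixed_p: float
    random_log_hr: float
    random_se: float
    random_p: float
    q_stat: float
    q_df: int
    q_p: float
    i2: float
    tau2: float
    n_cohorts: int

    @property
    def fixed_hr(self) -> float:
        return math.exp(self.fixed_log_hr)

    @property
    def random_hr(self) -> float:
        return math.exp(self.random_log_hr)

    @property
    def fixed_ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.fixed_log_hr - 1.96 * self.fixed_se),
            math.exp(self.fixed_log_hr + 1.96 * self.fixed_se),
        )


def meta_hr(results: Sequence[CoxResult]) -> MetaHR:
    """IVW fixed-effect and DerSimonian–Laird random-effects meta-analysis.

    ``I² = max(0, (Q − df)/Q)``; the DL between-cohort variance is
    ``τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`` with fixed-effect weights w.
    A single cohort passes through with a warning.
    """
    if len(results) == 0:
        raise ValueError("no cohort results supplied")
    b = np.array([r.log_hr for r in results])
    se = np.array([r.se for r in results])
    w = 1.0 / se**2
    sumw = w.sum()
    fixed = float((w * b).sum() / sumw)
    fixed_se = float(1.0 / math.sqrt(sumw))
    q = float((w * (b - fixed) ** 2).sum())
    df = len(results) - 1
    if len(results) == 1:
        warnings.warn("single cohort: meta-analysis is a pass-through", stacklevel=2)
        q_p, i2, tau2 = 1.0, 0.0, 0.0
        rand, rand_se = fixed, fixed_se
    else:
        q_p = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
        c = sumw - (w**2).sum() / sumw
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        rand = float((w_star * b).sum() / w_star.sum())
        rand_se = float(1.0 / math.sqrt(w_star.sum()))
    two_sided = lambda est, s: float(2.0 * stats.norm.sf(abs(est / s)))
    return MetaHR(
        fixed_log_hr=fixed, fixed_se=fixed_se, fixed_p=two_sided(fixed, fixed_se),
        random_log_hr=rand, random_se=rand_se, random_p=two_sided(rand, rand_se),
        q_stat=q, q_df=df, q_p=q_p, i2=i2, tau2=tau2, n_cohorts=len(results),
    )


# ---------------------------------------------------------------------------
# decile rescaling

def pooled_deciles(grs_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Decile cut-points (10th…90th percentile) of the pooled GRS distribution.

    Linear-interpolation quantiles, so the cut-points are reproducible
    bit-for-bit across runs.
    """
    values = np.asarray(grs_values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 GRS values for deciles")
    return np.percentile(values, np.arange(10, 100, 10), method="linear")


def decile_contrast_hr(hr_per_allele: float, grs_low: float, grs_high: float) -> float:
    """Rescale a per-average-risk-allele HR to a GRS-contrast HR.

    ``exp(log(HR)·(GRS_high − GRS_low))`` — the hazard ratio between
    hypothetical individuals at the two GRS values (typically the ninth
    versus the first decile cut-point).
    """
    if hr_per_allele <= 0:
        raise ValueError("hazard ratio must be positive")
    if grs_high < grs_low:
        raise ValueError("grs_high must be >= grs_low")
    return math.exp(math.log(hr_per_allele) * (grs_high - grs_low))


# ---------------------------------------------------------------------------
# predictive indices

@dataclass
class IndexReport:
    """Added predictive value of the GRS at a fixed horizon."""

    c_index_delta: float
    nri: float
    ipa_delta: float
    horizon: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_n: int = 1000
    seed: int | None = None


def _risk_at_horizon(cph: CoxPHFitter, X: pd.DataFrame, horizon: float) -> np.ndarray:
    surv = cph.predict_survival_function(X, times=[horizon])
    return 1.0 - surv.iloc[0].to_numpy()


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    return km


def _ipcw_weights(time, event, horizon, km_cens):
    """IPCW weights: events before the horizon weighted by 1/G(T−), survivors by 1/G(h).

    Subjects censored before the horizon get weight 0.
    """
    g_at = lambda t: np.clip(km_cens.survival_function_at_times(t).to_numpy(), 1e-8, None)
    w = np.zeros(len(time))
    is_event = (event == 1) & (time <= horizon)
    is_survivor = time > horizon
    w[is_event] = 1.0 / g_at(np.maximum(time[is_event] - 1e-9, 0.0))
    w[is_survivor] = 1.0 / g_at(np.full(is_survivor.sum(), horizon))
    return w, is_event, is_survivor


def _continuous_nri(time, event, risk_with, risk_without, horizon) -> float:
    """Continuous NRI under IPC weighting at the horizon.

    Events are rewarded for upward reclassification (higher predicted risk
    once the GRS is added), non-events for downward; each group's net
    proportion is weight-normalized and the two are summed.
    """
    km_cens = _censoring_survival(time, event)
    w, is_event, is_survivor = _ipcw_weights(time, event, horizon, km_cens)
    direction = np.sign(risk_with - risk_without)
    if w[is_event].sum() == 0 or w[is_survivor].sum() == 0:
        raise ValueError("no events (or no survivors) before the horizon")
    nri_events = (w[is_event] * direction[is_event]).sum() / w[is_event].sum()
    nri_nonevents = -(w[is_survivor] * direction[is_survivor]).sum() / w[is_survivor].sum()
    return float(nri_events + nri_nonevents)


def _ipcw_c_index(time, event, risk, horizon) -> float:
    from sksurv.metrics import concordance_index_ipcw
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    return float(concordance_index_ipcw(y, y, risk, tau=horizon)[0])


def _ipa(time, event, risk, horizon) -> float:
    """Index of prediction accuracy: 1 − Brier(model)/Brier(null) at the horizon."""
    from sksurv.metrics import brier_score
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    surv_prob = np.clip(1.0 - risk, 1e-12, 1.0)
    _, bs_model = brier_score(y, y, surv_prob[:, None], [horizon])
    km = KaplanMeierFitter().fit(time, event_observed=event)
    s_null = float(km.survival_function_at_times(horizon).iloc[0])
    _, bs_null = brier_score(y, y, np.full((len(time), 1), s_null), [horizon])
    return float(1.0 - bs_model[0] / bs_null[0])


def _indices_once(df, base_covariates, horizon):
    cph_base = _fit_cox(df[list(base_covariates) + ["T", "E"]], "T", "E")
    cph_full = _fit_cox(df[list(base_covariates) + ["GRS", "T", "E"]], "T", "E")
    risk_base = _risk_at_horizon(cph_base, df, horizon)
    risk_full = _risk_at_horizon(cph_full, df, horizon)
    time = df["T"].to_numpy()
    event = df["E"].to_numpy()
    d_c = _ipcw_c_index(time, event, risk_full, horizon) - _ipcw_c_index(
        time, event, risk_base, horizon
    )
    nri = _continuous_nri(time, event, risk_full, risk_base, horizon)
    d_ipa = _ipa(time, event, risk_full, horizon) - _ipa(time, event, risk_base, horizon)
    return d_c, nri, d_ipa


def predictive_indices(
    cohort: pd.DataFrame,
    model: GRSModel | None = None,
    horizon: float = 5.0,
    base_covariates: Sequence[str] = tuple(BASE_COVARIATES),
    bootstrap_n: int = 1000,
    seed: int | None = None,
    outcome: str = "AD",
    grs: pd.Series | None = None,
) -> IndexReport:
    """ΔC-index, continuous NRI and ΔIPA for adding the GRS to a base model.

    Both Cox models (base covariates, base + GRS) are fitted on the cohort;
    predicted risks at the horizon drive all three indices.  Confidence
    intervals come from a non-parametric bootstrap over subjects (stratified
    by cohort when several are present), with the seed recorded in the
    report.
    """
    if grs is None:
        if model is None:
            raise ValueError("either a GRS model or precomputed scores are required")
        grs = compute_grs_frame(cohort, model)
    df = cohort[list(base_covariates)].copy()
    df["GRS"] = np.asarray(grs, dtype=float)
    df["T"] = cohort["TIME"].astype(float)
    df["E"] = _event_indicator(cohort, outcome)
    if not ((df["E"] == 1) & (df["T"] <= horizon)).any():
        raise ValueError(f"no events before the horizon ({horizon})")
    df = df.reset_index(drop=True)
    strata = (
        cohort["COHORT_ID"].reset_index(drop=True)
        if "COHORT_ID" in cohort.columns
        else pd.Series("all", index=df.index)
    )

    d_c, nri, d_ipa = _indices_once(df, base_covariates, horizon)

    ci: dict[str, tuple[float, float]] = {}
    if bootstrap_n and bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        reps = {"c_index_delta": [], "nri": [], "ipa_delta": []}
        groups = {g: idx.to_numpy() for g, idx in df.groupby(strata).groups.items()}
        for _ in range(bootstrap_n):
            take = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in groups.values()]
            )
            boot = df.iloc[take].reset_index(drop=True)
            try:
                bc, bn, bi = _indices_once(boot, base_covariates, horizon)
            except (FittingError, ValueError):
                continue  # degenerate resample
            reps["c_index_delta"].append(bc)
            reps["nri"].append(bn)
            reps["ipa_delta"].append(bi)
        for key, vals in reps.items():
            if vals:
                lo, hi = np.percentile(vals, [2.5, 97.5])
                ci[key] = (float(lo), float(hi))

    return IndexReport(
        c_index_delta=d_c, nri=nri, ipa_delta=d_ipa, horizon=horizon,
        ci95=ci, bootstrap_n=bootstrap_n or 0, seed=seed,
    )


def conversion_probabilities(
    cohort: pd.DataFrame,
    model: GRSModel | None = None,
    horizon: float = 3.0,
    decile_cuts: np.ndarray | None = None,
    covariates: Sequence[str] = tuple(BASE_COVARIATES),
    outcome: str = "AD",
    grs: pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Mean predicted conversion probability per GRS-decile group.

    Fits the Cox model on the cohort, derives each subject's
    ``1 − S(horizon | covariates)`` from the Breslow baseline hazard, averages
    within the groups formed by the GRS deciles (pooled cut-points when
    supplied, the cohort's own otherwise) and reports the
    highest-minus-lowest group difference.
    """
    if grs is None:
        if model is None:
            raise ValueError("either a GRS model or precomputed scores are required")
        grs = compute_grs_frame(cohort, model)
    grs = pd.Series(np.asarray(grs, dtype=float), index=cohort.index)
    df = cohort[list(covariates)].copy()
    df["GRS"] = grs
    df["T"] = cohort["TIME"].astype(float)
    df["E"] = _event_indicator(cohort, outcome)
    event_times = df.loc[df["E"] == 1, "T"]
    if len(event_times) and horizon > event_times.max():
        warnings.warn(
            f"horizon {horizon} exceeds the last event time {event_times.max():.3g}; "
            "probabilities are extrapolated",
            stacklevel=2,
        )
    cph = _fit_cox(df, "T", "E")
    prob = _risk_at_horizon(cph, df, horizon)
    cuts = pooled_deciles(grs.to_numpy()) if decile_cuts is None else np.asarray(decile_cuts)
    group = np.digitize(grs.to_numpy(), cuts)  # 0..9
    table = (
        pd.DataFrame({"DECILE_GROUP": group + 1, "PROB": prob})
        .groupby("DECILE_GROUP")["PROB"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "MEAN_PROB", "size": "N"})
        .reset_index()
    )
    top = table.loc[table["DECILE_GROUP"].idxmax(), "MEAN_PROB"]
    bottom = table.loc[table["DECILE_GROUP"].idxmin(), "MEAN_PROB"]
    return table, float(top - bottom)
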