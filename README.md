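# addgwas

A toolkit for two-stage genome-wide association studies of Alzheimer's
disease and related dementias (ADD), aimed at statistical geneticists who
want the full analysis chain — from per-study summary statistics to
prioritized genes and a clinically interpretable genetic risk score — as
tested, composable Python rather than a pile of one-off scripts.

The pipeline implements:

* **Summary-statistics QC and harmonization** — canonical
  `CHR POS REF ALT EA BETA SE P EAF INFO` tables; duplicate/missing-data
  removal; the filters |β| ≤ 5, imputation INFO ≥ 0.3 and MAC × INFO ≥ 20;
  proxy-case (parental-history) studies rescaled to the case-control scale by
  β, SE → 2β, 2SE (z and p unchanged).
* **Fixed-effect IVW meta-analysis** — β = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ²,
  se = (Σwᵢ)^(−1/2), Cochran's Q heterogeneity; post-meta filters on
  heterogeneity p < 5×10⁻⁸, case fraction < 20 %, cross-study frequency
  amplitude > 0.4, and reference-panel presence; genomic inflation by the
  median method, λ = median(χ²)/0.455, excluding the APOE region
  (chr19:44–46 Mb, GRCh38).
* **Locus definition** — ±500 kb regions around stage I p < 10⁻⁵ hits,
  merged; greedy iterative clumping (lowest p becomes the index; members
  within 500 kb and r² > 0.001); two-stage calls: genome-wide significant iff
  the stage II effect has the same sign, stage II p ≤ 0.05 and combined
  p ≤ 5×10⁻⁸.
* **Gene prioritization** — protein-coding candidates within ±1 Mb of the
  lead; evidence across seven domains (variant annotation, eQTL, sQTL, pQTL,
  mQTL, haQTL, APP metabolism) aggregated with anti-inflation rules and
  scored as a weighted sum (replicated > single hits, brain > peripheral
  tissue); tier 1 requires a top score ≥ 4 and a ≥ 20 % relative gap to the
  runner-up.
* **Genetic risk score (GRS)** — GRS = n · Σwᵢdᵢ/Σwᵢ over risk-allele
  dosages with stage II log(OR) weights (APOE variants excluded), so a Cox
  hazard ratio on this scale is *per average risk allele*; per-cohort Cox
  fits adjusted for age, sex, four PCs and APOE ε4/ε2 counts; fixed- and
  random-effects (DerSimonian–Laird) HR meta-analysis; decile-contrast
  rescaling exp(log HR · (GRS₉ − GRS₁)); ΔC-index, continuous NRI and ΔIPA
  with bootstrap CIs.
* **Synthetic data** — generators for every input (per-study summary
  statistics under a shared true-effect model with proxy studies on the
  halved scale, block LD, evidence catalogs with designated causal genes,
  proportional-hazards cohorts), so the whole pipeline is exercisable and
  testable without any consortium data.

## Worked example

```python
import addgwas as a
from addgwas.synthetic import SimConfig, gen_sumstats, gen_ld
from addgwas.sumstats import apply_variant_qc, correct_proxy

cfg = SimConfig(n_variants=5000, n_causal_loci=8, seed=7)
stage1, stage2, truth = gen_sumstats(cfg)

clean = []
for s in stage1:
    s, report = apply_variant_qc(s)
    if s.design == "proxy":
        s = correct_proxy(s)
    clean.append(s)

m1 = a.meta_analyze(clean)
lam = a.genomic_lambda(m1["P"], m1["CHR"], m1["POS"])
m2 = a.meta_analyze([apply_variant_qc(s)[0] for s in stage2])
calls = a.call_loci(m1, m2, gen_ld(cfg, truth))
```

which prints, with the formatting of the example script:

```
lambda_GC = 1.031
10 clumps, 9 genome-wide significant
top locus: 3:98441205:G:A  OR = 1.196  log10 p = -462.7
decile-contrast HR (population): 1.93
```

λ ≈ 1.03 says the null variants are well calibrated (the slight excess is
the 8 causal loci); 9 of the 10 detected clumps pass the two-stage
significance rules; the top locus's combined log₁₀ p illustrates the
log-space p-value handling. The last line rescales a per-average-risk-allele
hazard ratio of 1.076 to the contrast between the first and ninth deciles of
a pooled GRS distribution (50.76 and 59.74): carrying a ninth-decile burden
roughly doubles the conversion hazard relative to a first-decile burden.

The same stages are available from the shell:

```sh
addgwas simulate --out fixture/ --seed 7
addgwas run --config fixture/pipeline_config.yaml
addgwas grs build --subset known --out grs_known.tsv
```

## Layout

```
src/addgwas/
  sumstats.py        # parsing, harmonization, QC, proxy correction, lambda
  meta.py            # IVW meta-analysis, heterogeneity, filters, stage combination
  loci.py            # regions, clumping, two-stage significance calls
  prioritization.py  # evidence aggregation, weighted scores, tiers
  grs.py             # risk scores, Cox fits, HR meta, deciles, indices
  synthetic.py       # generators for every input
  pipeline.py        # orchestration, validation, manifest
  cli.py             # `addgwas` command
  data/              # lead-variant catalog, exemplar prioritization weights
docs/methods.md      # models, assumptions, parameter choices, limitations
```
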