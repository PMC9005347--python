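# Methods

This note records the statistical models the package implements, the
conventions and defaults it pins down where several choices were defensible,
and what the synthetic-data generators do and do not emulate.

## Summary statistics, QC and proxy correction

A study is a table of per-variant logistic-regression results (log-OR β,
standard error, p, effect-allele frequency, imputation INFO, case/control
counts) on GRCh38 coordinates. Records are harmonized so the effect allele
is always the ALT allele (flip β → −β, EAF → 1−EAF otherwise); variants whose
effect allele matches neither REF nor ALT are reported and dropped rather
than guessed. Missing p-values are recomputed from β/SE under the two-sided
normal convention.

The per-variant QC removes, in this attribution order: duplicated variant
keys (all copies — a duplicated key cannot be disambiguated), records with
missing β/SE/p, |β| > 5, INFO < 0.3, and MAC × INFO < 20, where the minor
allele count is `MAC = floor(2·N·min(EAF, 1−EAF))` with N = cases + controls
(MAC has no universal definition; this one is documented and tested). All
comparisons are strict as phrased ("above 5", "below 0.3", "below 20"), so
boundary values survive. The *retained set* is independent of rule order;
the order matters only for attributing a multiply-violating record to a
single removal count, keeping the bookkeeping identity
`input = output + Σ removals` exact. Records lacking EAF or INFO cannot be
assessed by the frequency rules and pass them. Proxy-design studies get an
additional pre-filter (MAF > 0.01 %, MAC > 3, on by default) reflecting the
weaker information content of proxy phenotypes at rare variants.

Proxy (parental-history) studies estimate roughly half the case-control
effect, so β and SE are both multiplied by two; z-statistics and p-values
are unchanged. The direction (multiply, not divide) rescales half-strength
proxy effects *up* to the case-control scale; it is a convention choice that
downstream weights depend on (weights scale as 1/SE², so a corrected proxy
study contributes a quarter of the weight of an equally sized case-control
study), and it is guarded against double application.

Genomic inflation uses the median method: λ = median(χ²)/0.4549364 with
χ² = [Φ⁻¹(1−p/2)]², computed after removing the APOE region
(chr19:44,000,000–46,000,000, GRCh38) whose enormous signal would otherwise
dominate the median in dementia GWAS.

## Meta-analysis

Fixed-effect IVW: β = Σwβ/Σw, w = 1/se², se = (Σw)^(−1/2),
Q = Σw(β−β̄)² with het_p from χ² on k−1 df (defined as 1 for k = 1).
P-values are carried in log10 space (`log10_p = [log 2 + log Φ̄(|z|)]/log 10`)
because the strongest dementia signals sit far below the double-precision
underflow point; the linear-scale `P` column floors at 1e−323.

Post-meta filters: heterogeneity p < 5×10⁻⁸; analyzed case fraction < 20 %
of total cases; frequency amplitude (max − min EAF across studies) > 0.4;
absence from a designated reference study. The reference requirement is a
generalization of a dataset-specific rule (presence in the consortium's
TOPMed-imputed panel) to a configurable study flag. Every violated rule is
listed, and all thresholds are overridable. A single historically excluded
variant (chr6:32657066:G:A) is not hard-coded; the amplitude filter is the
general rule it instantiates.

Stage I and stage II combine by the same IVW rule. Because IVW is
associative, combining stage-level estimates is algebraically identical to
pooling the underlying studies; the test suite asserts this to 1e−12, which
also settles the question of which of the two routes is "the" combined
estimate.

## Locus definition

Regions: every variant with stage I p < 10⁻⁵ (strict) contributes the
2·window-long interval `[pos − window + 1, pos + window]` (window 500 kb);
intervals on a chromosome are merged, with exactly-adjacent (bookended)
intervals treated as mergeable, matching the default of the standard
interval-merge tool. Merged regions overlapping the APOE region are dropped
entirely.

Clumping is greedy: repeatedly take the unassigned qualifying variant with
the lowest p as index, and assign to its clump every unassigned qualifying
variant within 500 kb of the index (inclusive, index-to-variant distance)
and with r² > 0.001 (strict). Ties on p are broken by chromosome, position,
then alleles, making the partition deterministic; an independent brute-force
restatement of the rule is kept in the test suite and the two must agree
exactly on randomized instances.

Two-stage calls: a clump's signal is `genome_wide_significant` iff the lead
has the same effect direction in both stages, stage II p ≤ 0.05 and combined
p ≤ 5×10⁻⁸; `stage2_unsupported` records signals reaching 5×10⁻⁸ combined
without stage II support. Within a clump the reported lead is the member
with positive follow-up and the lowest combined p, falling back to the index
variant when no member has positive follow-up. A missing stage II estimate
defers classification rather than guessing.

## Gene prioritization

Candidates are protein-coding genes whose interval intersects lead ± 1 Mb.
A gene inside two loci's windows belongs to the locus with the nearer lead
(distance to the nearest gene edge, zero inside; ties to the lower-position
lead). Structurally complex loci (e.g. immunoglobulin gene clusters) can be
excluded by an exclusion list rather than code.

Evidence items carry (gene, domain, category, subcategory, unit, dataset).
Aggregation applies three anti-inflation rules before weighting:
(1) multiple correlated units (splice junctions, CpGs, peaks) of one gene in
one dataset collapse to one item; (2) a fine-mapped TWAS association
suppresses the same gene's plain TWAS associations in that domain; (3) a
gene with MetaMeth CpGs on both sides of the 75th percentile of the
blood–brain methylation-correlation distribution (computed over the catalog
at hand) keeps only the high-correlation CpGs. "Replicated" means the same
(gene, domain, subcategory) observed in ≥ 2 distinct datasets; the collapsed
item keeps its tissue category and the replication flag.

Scores are weighted sums. The weight table ships as an editable YAML
(`data/weights.yaml`) whose exemplar values satisfy the scheme's two
ordering constraints — replicated ≥ single and brain ≥ peripheral — and are
validated at load time; sites with a calibrated table can transcribe it
without code changes. Rescaled scores are 100·raw/max_score clipped to
[0, 100]; tier thresholds operate on the *raw* scale (the scale on which the
≥ 4 minimum is stated), with the rescaled interpretation available as a
flag.

Tiers, with S₁ the top raw score and rel(g) = (S₁−S_g)/S₁: the top gene is
tier 1 iff S₁ ≥ 4 and the runner-up has rel ≥ 0.20 (the runner-up alone
decides, since any further gene has larger rel); then genes with rel in
[0.20, 0.50] — both ends inclusive — are tier 2 and the rest unranked. A
runner-up within 20 % demotes the top gene and all such close genes to
tier 2; a top score below 4 makes the top gene tier 2, joined by its < 20 %
band. All-zero loci stay unranked. Relative differences are rounded to 12
decimals before comparison so that boundary cases are classified by value
rather than floating-point representation.

## Genetic risk score and progression analysis

GRS = n_avail · Σwᵢdᵢ/Σwᵢ over the model entries a subject has dosages for,
with dᵢ the risk-allele dosage and wᵢ = |stage II log(OR)| oriented to the
risk-increasing allele; multiplying by the number of variants makes the Cox
hazard ratio a per-average-risk-allele effect and the score invariant to a
positive rescaling of all weights. APOE variants never enter the model.
Missing variants renormalize per subject by default; an alternative imputes
2·RAF. The packaged lead-variant catalog (83 variants: 39 known-locus, 44
new-locus) provides default combined and partitioned models.

Cox models adjust for age, sex, the first four PCs and the APOE ε4/ε2 allele
counts (additive); with the AD outcome, conversions to other dementias are
censored at conversion. Fits use lifelines; non-convergence (including a
collinear added covariate) raises a fitting error with the library's
diagnostics rather than returning a degenerate estimate. Per-cohort log-HRs
combine by fixed-effect IVW and DerSimonian–Laird random effects
(τ² = max(0, (Q−df)/(Σw − Σw²/Σw)), I² = max(0, (Q−df)/Q)).

Decile cut-points use linear-interpolation quantiles (the common "type 7"
definition) so they are bit-reproducible; the decile-contrast HR is
exp(log HR · (GRS₉ − GRS₁)) evaluated at cut-point values, consistent with
the printed arithmetic it reproduces (1.076 → 1.93 and 1.056 → 1.63 for
cut-points 50.76 and 59.74).

Predictive indices at a fixed horizon: ΔC-index uses the truncated IPCW
concordance (scikit-survival); IPA = 1 − Brier/Brier_null with the IPCW
Brier score and a Kaplan–Meier null; the continuous NRI is an IPCW
adaptation (events by the horizon weighted 1/G(T−), survivors 1/G(horizon),
censored-before-horizon excluded; net up-classification among events plus
net down-classification among non-events). The exact censoring-adapted NRI
estimator is not uniquely standard; this one is documented, not claimed
identical to any particular prior implementation. Absolute risks come from
the Breslow baseline hazard. Bootstrap CIs resample subjects (stratified by
cohort), with the seed recorded in the report; the default of 1,000
resamples is configurable downward for interactive use.

## Synthetic data

The generators emulate the *statistical structure* the analysis assumes, at
desk scale. Defaults: 8 case-control + 2 proxy stage I studies and 4
stage II studies of 5,000 cases / 10,000 controls each; 20,000 variants on
four 100-Mb chromosomes in LD blocks of 10 with a single within-block
r² = 0.5; 20 causal loci with |log-OR| uniform on [0.04, 0.18] (the range of
the moderate dementia loci); cohorts of 2,000 with per-allele HR 1.076, 30 %
censoring and 10 years of follow-up.

Per-study effects are β̂ ~ N(β, se²) with the standard sampling
approximation se = 1/sqrt(2·N_eff·f(1−f)), N_eff = 4/(1/cases + 1/controls);
proxy studies draw around β/2. Sampling noise is correlated within LD blocks
(correlation sqrt(r²)) and block-mates of a causal variant carry the
LD-attenuated marginal effect sqrt(r²)·β, so clumping and calibration see
realistic local correlation. One global seed cascades to per-generator
streams via `SeedSequence([seed, stream_id])` (0 summary statistics,
1 evidence, 2 cohorts, 3 auxiliary), so each stage reproduces individually.

Cohort covariate effects are fixed documented defaults (log-hazard scale:
age 0.05/yr centered at 70; sex 0.2; 0.02 per PC; APOE ε4 log 2.0 per
allele, ε2 −0.35), values in the range reported for dementia progression;
the analysis only requires that they be nonzero and adjustable. Censoring is
an independent exponential dropout calibrated so that about `censor_rate` of
subjects are censored before an event, plus administrative end of follow-up;
`censor_rate = 1` degenerates to all-censored. Event times are exponential
given the linear predictor — proportional hazards holds by construction.

What the generators do **not** emulate: real haplotype structure and LD
decay (the block model has two r² levels only), allele-frequency spectra and
imputation-quality patterns of real panels, population stratification
(the PCs are pure noise), between-study heterogeneity of true effects,
non-proportional hazards, informative censoring, and the messy evidence
correlations of real QTL catalogs. Passing tests therefore demonstrate the
*algorithms* are correct under the stated model, not that the pipeline is
robust to every pathology of real consortium data.

## Problem sizes in the checks

The acceptance checks run at sizes chosen to make their statistics
informative while staying desk-scale: 100,000 independent null variants for
λ and p-uniformity (λ's ±0.02 band is then ~7 median absolute deviations);
1,000 randomized ≤ 50-variant instances for clump-oracle equivalence; 200
random instances for IVW exactness; 200 simulated cohorts of 20,000 for CI
coverage (binomial SE ≈ 1.5 points at 95 %, inside the ±3-point band); 20
loci for causal-gene recovery.

## Known limitations

* Liftover, strand-ambiguous palindromic-variant resolution and
  reference-frequency concordance checks are out of scope (a drop option and
  an off-by-default frequency filter exist).
* Conditional/joint analysis within loci is not implemented; one clump is
  one signal.
* The shipped prioritization weights are an exemplar satisfying the ordering
  constraints, not a calibrated table; tier calls on real data should use a
  site-calibrated weight file.
* Variant-level random-effects meta-analysis, sample-overlap correction and
  LD-score-regression intercepts are not provided.
* Competing risks are handled by censoring, not by a Fine–Gray model.
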