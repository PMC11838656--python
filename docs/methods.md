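# Methods

## Data model and assumptions

The pipeline assumes a cohort of n individuals with (i) biallelic SNP
dosages in {0,1,2}, (ii) a protein abundance matrix (individuals ×
aptamers) with an aptamer→gene map including chromosome and transcription
start site (TSS), and (iii) a covariate/trait table. A protein *A* is a
candidate **regulator** when some SNP near its encoding gene (a
*cis*-pQTL) explains part of its abundance; that SNP then serves as an
instrumental variable for the pairwise causal effect of *A* on any other
protein *B*. The instrumental logic requires the usual three conditions —
the SNP is associated with *A*, affects *B* only through *A*, and is
independent of confounders of the *A*–*B* relationship. *Cis* SNPs are
used precisely because their proximity to the encoding gene makes the
first condition strong and the second plausible; the controlled test below
guards against the main violation (direct pleiotropy of the SNP on *B*).

## Preprocessing

Per protein: Box-Cox transform at the maximum-likelihood λ (columns that
are not strictly positive are shifted by `1 − min` with the offset
recorded), then centering to mean 0 / SD 1. Globally: each protein's 99th
percentile is computed and the 99.5th percentile of those cutoffs is the
masking threshold; values strictly above it become missing. Percentiles
use linear interpolation between order statistics ("type 7") everywhere.
Proteins are then residualized on age and sex by least squares
(complete-case per protein; masked entries stay masked), and finally
**supernormalized**: ranks (ties → average) map through
`Φ⁻¹((r − 3/8)/(m + 1/4))` and are rescaled to unit sample variance. The
stage order — transform → center/scale → mask → adjust → supernormalize —
is fixed and recorded in the parameter sidecar. Missing values are
excluded pairwise downstream, never imputed.

## Instrument discovery

For each protein, every SNP within a 300 kb window centered on the gene's
TSS is tested by simple linear regression on additive dosage. The
window-level p-value is Bonferroni-adjusted for the number of SNPs in the
window (`min(1, m_window × min p)`), and q-values across proteins come
from the Storey–Tibshirani estimator: π₀(λ) = #{p > λ}/(m(1−λ)) over
λ ∈ {0.05,…,0.95}, smoothed by a cubic spline and evaluated at λ = 0.95;
q-values are the usual step-down minimum. Proteins with q ≤ 0.05 carry a
valid instrument; the lead pSNP is the smallest-raw-p SNP in the window.
The TSS anchor reconciles the "300 kb spanning the gene" window with the
"±150 kb around the lead variant" window used later; it is a configuration
knob, not a claim about gene-body handling.

Independent *cis*-SNP sets (for variance decomposition) come from forward
conditional selection within ±150 kb of the lead variant: at each step the
candidate with the smallest Wald p in the joint model with the selected
SNPs is added if p < 0.00763 and its dosage r² with every selected SNP is
< 0.9. The p threshold is the published value corresponding to FDR < 5%
in this selection context.

## Pairwise causal tests

Genotype is treated as categorical with k = number of observed dosage
levels (2 or 3); levels with fewer than 2 carriers are merged into the
nearest level so the Beta degrees of freedom stay valid. All tests use
complete cases per pair, re-standardizing *B* (MLE variance) on those
cases.

* **Secondary linkage (P2).** With per-category means μ̂ⱼ of standardized
  *B* and shares nⱼ/n, the explained fraction is ρ² = Σⱼ (nⱼ/n) μ̂ⱼ² and
  `llr2 = −(n/2) ln(1−ρ²)`. Under the null (no E–B association),
  ρ² ~ Beta((k−1)/2, (n−k)/2), giving an exact p-value.
* **Controlled (P5).** Nested models B ~ category means vs B ~ category
  means + c·A give `llr5 = (n/2) ln(RSS₀/RSS₁) = −(n/2) ln(1−r²_partial)`
  where r_partial is the correlation of the genotype-demeaned residuals of
  A and B; under the null r²_partial ~ Beta(1/2, (n−k−1)/2).

Both null laws were verified against 10⁵-permutation p-values at n = 30
(agreement within Monte-Carlo error plus a 10% relative allowance for the
O(1/n) gap between the conditional permutation null and the unconditional
law) and against KS uniformity on 10⁴ null replicates at n = 500.

LLRs are capped at 700 nats (beyond which the posterior is 1 to machine
precision).

### LLR → posterior (local FDR)

Per regulator row (one A against all B), the posterior of the alternative
is `1 − π̂₀ f₀(llr)/f̂(llr)`, clipped to [0,1] and made monotone
non-decreasing in llr by isotonic regression. f₀ is the null density
induced by the Beta law (evaluated as exact null mass per bin); f̂ is a
histogram of the row's LLRs over equal-width bins on [0, max llr] with a
one-pseudo-count floor. Two numerical choices matter and were validated
on null rows:

* the bin count is ~√(row length), capped at 200 — a fixed 200-bin grid
  leaves ~2 points per bin on short rows and the Poisson noise of the
  density ratio inflates null posteriors;
* π̂₀ uses Storey's fixed-λ estimator at λ = 0.5 (`min(1, #{p>0.5}/(0.5m))`)
  rather than the spline smoother: the smoother's downward noise on short
  rows translates directly into inflated null posteriors. The fixed-λ
  estimator is conservative (≤ upward-biased) under sparse alternatives.

Rows with fewer than 100 testable pairs are pooled across rows and fitted
on the common null scale s = −ln p, where the null is exactly Exp(1)
regardless of each pair's (n, k); the same histogram + isotonic
construction applies. Null calibration: mean null-row posterior ≈ 0.03–0.04.

### Edge selection

`PP = P2 × P5` for every ordered pair (A instrumented, B any other
aptamer not encoded by A's own gene — same-gene aptamers share the cis
region, so the exclusion-restriction assumption fails by construction).
The global Bayesian FDR of a candidate set is 1 − mean(PP); edges are
selected by sorting PP descending and keeping the largest prefix whose
running FDR stays at or below the target. The FDR is computed jointly over
all scored pairs (not per regulator). On 100 fully null cohorts the
realized false-edge rate at nominal 1/5/10% stayed within nominal + 2 SE.

## Network assembly

Regulators with ≥ 10 selected targets (default) form subnetworks; smaller
regulators keep their role as targets of others. Genes measured by several
aptamers keep the aptamer with the most targets (ties: larger summed PP,
then lexicographic id). Regulators whose lead pSNPs coincide or are in LD
(dosage r² ≥ 0.5, transitive closure) form an LD block; within a block a
regulator is independent only when the target-set intersection/union ratio
I is < 0.6 against every other member (I = 0.6 exactly falls to collapsed
— the boundary is left open by the published rule, and collapsing is the
conservative reading). Non-independent members merge into one unresolved
subnetwork labelled by the joined gene names; mutual-target regulator
pairs are flagged unresolved wherever they occur, and unresolved networks
are excluded from variance-explained analyses.

The **eigenprotein** is PC1 of the standardized member abundances
(members = regulator + targets; rows with any missing member value are
dropped from the decomposition and carry a missing score). It is kept when
PC1 explains > 15% of the member variance, and its sign is oriented so the
score correlates positively with the mean member profile — a data
property, so scores are reproducible across linear-algebra backends.

## Hierarchy and topology

Regulator-regulator edges are made acyclic greedily: edges in decreasing
PP (ties lexicographic by source then target) are kept unless they close a
directed cycle; kept + removed = input on every run. Roots are regulators
without incoming kept edges; levels are shortest-path distances from any
root (isolated regulators are roots). Removed edges can be reintroduced
and classified by level jump: 0 same-level, +1 one-below, −1 one-above,
≤ −2 two-or-more-above, and ≥ +2 reported as a distinct long-forward class
(the published four-class legend leaves long forward jumps undefined).
Transitive reduction (unique for a DAG) and exact motif counts
(feed-forward loops, 2-node and 3-node feedback loops, by enumeration) are
oracle-tested against brute force on small random graphs. Connected
components are weakly connected throughout; hub robustness deletes the
top-k out-degree hubs (ties lexicographic) and reports the largest
component relative to the original node count.

## Evaluation

**Subsampling robustness.** The full-sample network at a fixed global FDR
is the ground truth, flattened to binary labels over the ordered pairs it
scored. Each subsample is fully re-inferred — preprocessing,
supernormalization, instruments and local-FDR fits are refit on the
subsample, not merely re-thresholded — and its per-pair PP (0 where the
pair was not scored) is compared to the labels by ROC AUC and
precision-recall. Self-agreement is exact up to posterior ties (binned
posteriors tie at the selection threshold, so the full-sample AUC can fall
marginally below 1).

**PPI overlap.** Network edges collapse to unordered gene pairs (each
pair counted once even when both directions exist). Overlap with a
HIPPIE-style reference at each confidence threshold (strict >) is compared
to random networks with the same number of distinct unordered pairs drawn
uniformly from the measured-gene universe, without self-pairs or
duplicates; z = (observed − mean)/SD over 10 draws, one-sided p = 1 − Φ(z).

**Variance explained.** Adjusted R² of a protein on its independent
cis-SNPs (0 when it has none, by convention); the parental decomposition
reports adjR²(parents' + own SNPs) − adjR²(own), with overlapping SNPs
deduplicated. Across synthetic cohorts the number of instrumented parents
correlates positively (Spearman) with the parental-cis variance share.

## Trait associations and ranking

Features (regulator abundance or eigenprotein score, standardized to unit
SD) are associated with quantitative traits by OLS, prevalent binary
traits by logistic regression, and incident outcomes by Cox proportional
hazards, always adjusting for age and sex. Cox refuses when no events are
observed; logistic separation falls back to an L2-penalized fit, is
flagged, and reports p = 1 (conservative — no closed-form Wald p exists
for the ridge fit). Regulator significance is BH FDR < 0.05 per trait
(trait-wise families, switchable to pooled); eigenprotein significance is
Bonferroni at 0.05 / n_subnetworks. The per-trait code of a subnetwork is
(regulator flag) + (eigenprotein flag) ∈ {0,1,2}; a missing eigenprotein
contributes 0. The rank score is the sum over the six traits and
"top-ranked" means score ≥ 7.

## Synthetic cohort generator

The generator plants exactly the structure the analysis assumes, with
per-component RNG streams derived from one master seed (stage-level
reproducibility; identical seeds give bitwise-identical outputs).

* **Genotypes.** Dosages ~ Binomial(2, maf) per SNP (HWE), maf uniform on
  (0.05, 0.5] by default. Genome layout: one synthetic chromosome, genes
  1 Mb apart (cis windows never overlap unless a fixture co-locates genes
  on purpose), `snps_per_gene` SNPs per gene inside ±100 kb of the TSS;
  for regulator genes the first is the causal cis SNP.
* **Truth network.** A random topological order; regulators occupy
  positions with at least `min_targets` downstream proteins; out-degrees
  follow a truncated Pareto law (tail exponent 2 by default → heavy tail,
  max out-degree ≫ median). Chance-closed feed-forward shortcuts are
  stripped, then the stated fraction of open x→y→z paths is closed by
  adding x→z, so `ffl_fraction = 0` guarantees zero FFLs and the FFL
  content is controlled, not incidental. Edge effects are uniform on
  ±(0.15, 0.35) by default — the magnitude distribution of
  protein→protein effects is not empirically constrained, so it is an
  explicit configuration parameter rather than a fixed claim. Cis variance
  fractions are Beta draws rescaled to mean 0.074 (max 0.5 by default, up
  to 0.84 supported); confounder loadings are sparse (density 0.3,
  magnitudes 0.1–0.3, random sign) on 5 global latent Gaussian factors
  never exposed to inference. Per protein, cis + Σb² + Σc² is capped at
  0.85 by rescaling (b, c) jointly, keeping ≥ 0.15 noise variance.
* **Proteins.** Generated in topological order as
  `z = √(cis)·std(dosage) + Σ b·parent + Σ c·latent + ε` with residual SD
  filling the unit-variance budget, so realized cis R² matches the planted
  fraction up to sampling noise. The cohort default maps z through
  `exp(0.5 z + 8)` — positive, right-skewed, assay-like units; the map is
  monotone, so the rank-based pipeline is unaffected while Box-Cox has
  something real to do (λ̂ ≈ 0 recovers the log scale).
* **Traits.** Six traits (2 quantitative, 2 prevalent, 2 incident by
  default), each driven by the standardized mean profile of one planted
  subnetwork plus age/sex confounding (0.2·age_z + 0.15·sex on the linear
  predictor). Quantitative: linear + unit Gaussian noise. Prevalent:
  logistic with intercept −1.8 (≈15% base prevalence). Incident:
  exponential event times with log-hazard linear in the signal, an
  administrative horizon of 12 years and baseline rate set for ~15%
  cumulative events; `censoring_rate` is the probability of random loss to
  follow-up truncating the record before any event (selection independent
  of covariates, so hazard estimates remain consistent — verified by
  parameter recovery); `censoring_rate = 1` yields exactly zero events.

**What the generator does not emulate:** assay plate/dilution artifacts
and batch structure, LD beyond the planted cis blocks (background SNPs are
independent), multi-ancestry structure, gene-body length effects on cis
windows, proteins driven by age/sex (only traits are), and non-Gaussian
noise. Passing tests therefore demonstrate correctness of the machinery
and calibration under the stated model, not performance on real serum
proteomics.

## Problem sizes used in the shipped analyses

The headline robustness benchmark (scripts/acceptance.py and the matching
test) runs at n = 5,000 individuals and 300 proteins with ~50 instrumented
regulators — the cohort size of the motivating design at reduced protein
count, which keeps the full run around a minute on one CPU while leaving
~15,000 scored pairs per run. Unit and property suites use smaller
configurations (n = 300–2,000, 20–100 proteins) chosen so each suite
finishes in seconds while Monte-Carlo tolerances stay meaningful.

## Known limitations

* The controlled test conditions on a single lead SNP; multi-SNP
  instruments per pair are out of scope.
* Posteriors are bin-valued, so near the selection threshold many pairs
  tie; threshold-adjacent membership can differ across platforms in those
  tied groups (selection size and FDR are unaffected).
* The pooled local-FDR fallback borrows strength across regulators and
  can shrink a genuinely dense row's posteriors; rows of ≥ 100 pairs are
  always fitted individually.
* Logistic separation reports a penalized estimate with p = 1 rather than
  an exact conditional test.
* The variance-budget rescaling in the generator means extreme requested
  configurations (many strong parents plus strong cis) silently attenuate
  edge effects; the truth object always records the effective values.
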