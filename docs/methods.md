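# Methods

## The condFDR/conjFDR model

The analysis treats each variant's pair of two-sided GWAS p-values
(p1, p2) as draws from a two-group-style mixture: most variants are null
for a given trait, a small fraction carry signal, and a smaller fraction
carry signal for both traits. condFDR(1|2) for variant i is estimated by
the conservative plug-in

    condFDR(1|2)_i = min(1, p1_i / F̂(p1_i | p2 ≤ p2_i)),   π₀ fixed at 1.

Fixing π₀ = 1 overstates the null fraction and makes each directional
condFDR conservative; the alternative (estimating π₀ per stratum) buys
power at the cost of stability and is deliberately not done. conjFDR is
the elementwise maximum of the two directional condFDRs, and selection
uses a strict inequality at the threshold (default 0.01; the threshold
is a parameter since reasonable analyses also use 0.05).

Two evaluation routes exist and are both part of the public API:

* **Exact direct counting** (`cond_fdr(..., cdf=None)`) — F̂ evaluated
  at each variant's own (p1, p2) by 2-D dominance counting with exact
  `≤` tie handling (Fenwick tree over p1 ranks swept in p2 order,
  O(n log n)). This is the defining formula; the test suite checks it
  against a literal O(n²) counter to 1e-12 at 10⁴ variants.
* **Stratified lookup** (`build_conditional_cdf` + `cond_fdr`) — F̂
  tabulated on a −log10 grid (step 0.1 in both coordinates, from 0 to
  the data maximum) of cumulative trait-2 strata, averaged over random
  LD-pruning iterations, interpolated bilinearly per variant. This is
  the pipeline default. Counting within a stratum is nested, so each
  column of the table is automatically monotone in p1; a cummax
  regularization pass is still applied and is a no-op on
  already-monotone columns. Strata whose denominator is empty in every
  pruning iteration are marked invalid, and variant coordinates are
  clipped to the valid range (a variant beyond all valid strata would
  receive condFDR 1 and a flag).

Pruning (one variant drawn uniformly per LD block, r² > 0.1, 100
iterations by default) enters the CDF estimate only; the fitted lookup
is then applied to every variant, so pruned-out variants still receive
condFDR values. Rationale: pruning removes the LD-induced inflation of
the empirical CDF, while discovery should still consider all variants.
Without pruning the unadjusted empirical CDF over-counts correlated
signal variants; we measured a visibly worse conjunction false-discovery
proportion for the unpruned exact route than for the pruned lookup on
LD-structured simulations.

The lookup agrees with exact counting closely where it matters: median
relative difference under 2% without pruning, and in the discovery
region (condFDR < 0.2) its deviations are conservative (lookup ≥ exact
up to interpolation error ≤ 0.02). Large deviations occur only in
near-empty deep strata (p2 below ~1e-9 with a handful of members) where
both estimates are unstable and the lookup errs toward 1.

### Known limitation: conjunction calibration

Each directional condFDR is conservative (simulated empirical FDR of
condFDR<0.05 calls ≈ 0.04 under the null mixture). The conjunction
estimator max(condFDR(1|2), condFDR(2|1)) is the field's standard
conservative combination but is *not* a union bound: the probability of
being null for either trait can exceed the larger of the two
single-trait posteriors. On the default pleiotropic simulation the
empirical conjunction false-discovery proportion at conjFDR < 0.05 is
≈ 0.084 rather than ≤ 0.05 — mildly anti-conservative, concentrated in
single-trait variants whose other-trait p-value is moderately small by
chance. Clumping does not repair this (false calls tend to be
singletons while true calls collapse into loci). Users who need strict
conjunction FDR control should select at a stricter threshold; at
conjFDR < 0.01 the measured proportion is ≈ 0.017.

## Conditional Q–Q curves and the enrichment summary

For each stratum cutoff t ∈ {0, 1, 2, 3} in −log10 p2, variants with
−log10 p2 ≥ t are ranked by p1 and rank i maps to the nominal quantile
−log10(i/(m+1)). Curves are evaluated on a common nominal grid,
averaged over pruning iterations, and truncated at the stratum's own
nominal range. The scalar enrichment summary per stratum is the mean
vertical gap to the all-SNP curve over the shared nominal grid,
truncated at the rank-10 quantile of the smallest stratum: the top
order statistics of a small stratum fluctuate far too much (the
single most extreme p-value moves the curve by ±0.5 on the log scale)
to average over, while ranks ≥ 10 are stable. Under independence the
summaries sit within ±0.05 of zero at 10⁵ variants; under the default
pleiotropic mixture they increase strictly across strata. Strata with
fewer than 100 members (after pruning) are omitted with a warning.

## Harmonization

Merging is on variant id, keeping the primary trait's allele
orientation. A secondary record whose alleles are (a2, a1) has its z
sign flipped; strand complements are complemented before matching;
records that match neither way are dropped and counted. A/T and C/G
pairs are strand-ambiguous — without allele frequencies the orientation
cannot be resolved — and are dropped by default. p = 0 inputs are
clamped to the smallest subnormal double and flagged, since downstream
log transforms must not produce infinities. When both z and p columns
are supplied they are cross-checked (5% relative tolerance, flagged,
configurable); the p column stays authoritative because the FDR
machinery is p-based. Positions are 1-based with closed intervals; the
optional MHC exclusion window is chr6:25,000,000–35,000,000 and is off
by default. Genomic-control correction (λ = median(z²)/0.4549, z/√λ) is
optional and off by default; λ < 1 is never applied unless forced.

## LD representation

LD arrives as a pairwise r² table (PLINK `.ld`-style), not genotypes.
Blocks are connected components of the graph with edges strictly above
the r² threshold (single linkage), matching the transitive behaviour of
standard clumping tools; the component labelling is deterministic
(ordered by first appearance in the sorted variant list). Clumping of
significant variants computes components among significant variants
only; the lead is the minimal-conjFDR member, ties broken toward larger
|z1| then smaller position (the tie-break is this package's rule — the
field convention says only "most significant"). Loci are numbered in
genomic order of their leads.

## Mendelian randomization

Ratio estimates θ_j = β_out/β_exp with first-order SE se_out/|β_exp|
(exposure uncertainty ignored — the strong-instrument approximation,
consistent with reporting single-instrument Wald estimates without
propagated exposure error). IVW is fixed-effect (no overdispersion
scaling), appropriate for the small instrument counts (≤ 6) this kind
of analysis typically has; a single instrument short-circuits to the
Wald ratio exactly. The weighted median interpolates the ordered θ at
cumulative weight 1/2 with inverse-variance weights; its SE is a seeded
parametric bootstrap (default 1000 draws resampling both β_exp and
β_out from their normal errors) because no closed form is standard.
OR = exp(β) with 95% CI exp(β ± 1.959964·se); `summarize_or_ci` inverts
published OR/CI triples assuming a symmetric normal CI on the log scale.

## Differential expression

Genes are z-scaled across *all* samples (not within group — the
within-group variant would erase mean shifts); entries strictly beyond
3 SD are masked per entry; Welch's unequal-variance t-test is the
default (a pooled-variance flag exists) because group variances cannot
be assumed equal after outlier masking; BH correction runs across the
tested gene subset with significance at q < 0.05. Genes left with
fewer than two usable values in a group are excluded and flagged.
Annotation filters: CADD strictly above 12.37 flags potential
pathogenicity; RegulomeDB categories are ordered 1a < 1b < … < 1f <
2a < … < 7 and the regulatory flag fires at or better than the
configured category (default 1f); unknown tokens are flagged unparsed.
The gene-set test is a one-sided hypergeometric tail on the overlap
with each user-supplied GMT set, intersected with the declared
universe, BH-corrected across sets.

## Synthetic data: what it emulates and what it does not

`simulate_sumstats_pair` draws one mixture component per LD block from
π = (0.90, 0.04, 0.04, 0.02) — null, trait-1-only, trait-2-only,
pleiotropic — with effect SD σ = 3 on the z scale and pleiotropic
effect correlation ρ_b = 0.5. Observed z-scores add unit-variance noise
with cross-trait correlation ρ_ns (0 by default; positive values model
overlapping GWAS samples, and the generator demonstrably induces
cross-trait z correlation ≈ ρ_ns for audit tests). Within-block
correlation comes from a shared per-block noise factor with weight
√0.8, giving null z correlation 0.8, the value emitted as R2 in the LD
table (a chain per block), so `ld_blocks` on the emitted table recovers
the generating partition exactly. Block sizes are uniform on 1–5;
default size 10⁵ variants, the scale at which the calibration
properties are stated. Alleles are assigned with random swaps and
strand flips (recorded in the truth table) so harmonization is
genuinely exercised.

Not emulated: realistic human LD maps and allele-frequency spectra,
minor-allele-dependent power, effect-size–frequency coupling,
population stratification, or functional annotation structure. Passing
calibration here shows the estimators behave as designed under the
stated mixture model, not that real-data discoveries at a given
threshold carry the same error rate.

`simulate_mr_instruments` draws β_exp ~ N(0.3, 0.1²) resampled to
|β_exp| > 0.05, β_out = 0.2·β_exp + α + N(0, 0.05²) with α an optional
pleiotropy term. `simulate_expression` mirrors a 50-case/66-control
blood-expression design with N(0,1) baseline, 10% of genes shifted by
1.5 SD in cases, and optional injected outliers of magnitude 4–8 SD.

## Numerical choices

* z→p uses the log survival function; the linear-scale value underflows
  below ~1e-324 (|z| ≳ 38.5) and is clamped there, while
  `log10p_from_z` remains exact for any finite z and is what plots use.
* Ties in p are compared with exact `≤` everywhere; no jitter.
* All generators and pruning draws use `numpy.random.default_rng`
  seeded from documented (seed, iteration) pairs; reruns are
  byte-identical, and the pipeline echoes its full configuration into
  the run log.
* −log10 conjFDR is capped at 300 in Manhattan-plot data.
* Problem sizes in the test and acceptance suites (10⁵-variant
  simulations; 200/60/50/30 replicates for the calibration, audit and
  recovery runs) are the package's chosen study conditions; quantities
  are reported with the n they were computed at.
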