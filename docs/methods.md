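# Methods

This note documents the statistical model behind `gradsel`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a user should know before
trusting a scan.

## The design: nested phenotypic gradient pairs

The scan assumes one cohort, one quantitative trait per scan, and genotypes
that are phased and imputed upstream (the XP-EHH half of the method requires
phase; the F_ST half does not). Samples with a missing trait value are dropped
per trait. The ranking is by raw phenotype, descending, with ties broken by
ascending sample id so the whole construction is a pure function of its
inputs.

Three nested high/low pairs are cut from the ranking:

| level | high side | low side |
|---|---|---|
| 1 | top ⌈N/2⌉ | bottom ⌊N/2⌋ |
| 2 | top 75 | bottom 75 |
| 3 | top 45 | bottom 45 |

For odd N the extra individual goes to the high side; this choice is
arbitrary, documented, and immaterial because levels 2 and 3 dominate the
analysis. Levels 2 and 3 are cut from the full ranking, which is identical to
cutting them from the previous level's pools. Pools smaller than 40
individuals trigger a warning (not an error): below that size the
differentiation statistics are too noisy to rank reliably.

The default sizes (75, 45) suit cohorts of roughly 200–300 individuals; both
are configurable (`--pair-sizes`).

## Statistics

**F_ST.** The default estimator is Wright/Nei's
`(H_T − H_S)/H_T` with unweighted pooling of the two pool frequencies,
computed per SNP. It is evaluated through the algebraically equivalent form
`(p₁−p₂)²/2 / H_T`, which is numerically stable near fixation. Markers
monomorphic in both pools get F_ST = 0 (not NaN) so the genome-wide ranking is
total. The Weir–Cockerham two-population θ̂ is available as an alternative
(`fst_estimator: weir_cockerham`); it is unbiased under the null but can be
negative and is deliberately not clamped. With equal pool sizes the two
estimators rank planted differentials almost identically (rank correlation
> 0.9 in the test suite).

**EHH.** The *site* form is used: at the span from the core SNP to a flanking
SNP, all haplotypes in a pool are partitioned by their allele string over the
span, and EHH = Σ_g C(c_g,2) / C(n,2) — the probability that two haplotypes
drawn without replacement are identical over the span. At the core this equals
the core-site homozygosity. Site-EHH (rather than core-allele-conditioned EHH)
is the natural substrate for a two-population comparison because it needs no
choice of ancestral/derived allele and is invariant to global allele
relabeling.

**iHH.** EHH is integrated against physical distance (bp) with the trapezoid
rule, separately to the left and right of the core, walking marker by marker
until EHH drops below a cutoff (default 0.05, `--ehh-cutoff`, the common field
convention) and linearly interpolating to the exact crossing. If the
chromosome edge arrives first, the side is integrated to the edge and flagged
`chromosome_edge`; edge-flagged scores are kept by default and can be dropped
with a stricter option (`drop_edge`). If even the core-site homozygosity is
below the cutoff the statistic is degenerate: iHH = 0, flagged. Distances are
physical bp — on a 60K chip there is no usable genetic map — and units cancel
in the XP-EHH ratio. No maximum-gap penalty is applied by default (chip
spacing is fairly regular); `ihh` is linear in distance, so doubling all
inter-marker gaps exactly doubles it.

**XP-EHH.** `ln(iHH_low / iHH_high)`, used unstandardized: the three pair
levels deliberately differ in sample size and allele-frequency composition,
and standardizing within frequency bins would destroy the cross-level
comparability the gradient filter relies on. The sign convention is fixed so
that negative scores indicate the extended homozygous haplotype in the
high-phenotype pool. Undefined scores (either iHH = 0) are recorded as missing
and excluded from ranking. `xpehh(A,B) = −xpehh(B,A)` exactly.

A caveat at partial sweeps: when the selected allele sits at intermediate
frequency in the high pool, the high pool's *site* homozygosity at the core is
lower than the low pool's (which is nearly fixed for the alternative allele),
and the sign of XP-EHH at the core SNP can go either way depending on whether
the carriers' long shared haplotype outweighs that site term in the integral.
In the recovery experiments most — but not all — XP-EHH hits adjacent to a
trait-increasing QTL point "high".

**Empirical p-values.** p = rank/N over all scored markers, rank 1 for the
most extreme score (upper tail for F_ST; absolute value for XP-EHH, since both
signs are biologically meaningful). Ties share the worst rank of their group,
making p conservative; p is invariant under any strictly monotone transform of
the scores. Significance is strict: p < 0.01 (`--p-threshold`). With 37,061
markers this flags exactly 370 per scan.

**Signature calling.** By default significance is anchored in the level-3
(most contrasted) pair, and the gradient filter is applied to the raw score
triple: strict `s₁ < s₂ < s₃` for F_ST, strict rise in magnitude with one
shared sign for XP-EHH. Equal consecutive scores fail (ties are not a
"gradient"). An `all` mode instead requires p < α at every level. Method lists
(F_ST vs XP-EHH) are kept separate throughout. Anchoring at level 3 was chosen
because the most contrasted pair carries the strongest signal and yields the
interpretable "~1% of markers" per-pair outlier set; the choice is exposed as
`--significance-mode`.

### What the gradient filter does and does not control

The filter is a *selection*-consistency check, not a calibrated specificity
control. Under a pure null (trait independent of genotype) the three levels
are **not** exchangeable: per-SNP F_ST sampling variance grows as pool size
shrinks (E[F̂_ST] ≈ 1/(4n) per side, so level 3 > level 2 > level 1), and
conditioning on the level-3 upper tail makes `s₃` the largest of the triple
almost surely. Measured on 20 null cohorts at chip scale (233 individuals,
37,061 markers), ~92% of level-3-significant loci pass the strict chain, so
the null yield is ~340 of ~370 significant loci per scan — the filter removes
only a minority of pure-noise outliers. (For genuinely exchangeable,
independently scored levels the strict-chain probability is 1/6, and the unit
suite verifies that combinatorial fact on iid triples.) The filter's value is
in *real* data, where it demands the signal strengthen with phenotypic
contrast and suppresses loci whose outlier status comes from cohort structure
shared across levels; interpretation of absolute signature counts should keep
the null behavior in mind.

## Quality control

Filters run in a fixed order — SNP missingness < 0.05, sample call rate
> 0.90, Hardy–Weinberg p > 1e-6, MAF > 0.05, autosomal markers with known
positions — each stage counted separately; MAF and HWE are computed on the
samples surviving the call-rate filter, and re-applying QC to its own output
removes nothing. Inequalities are strict as written. The HWE test is the exact
conditional test (sum of probabilities of heterozygote counts no more probable
than observed, given the allele counts), computed in log space; a χ² variant
is available. The HWE threshold default is 1e-6 (`hwe_min_p`), configurable.
Diagnostics: the MAF spectrum over right-closed bins covering (0, 0.5], and
mean r² per 1 kb distance bin for LD decay.

## The synthetic cohort generator

Each of the 2N gametes is a first-order mosaic over K founder haplotypes:
start on a uniform founder; between adjacent markers at distance d bp, switch
to a uniformly drawn founder with probability 1 − exp(−switch_rate·d). Founder
alleles are independent Bernoulli draws with per-site frequency uniform on
(0.1, 0.9). Each QTL is pinned to a marker whose allele is forced to 1 exactly
on a chosen subset of carrier founders, so the QTL allele tags those founders'
local haplotype background; the trait is y = Σ β·dosage + N(0, noise_sd²).

Defaults model a 233-animal cohort on one 120 Mb chromosome with 2,000 markers
(60 kb spacing, the density of a ~60K chip genome-wide), K = 8 founders,
switch rate 1e-6/bp (≈1 Mb haplotype blocks, so r² decays over a few hundred
kb as on real chip data), one QTL of effect 1.5 trait SD on one carrier
founder (allele frequency ≈ 1/8, safely above the MAF filter), and noise SD 1.
Everything flows from a single seeded generator, so cohorts are bit-identical
under a fixed seed. The realized single-locus heritability matches its
analytic value β²·2pq / (β²·2pq + σ²) within Monte-Carlo error.

What it does **not** emulate: multi-generation drift and mutation, pedigree
structure, genotyping error, ascertainment bias of chip SNPs, multiple
chromosomes, polygenic trait architecture, or linkage between QTL. Passing
recovery tests therefore demonstrate that the pipeline detects a
haplotype-borne additive signal of the stated size under realistic LD — not
that it is calibrated for any particular real population's demography.

## Problem sizes used in the checks

The null calibration uses 20 cohorts of 233 individuals × 37,061 markers
(F_ST arm only, which is what the calibration concerns). The recovery study
uses 20 cohorts of 240 individuals × 2,000 markers over 120 Mb with pairs
(half, 75, 45) and a ±500 kb recovery radius; both finish in a few minutes on
one CPU. The negation-symmetry check uses one such cohort: negating the trait
swaps the high/low pools exactly (even N, continuous trait), so the signature
set must be identical with XP-EHH scores negated and directions flipped, while
F_ST is unchanged.

## Degenerate inputs and tie-breaks

- Markers with zero calls in a pool get NaN frequency and are excluded from
  that level's ranking; monomorphic-in-both markers get F_ST 0.
- Ranking ties (phenotype or scores) are always resolved deterministically
  (ascending id; worst rank), never randomly.
- `empirical_p` errors when every score is missing; QC errors when a filter
  would remove every sample or every marker.
- Haplotype containers reject missing data outright — phase upstream.
- Region merging treats bookended windows (adjacent bp) as one region; merging
  is idempotent.

## Known limitations

- Fixed loci are invisible by construction: the MAF filter removes them, and
  a completed sweep leaves no within-cohort differentiation to detect.
- Unstandardized XP-EHH scores are comparable across levels but not across
  cohorts or chips with different marker densities.
- Empirical rank p-values are relative outlier measures, not error-controlled
  probabilities; the ~1% flagged per scan is by construction.
- The gradient filter's null behavior (above) means signature counts are not
  false-discovery-controlled; treat calls as candidates for annotation and
  follow-up, not as significance statements.
- PLINK text input is supported for QC/F_ST workflows, but the XP-EHH arm
  requires phased VCF input.
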