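# Methods

## Allelic calling and sister-clone classification

A clone's call depends only on the allelic intensity ratio: monoallelic iff
`max(a,b)/min(a,b)` strictly exceeds `mono_fold_threshold` (default 2.33,
the conventional ~70:30 allelic skew boundary). The max/min form makes the
A/B symmetry exact by construction. A ratio of exactly the threshold is
biallelic. One allele at zero with the other positive is the strongest
monoallelic evidence and is called monoallelic; both at zero leaves the
ratio undefined (no-call). Negative intensities are rejected as invalid
input rather than clamped — they indicate an upstream processing error.
The threshold is applied to the supplied intensities as-is; the package does
not transform or renormalise them.

Classification across sister clones of one cell source is a function of the
multiset of calls (clone order is irrelevant):

| status | condition |
|---|---|
| StMA | ≥1 monoallelic clone and ≥1 informative sister with a different call |
| BA | all informative clones biallelic, and ≥ `min_clones_for_ba` (default 3) of them |
| consistent-MA | ≥2 informative clones, all the same monoallelic call |
| unclassified | anything else (incl. a single clone, or two biallelic clones) |

The categories are mutually exclusive. `min_clones_for_ba` reflects designs
with three clonal lines per source; it is configurable for synthetic
scenarios with other clone counts. Merging across cell sources is by union;
a gene StMA in one source and BA in another goes to the StMA list only,
because demonstrated allelic variability anywhere overrides biallelic
behaviour elsewhere (the conflict is logged — the choice is this package's,
as the upstream convention is not documented anywhere authoritative).

## CNV regions

Coordinates are 0-based half-open everywhere; BED input is taken as-is.
Overlap means sharing ≥1 base, so abutting intervals (`end == start`) never
merge — the conservative reading of "overlapping", and the half-open
arithmetic keeps it exact. Merging is a sort-then-sweep over (chrom, start):
output *maximal* regions are disjoint, contain every input, and their union
equals the input union; the operation is idempotent and order-independent
(both property-tested against an O(n²) pairwise-closure oracle).

*Minimal* (critical) regions are defined per overlap cluster as the maximal
sub-intervals covered by ≥2 member CNVs, with single-member clusters passed
through unchanged; the construction is pinned by a per-base
coverage-counting oracle test. The member count of a minimal region counts
cluster members overlapping the emitted sub-interval.

The >100 kb size selection (strictly greater) applies to control datasets
only, before merging — population-survey control sets are dominated by very
short calls that would otherwise deflate control gene content. Disease sets
pass unfiltered.

Gene mapping attaches a symbol to a region on ≥1 bp overlap of any of its
isoform intervals, once per region; dataset-level gene sets are unions over
regions, so a gene spanning two regions counts once in totals. Because
merged regions are disjoint and sorted, the join is a binary search per
gene; tests cross-check it against an independent interval-join
implementation (pyranges).

## Contingency tests

The method-selection rule mirrors the standard statistical-environment
warning: if any expected cell of the 2×2 is < 5, use the two-sided Fisher's
exact test; otherwise the 1-df chi-squared with Yates' continuity
correction. The Yates term is `min(0.5, |O−E|)`, so near-independent tables
yield a statistic of exactly 0 rather than a spurious signal. The two-sided
Fisher p sums hypergeometric probabilities (over the full table support at
fixed margins) not exceeding the observed table's probability, with a
1 + 1e-7 relative tie tolerance; this matches R's `fisher.test` and is
verified against frozen R 4.3.3 values and a log-factorial enumeration
oracle to 1e-10. Fold enrichments are always computed from raw counts —
`(a/(a+b))/(c/(c+d))` — never from rounded rates (rounded rates give 16.2/3.2
≈ 5.06 where the full-precision value is 5.00).

The region-level test uses the same rule on the 2×2 of (regions with ≥1
StMA gene, regions without) × (case, control). Report tables round half-up
at reporting precision (1 decimal for per-1000 rates, 3 for per-Mb, 2 for
Mb sizes and folds); all internal computation is full precision.

## Permutation null

Samples are drawn uniformly without replacement (a gene list has no
duplicates) from the expressed-gene pool; the default sample size is the
StMA list restricted to the pool — the only size that makes the surrogate
like-for-like with the list it replaces. One sample per iteration is shared
across all datasets, so dataset columns are correlated exactly as a single
resampled list implies. Per-iteration tests use the same selection rule as
the main analysis; Bonferroni adjustment multiplies each iteration's p by
the number of case datasets. Default 10,000 iterations; the test suite and
examples run 2,000, which bounds the Monte-Carlo standard error of a median
well below the tolerances asserted. The empirical p for an observed count
uses the add-one rule `(1 + #{count ≥ observed})/(n_iter + 1)`.

## Synthetic studies

The generator produces the structure the analysis assumes, not a realistic
human genome (no gene-density gradients, CNV hotspots or segmental
duplications — passing tests say nothing about those features):

- **Genome**: `n_genes` (default 3000, the scale of an expressed-gene assay)
  fixed-length 10 kb genes placed uniformly without overlap on 20 × 150 Mb
  chromosomes (~3 Gb). Fixed gene length keeps per-Mb and per-gene metrics
  analytically related.
- **Truth labels**: fractions `frac_stma` = 0.08, `frac_ba` = 0.62,
  remainder consistent-MA.
- **Clone tables**: expressed-allele mean 100 (arbitrary units), silenced
  mean 4 — near zero but positive so the default path exercises the
  fold-ratio rule rather than division-by-zero — with independent
  multiplicative log-normal noise (`noise_sd`, default 0.2, on the log
  scale). StMA genes draw an allele per clone conditioned on the clones not
  all agreeing, so planted labels are realisable and σ = 0 recovery is
  exact; misclassification grows monotonically with noise.
- **CNVs**: exponential lengths (closed-form expectations for tests), case
  mean 1.2 Mb vs control mean 0.49 Mb and 150 vs 440 variants, mimicking
  the case-larger/control-smaller-but-more-numerous asymmetry of real
  disease vs population-survey datasets. Controls are placed uniformly; a
  case CNV is centred on a random StMA gene with probability `q`, else
  uniform.

`q` is solved from the requested fold `F`: with background per-gene
coverage `c_b = 1 − exp(−n(L+l)/G)` and StMA fraction ρ, the measured
per-1000 fold equals `F` in expectation when StMA coverage is
`c_s = r·c_b`, `r = F(1−ρ)/(1−Fρ)`, giving `q = N_s(−ln(1−r c_b) − μ_b)/n`.
The unique-gene (coverage) formulation absorbs duplicate targeting of the
same gene, so recovery is unbiased rather than saturating at high folds.
Infeasible requests (`Fρ ≥ 1`, `r c_b ≥ 1`, `q > 1`) raise immediately
instead of silently planting a weaker fold. Default geometry was chosen so
that (i) a fold of 5 is still feasible (`q ≈ 0.93`), and (ii) null
contingency cells land in the teens, where the Yates-corrected test is close
to nominal size — the test is intrinsically slightly conservative, which is
visible in calibration results (~3.5–4.5% rejection at α = 0.05).

All three generators are deterministic under `rng_seed`, with independent
per-stage streams derived from it.

## Problem sizes in the checks

The statistical acceptance checks run 500 seeds for type-I calibration, 50
seeds per planted fold for recovery, and 2,000 permutation iterations —
sizes at which the binomial/Monte-Carlo standard errors are several times
smaller than the asserted tolerances. The brute-force oracles run at small
n (margins ≤ 60 for Fisher enumeration, ≤ 50 intervals on 10 kb toy
chromosomes) where exhaustive computation is exact.

## Known limitations

- The minimal-region construction (coverage ≥ 2, singleton passthrough) is
  one reasonable definition of "critical overlap"; alternatives (e.g.
  full-cluster intersection) would give smaller cores.
- Gene mapping uses ≥1 bp overlap with no minimum-fraction rule; a CNV
  clipping a gene's last base claims the whole gene.
- The permutation pool is sampled uniformly; no matching on gene length or
  GC content.
- CNV type (gain vs loss) is ignored; deletions and duplications are
  pooled.
- Classification treats clones as exchangeable replicates; it does not
  model clone-specific quality or allelic-choice bias.
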