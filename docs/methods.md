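# Methods

`selfscape` analyses the spatial population structure of a predominantly
self-fertilising plant sampled as individuals at geographic field sites and
genotyped at a modest panel of biallelic SNPs (the default panel size is 139
markers with minor allele frequencies ascertained in the 25–30% band).  This
note records the models, the estimators, the synthetic data they are tested
on, and the numerical choices that were genuinely open.

## Genotype representation and cleaning

Calls are one of hom-ref, het, hom-alt, missing.  Cleaning applies three
filters in order:

1. **Samples** with a missing-call fraction strictly above a threshold are
   dropped (default 50/149 ≈ 0.336, stored as a fraction so the rule scales
   with panel size); excess missingness indicates degraded DNA.
2. **Markers** with missing fraction > 0.25 *or* heterozygous fraction
   > 0.25 are dropped.  The two symptoms are tested separately: both
   indicate a failing assay, and combining them would double-count.
3. **Blacklisted haplogroups**: any haplogroup containing a configured
   sample (typically common lab strains) is removed wholesale, as broad
   geographic scatter of a lab genotype indicates contamination.  Because
   the blacklist is defined on haplogroups, the pipeline clusters first,
   removes, then re-clusters the survivors.

Accepted missing encodings on input: `NA`, `N`, `.`, `./.` (and the phased
variant).  Pairs of haplotypes with no comparable marker are flagged
undefined and excluded from every downstream distribution, with a logged
count.

## Pairwise mismatch and haplogroup clustering

All haplotype comparisons treat heterozygous calls as missing: a
heterozygote carries both alleles and cannot be assigned to either side of
a haplotype mismatch.  For two haplotypes, `k` counts mismatches over the
`n` markers informative in both.

Clustering asks: which sets of plants carry *potentially identical*
haplotypes, given that a genotyping panel miscalls each marker with some
small probability ε?  Under that identity hypothesis the number of observed
mismatches is binomial, and the tail probability

    q = P(X ≥ k),  X ~ Binomial(n, ε)

measures how surprising the observed disagreement is.  The working distance
is `d = −log10(q)` (computed via the survival function; `d = 1 − q` is
available as an alternative transform).  Identical haplotypes give d = 0;
each additional mismatch adds roughly |log10 ε| to d, so d is unbounded —
which is what makes the size-adaptive inclusion rule below behave sensibly.
ε defaults to 0.005 (one discrepancy per 200 markers) and is configurable;
it is a property of the assay, not of the population.

A modified quality-threshold (QT) search then partitions the sample.  For a
candidate centre, neighbours are proposed in order of ascending distance
and included while `d < τ(m)`, where m is the current cluster size
(including the centre) and τ(m) = α·m with α = 0.05 by default; the walk
stops at the first failure.  Every remaining sample is tried as centre, the
largest grown cluster wins (ties: smaller total member distance, then lower
input index), is removed, and the search repeats.  Cluster sizes are
non-increasing along the extraction order.  The implementation vectorises
the centre search (row-sorted distance matrix; a centre's cluster is the
longest prefix satisfying the threshold sequence), and is tested for exact
partition equality against a literal re-evaluating reference implementation
on samples of up to 12 haplotypes.

The multiplicative threshold has a consequence worth stating plainly: **a
cluster can only absorb error-bearing copies after exact copies have grown
it**.  A copy carrying k miscalls is admitted only once m ≥ d(k)/α — about
6 for one miscall, 30 for three, 62 for five at the defaults.  Large clonal
groups (hundreds of copies, as a recently spread selfing lineage produces)
therefore tolerate scattered genotyping errors, while small groups stay
fragmented and unrelated haplotypes (tens of mismatches, astronomical d)
never merge.  Recovery tests use clone groups of ~100+ copies accordingly.

## Inbreeding and selfing rates

Within a field site, loci polymorphic at the site contribute observed and
expected heterozygosity:

    H_obs,j = het fraction at locus j (non-missing calls)
    H_exp,j = 2 p̂_j (1 − p̂_j) · 2n_j/(2n_j − 1)

with p̂_j the within-site allele frequency over the n_j genotyped plants,
and the multilocus inbreeding coefficient is the ratio of sums

    F_IS = 1 − Σ_j H_obs,j / Σ_j H_exp,j .

The ratio-of-sums combination is the standard multilocus estimator; the
2n/(2n−1) factor is the usual small-sample correction.  (Under strong
inbreeding the sampling variance of p̂ is inflated by (1+F), so a residual
downward bias of order F/(2n) in F̂_IS remains — about 0.05 percentage
points of selfing at n = 30, negligible at the tested scales.)

At mixed-mating equilibrium a constant selfing rate s yields F = s/(2−s),
inverted as

    s = 2 / (1/F_IS + 1) = 2 F_IS / (1 + F_IS),

clamped to [0, 1]; non-positive F_IS (heterozygote excess) maps to s = 0.
The conversion assumes outcrossing uniform within the site and equilibrium
allele frequencies and heterozygosity; within-site spatial mating structure
inflates estimates.  Sites qualify for estimation when all genotyped tissue
is field-collected seed or mature field-grown plants (material not filtered
by viability selection under cultivation) and at least two haplogroups are
present.  Confidence intervals are percentile intervals from a locus
bootstrap (default 1000 replicates); replicates whose resample is entirely
monomorphic are dropped, and the CI is reported undefined if they exceed
half.  Aggregate selfing is reported both plant-weighted and site-weighted,
since the two differ when site sizes vary.

## Diversity and the panmictic null

Site haplogroup diversity is the probability that two plants drawn without
replacement from a site belong to different haplogroups,
`1 − Σ c_i(c_i−1)/(n(n−1))` (a with-replacement Simpson variant is
available).  A site is "dominated" when its modal haplogroup exceeds 80% of
plants (configurable).

The pairwise mismatch-fraction distribution over all plant pairs is
stratified by continent pair.  Its null is a panmictic resampling: each of
n_sim simulated haplotypes copies, independently at every marker, the call
of a donor chosen uniformly with replacement (default n_sim = 10,000; a
variant restricts the donor pool to one representative per haplogroup to
remove clonal amplification).  The simulated mean mismatch fraction has a
closed-form expectation from donor call frequencies — at marker j, two
draws are both informative with probability g_j² and differ with
probability g_j² − Σ_c f_{c,j}² — used as an analytic cross-check of the
simulation (ratio of expectations; the comparable-marker count concentrates
tightly, making the approximation far finer than Monte-Carlo error).

Pairs are classified as *identical* (k = 0), *unrelated* (mismatch fraction
at or above the 1st percentile of the simulated panmictic distribution), or
*intermediate* (below the panmictic background but not identical).  The
published three-way split is descriptive; this rule is the package's
operational formalisation, and both the cut quantile and the identical rule
are configuration.

## Geographic analysis

Distances are great-circle (haversine, mean Earth radius 6371.0088 km) on
WGS84 decimal degrees, with no datum conversion.  Pairs are binned into
half-open fixed-width distance bins (presets 150, 10 and 0.5 km, i.e.
continental to within-field scale) by the floor rule.  Per bin: pair count,
same-haplogroup proportion, and mismatch-fraction percentiles
(9/25/50/75/91, linear interpolation).

Curves are fitted to the binned data, weighted by per-bin pair count by
default (the bins carry wildly different numbers of observations;
unweighted mode is available).  Forms: y = mx + b (closed-form weighted
least squares), y = C·exp(−λx), and y = K − C·exp(−λx)
(Levenberg–Marquardt).  Initialisation: C₀ from the first informative bin,
K₀ from the response maximum, λ₀ from a log-linear regression of the
response (decay) or of the residual against the plateau (saturating), with
its sign preserved — data trending the wrong way drive λ negative and the
fit is reported `converged=False` rather than raised or forced, mirroring
panels of real data that do not follow an exponential.  Bins with fewer
than 5 pairs are excluded from fits by default (configurable).  Reliable
recovery of λ requires bins spanning several decay lengths; the recovery
tests use 40 bins over six decay lengths.

Between-site differentiation uses the Weir–Cockerham two-population θ:
per-locus variance components a (between populations), b (between
individuals within populations) and c (within individuals), combined across
loci as Σa / Σ(a+b+c).  Negative combined estimates are retained — they are
part of the estimator's sampling distribution and truncation would bias the
distance regressions.  Loci with fewer than two genotyped individuals in
either site, or monomorphic in the pooled pair, contribute nothing.  Sites
need ≥ 4 genotyped plants by default.  θ is regressed on ln(km) (zero
distances excluded and logged), globally and in sliding windows of
consecutive pairs ordered by distance (window 500 for data at the original
study's scale; synthetic runs use 50).

## Synthetic data

The generator produces the statistical structure the estimators assume, so
every stage is testable without the original collection.

* **Panel**: baseline alt-allele frequencies uniform on [0.25, 0.30]
  (matching an intermediate-frequency ascertained panel), 139 markers.
* **Equilibrium site**: per plant per locus, with probability F an inbred
  draw (homozygous, allele by local frequency) else a Hardy–Weinberg draw.
  This is exactly the mixed-mating equilibrium under which F_IS → F, and
  heterozygosity per locus is (1−F)·2p(1−p).
* **Eurasia-like landscape**: sites uniform on a rectangle of side
  `extent_km` (default 3000 km); per-site allele frequencies perturb the
  baseline logit by a Gaussian field with covariance σ²·exp(−d/scale)
  (default σ = 1, scale = 1000 km), truncated to (0.02, 0.98).  This is a
  deliberately simple stand-in for whatever demographic process produced
  smooth spatial frequency gradients: it creates tunable isolation by
  distance without a forward simulator.  Default per-site F is 0.95 with
  s.d. 0.02 across sites (selfing ≈ 97% with site-level variation); plants
  per site uniform on [5, 40].
* **North-America-like landscape**: a few founder haplotypes (homozygous
  draws from the baseline) spread clonally; each site receives
  `clone_fraction` (default 0.9) of its plants as error-perturbed copies of
  one founder, the founder chosen with distance-decaying weight from random
  origin sites, plus equilibrium draws for the remainder.  This mimics a
  recent colonist whose un-recombined haplotypes blanket a continent with
  little continental-scale structure.
* **Noise**: each homozygous call flips to the *opposite homozygote* with
  probability `error_rate` (default 0.005); a hom→het error mode exists but
  is off by default because downstream treats heterozygotes as missing, so
  it would act as missingness rather than mismatch.  Missingness (default
  0.02) is applied after error.  Every generator is bit-reproducible from
  its spec and seed, and landscape truth records (per-site F, per-site
  frequencies or founder assignments) are emitted for recovery tests.

What the generator does **not** emulate: linkage and recombination (markers
are independent, matching the marker-level analyses), landmass geometry,
uneven global sampling effort, biparental inbreeding, and real ascertainment
quirks.  Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to everything field data
can do.

## Pipeline, seeds, determinism

`run_pipeline` executes simulate/ingest → QC → cluster → blacklist →
re-cluster → selfing → diversity/panmixia → IBD → F_ST from one validated
YAML config (unknown keys rejected), writing TSVs plus a YAML manifest with
config hash, per-stage wall times, filter accounting (every removed sample
or marker appears in exactly one report) and output checksums.  Stages
lacking inputs (no metadata, no geography) are skipped with explicit
manifest entries.  Per-stage seeds are derived from the master seed by
hashing the stage name, so adding a stage does not shift the randomness of
others.  Identical config + seed give byte-identical tabular outputs.

## Problem sizes in the default test suite

The suite exercises the chain at sizes a laptop handles in seconds: 50
sites × 30 plants for the whole-sample selfing recovery, 8 × 25 for the
North-America-like recovery, ≤ 12 haplotypes for exhaustive clustering
equivalence, ~400-plant clone landscapes (20 seeds) for founder recovery,
20-site landscapes (10 paired seeds) for the scenario contrast, and
100-seed curve-fit recovery on 40-bin fixtures.  These sizes were chosen so
the statistical assertions have comfortable margins while the whole suite
stays fast.

## Known limitations

* The clustering threshold rule is a behaviour-preserving interpretation of
  an under-specified published rule (a literal probability-valued distance
  degenerates); the transform and rule are configurable for sensitivity
  analysis, and conclusions that depend on the exact rule should be checked
  under the alternatives.
* F_IS-based selfing assumes mixed-mating equilibrium and uniform
  outcrossing within sites; biparental inbreeding and within-site structure
  inflate s.
* The maximum-likelihood selfing estimator from per-plant heterozygous-locus
  counts is not implemented; the het-count distribution is reported
  descriptively only.
* θ between small sites (4–10 plants) is noisy; the regression-on-distance
  analyses lean on many site pairs, not on individual θ values.
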