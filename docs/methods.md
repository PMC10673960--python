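# Methods

## The cross and its generative model

The package analyses (and simulates) a two-generation full-sib family of a
hermaphroditic land snail: parents P1 × P2, the two parents of P1 as
grandparents, and 75 offspring. P1 is the *informative* parent — it is
heterozygous at every retained marker and at both trait loci; P2 is
heterozygous at a configurable fraction of markers
(`both_parent_het_fraction`, default 0.5) and homozygous recessive at the
trait loci. Shell colour is scored yellow (=1) / not yellow, with pink
dominant; mid-banding is scored mid-banded (=1) / not, with band
suppression dominant. Because the second parent is homozygous recessive at
both loci, each phenotype is a deterministic function of the single allele
transmitted by P1 — a pseudo-testcross trait segregating 1:1.

Meioses follow the Haldane model: crossover counts per linkage group are
Poisson with mean length/100 and breakpoints uniform, i.e. no crossover
interference. This choice is deliberate: it makes the transmission process
exactly Markov along the chromosome, matching the assumption of the
genotype-probability HMM downstream, and it is the map function used
throughout (r = (1 − e^(−2d/100))/2).

Noise model: each called genotype is replaced by one of the two wrong
genotypes with probability `genotyping_error` (default 0.002, the error
rate the scan HMM assumes), masked completely at random with probability
`missing_rate` (default 0.05), and annotated with a negative-binomial read
depth (mean 10, matching the ~10× design coverage; variance m + φm²,
Poisson as φ→0). Site quality is written as the maximum (999), so the
QUAL filter is exercised through hand-built fixtures rather than the
simulator.

Default genome: the 22 published linkage-group lengths (cumulative
2143.71 cM) at a desk-scale density of ~1 marker per cM (2143 markers).
The published map has ~100 markers per cM; a desk-scale family of 75
offspring caps any pairwise LOD at ~23 (75·log₁₀2 per parent), so density
and thresholds are rescaled rather than the family size (see below).
Markers are grouped into contigs spanning contiguous runs (mean ~12
markers), giving the contig-conflict rules something real to act on.

Haplotype labelling: P1's first haplotype carries the reference allele at
every marker and the dominant allele at every trait locus; at markers
heterozygous in both parents, P2's haplotypes are phase-aligned the same
way. This is a labelling convention, not an assumption — digit 1 simply
means "grandparent-1 strand" — and it makes the F2 code of a called
genotype directly observable. Parents are written phased (`0|1`) in the
VCF, standing in for the multipoint pedigree phasing that a full
Lep-MAP3-style pipeline would perform (out of scope here).

## Marker retention

A site is kept iff QUAL ≥ 999, it is a SNP (not an indel), minor-allele
frequency ≥ 0.05 over the non-missing called alleles of *all* individuals
(the family is the only panel available; the published pipeline's
denominator is unstated), the missing fraction is ≤ 10%, and the mean
depth across non-missing calls lies in [10, 25] inclusive (vcftools-style
semantics). Removals are attributed to the first failed rule in the order
QUAL → indel → MAF → missingness → depth; the order affects only the
report, never the kept set, and the report reconciles exactly. The
informative-marker step then keeps sites heterozygous in P1 at which at
least one individual is not heterozygous.

## Two-point engine and map assembly

Transmission digits are resolved from calls plus parental phase: at
markers where P2 is homozygous, the offspring call determines the paternal
digit outright; at markers heterozygous in both parents, homozygous
offspring resolve both digits, while heterozygous offspring yield the
merged AB code with unresolved phase.

Two-point estimates come in two forms. For phase-known digit vectors the
folded binomial ML is used: r̂ = min(k, n−k)/n with LOD = log₁₀ L(r̂)/L(½).
For pairs of fully informative markers the likelihood marginalises the
unobserved transmitted phase of heterozygotes — the 9-category joint code
distribution P(AA,AA) = (1−r)²/4 etc. — and is maximised by an EM fixed
point, vectorised over all pairs. The phase-marginal form is essential:
summing the paternal and maternal phase-known LODs at such markers
double-counts (their resolved digit vectors coincide), which at ~18
doubly-homozygous offspring per pair produced false cross-group edges.

Grouping is single-linkage transitive closure over pairs with LOD ≥
`lod_limit`; groups below `size_limit` dissolve to singletons, which are
then re-joined to the group of their best-linked marker if that LOD ≥
`join_singles_lod`. The type defaults carry the full-scale study values
(9.5 / 600 / 5); the pipeline's desk defaults are 7.0 / 8 / 5.0, scaled to
the desk marker density where adjacent-marker LODs of ~7–10 carry the
same per-unit-density linkage evidence.

Ordering minimises the sum of adjacent recombination fractions: greedy
nearest-neighbour path construction (ties broken by marker id), 2-opt
refinement, 20 random restarts (restart seed = base + index), keeping the
best; orientation is canonicalised by marker id. Adjacent distances are
the Haldane images of the per-parent fractions, falling back to the
sex-combined estimate where a parent is uninformative for an adjacency;
fractions are capped at 0.45 before the map function so a noisy adjacency
cannot blow up the map. Note a known desk-scale bias: seriation prefers
downward-noise r̂ estimates, so assembled group lengths underestimate the
simulated truth by ~20–30% at 75 meioses. Ordering is exact (verified
against exhaustive search) for small groups and recovers the true order
on error-free data with ≥150–200 meioses.

Refinement rules, applied in order: (1) LOD-matrix pruning — at each map
location, co-located SNPs' maximum pairwise LODs are normalised by the
location maximum and a SNP is removed iff its normalised score is more
than one sample (n−1) standard deviation below the location mean (single
SNPs never removed); (2) contig conflicts — a contig on ≥2 groups is
removed entirely when it has ≤10 mapped SNPs, otherwise its SNPs are
removed from every group holding <10% of them, and a large contig still
straddling groups after that is removed entirely (logged separately);
(3) sex-averaging — cm_avg = (cm_male + cm_female)/2, group origins reset
to zero, lengths recomputed from cm_avg.

## Map statistics

With M markers on G groups of cumulative length L: s = L/(M−G);
expected genome length Σᵢ(Lᵢ + 2s) (two terminal regions per group);
coverage = observed/expected; recombination rate = L / genome size
(default 3500 Mb). Reporting precision: lengths 2 dp, s two significant
figures, rate 2 dp, coverage nearest percent. Note the identity
expected = L + 2Gs exactly; at the published scale (s = 0.0099, G = 22)
the expected length exceeds the observed by only ~0.4 cM, so coverage is
~100% by this formula — the package reports what the formula yields.

## Binary-trait scan

Genotype probabilities: a 3-state chain over {AA, AB, BB} per offspring
per group, prior (¼, ½, ¼), transitions from the Haldane fraction of each
adjacent gap with intercross transition probabilities, emissions 1−ε for
the observed code and ε/2 for each wrong code (ε = 0.002), missing
uninformative. Forward–backward with per-step normalisation; equivalent
to exact hidden-path enumeration (tested). The scan runs on the markers
heterozygous in both parents; pseudo-testcross markers support the map
but their maternal digit is undefined, so they carry no 3-state code.

LOD: at each position a logistic regression of the phenotype on the three
genotype-probability columns (no intercept — the columns sum to one, so
this spans intercept + contrasts and the coefficients are per-class
log-odds), fitted by iteratively reweighted least squares with an
iteration cap of 100, fitted probabilities clamped to [1e−12, 1−1e−12]
and coefficients capped at ±20 log-odds, which bounds the likelihood
under the complete separation a fully penetrant locus produces. LOD =
(ℓ_full − ℓ_intercept)/ln 10, clipped at zero. Because the second parent
is uninformative for the trait, heterozygote codes are split between
phenotypes and the information comes from the two homozygote classes —
peak LODs around 11 for 75 offspring, matching what such a cross can
yield.

Thresholds: phenotype labels permuted n_perm = 1000 times (seeded per
trait), threshold = empirical 95th percentile of the permuted genome-wide
maximum LOD. The realised genome-wide type-I error is ≈5% on null
simulations (tested at n_perm = 200 over 200 replicates).

Peaks: local maxima above the threshold; two adjacent maxima are
independent only if the LOD drops at least 1.8 below both of them in
between, otherwise the higher absorbs the lower. Credible interval: mass
∝ 10^LOD over the group's marker positions (no pseudomarker grid); the
interval is the smallest contiguous span containing the peak with ≥95% of
the normalised mass (ties broken by cM width, then leftmost). Allele
effects are the capped per-class log-odds from the same fit; the
dominance orientation for validation (which homozygote class implies
phenotype 1) is read from the sign of the effects at the peak. The
segregation check counts phenotype-incompatible homozygotes (AB exempt);
a candidate region is the span of check-consistent positions inside the
supported interval, its width reported to one decimal.

Calibration caveat: the 10^LOD mass is a likelihood-shaped posterior, not
an exact one. When the nearest informative marker is >2 cM from the
locus, the 95% interval covers the true position in only ~75–88% of
simulated crosses at n = 75; with the locus at a genotyped marker —
the study's situation, since the candidate contigs themselves carry
mapped SNPs — coverage is 96–99%. The coverage test uses the latter
design; interpret desk-scale intervals over sparse maps accordingly.

## Detection power

The likelihood-ratio test of a single-locus effect has noncentral
chi-square distribution under the alternative. For a locus explaining a
fraction h² of the trait variance, worst-case centred in a candidate
interval of width w cM (nearest marker w/2 away, attenuation (1−2r)² with
r = Haldane(w/2)):

λ = n(1−2r)²h²/(1−h²),  power = P[χ²₁(λ) > χ²₁,₁₋α].

One degree of freedom reflects the single transmission contrast of a
dominant binary locus in this cross. h² = 0 recovers the test size
exactly; h² = 1 is the deterministic limit (power 1). The grid scan
`power_threshold_h2` reports the smallest h² (1% steps) whose power,
rounded to the nearest percent, reaches a target. At the study design
(n = 75, α = 0.01): power is 100% for both the 2 and 5 cM intervals at
h² = 1; rounded power holds at ≥95% down to h² = 21%. The rounded-power
= 100% threshold computes to 29% under this model; no parameterisation of
the noncentral chi-square family can place it near 40% while keeping the
95% threshold at 21%, because between h² = 0.21 and 0.40 the
noncentrality grows 2.5-fold but the 95%→99.5% power step requires only a
~1.5-fold increase.

## What the simulator does and does not emulate

It reproduces the family structure, marker informativeness classes,
dominance architecture, Mendelian segregation, Haldane recombination,
call-level noise and depth — the features the mapping and scanning
machinery consumes. It does not emulate read-level artefacts (alignment
error, allelic dropout correlated with depth, paralogy-driven false
SNPs), segregation distortion, crossover interference, or the 100×
greater marker density of the resequencing study; passing tests therefore
certify the statistical machinery under the stated model, not robustness
to those artefacts. Known desk-scale behaviours: assembled map lengths
are compressed relative to truth (seriation noise-selection), and
candidate regions typically contain a single consistent position rather
than a multi-position span, because co-located SNP stacks are absent.

## Degenerate inputs and numerical choices

Zero-length groups put all markers at 0 cM; zero-distance transitions
copy states exactly (a missing code flanked by AA at 0 cM is AA with
certainty); an all-uninformative group keeps its input order with a
warning; a single-class phenotype yields a zero scan with a warning; an
empty candidate set reports "locus not localised". M = G makes s
undefined (reported 0 with a warning). Recombination fractions are
clipped at 1e-300 inside logs; the HMM renormalises per step and falls
back to uniform weights on zero-probability paths (possible only at
ε = 0 with contradictory codes). All stage seeds derive from the pipeline
seed via SHA-256 of the stage name, so stages are individually
reproducible and reruns are byte-identical.
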