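# Methods

## Estimator

`snpkin` estimates the kinship coefficient φ — the probability that a
random allele drawn from each of two individuals at the same locus is
identical by descent — from the spatial arrangement of minor alleles
along the genome rather than from per-locus allele-sharing counts.
Relatives share long chromosomal segments, so the bp gaps between an
individual's successive minor-allele sites are locally identical within
shared segments; the Minkowski distance between two individuals' gap
vectors therefore shrinks with relatedness.

The pipeline for one pair is: (1) drop sites where both individuals are
homozygous major, and any site with a missing call in either individual
(missingness is handled per pair; no imputation); (2) per individual,
assign each retained minor-allele site the gap to that individual's
previous minor-allele site among the retained sites, doubled when both
endpoint genotypes are homozygous minor; phase is ignored; (3) compute
d = (Σ|xᵢ−yᵢ|ᵖ)^(1/p) and convert to φ̂ = (1 − d/d_t)/2.

Two boundary anchors make the conversion exact at the extremes: a pair
with identical genotypes has d = 0 and φ̂ = 0.5 (self-pairs
short-circuit to 0.5 without computing anything — equivalent and
cheaper), and d_t is defined as the mean distance of the declared
unrelated training pairs at the current p, so those pairs average
φ̂ = 0 exactly.  Estimates below 0 (d > d_t) are legitimate and
reported as-is; users threshold φ̂ themselves.

### The artificial start

The upstream gap of an individual's first minor-allele site is
undefined, so an artificial site with genotype aa is anchored just
before the first retained site.  A literal offset of 10⁻¹⁶ bp would
underflow against bp-scale coordinates in double precision, so the
anchor gap is computed as (pos − first_retained_pos) + ε with
ε = 10⁻¹⁶ by default: the individual whose first minor allele sits at
the first retained position gets a gap of exactly ε (doubled to 2ε if
homozygous), and the genotype information at that site survives.  A
fresh anchor is inserted at every chromosome boundary; no gap ever
spans two chromosomes, which makes per-chromosome feature computation
decompose exactly under concatenation.

### Fitting the order parameter

p is the single free parameter, constrained to (0, 1] (a practical
lower clamp of 10⁻⁶ avoids the singular limit).  The training objective
sums, over the relationship classes present in the training set, the
squared gap between the class-mean φ̂ and the theoretical value
(PO/FS 1/4, 2nd 1/8, 3rd 1/16, UN 0), with d_t recomputed from the
training UN pairs at every candidate p so the calibration stays
self-consistent.  A per-pair residual variant is available
(`residuals="pair"`), but class-mean residuals are the default: they
match the class-level definition of the target quantities, and they
give the unrelated class an identically-zero residual, which has an
important consequence below.

The one-dimensional bounded problem is solved by multi-start bounded
Brent search (five uniformly spaced brackets of (0, 1] by default,
tolerance 10⁻⁶, at most 400 iterations per start).  The incumbent
solution is the canonical initial guess p₀ = 0.5 — the midpoint of the
constraint box — and a candidate replaces it only when it improves the
objective by more than the convergence tolerance: objective differences
below 10⁻⁶ are by definition indistinguishable from converged.

This incumbent rule is the load-bearing numerical choice.  When the
training set contains only unrelated pairs — the cheapest and most
common labeling — the class-mean objective is identically zero at every
p: the UN class mean is forced to zero by the construction of d_t, so
the data cannot prefer any order.  The fit then returns p₀ = 0.5
deterministically.  The per-pair variant is no better in substance: its
UN-only objective is a noise function at the 10⁻⁵ level whose minimizer
is an arbitrary crossing point of two empirical distance curves, and
the resulting p (and all downstream class means) vary wildly between
data sets.  Returning the least extreme admissible order under a flat
objective is the honest resolution, and empirically it is also an
accurate one: across simulated data sets the class means at p = 0.5
track the theoretical values closely (see the README example).  With
informative training (pairs from related classes), the objective has
genuine curvature well above the tolerance and the search finds its
minimum; a dedicated test pins the fit to a dense grid-search oracle in
that regime.  Solutions landing on a box bound with an objective above
100× tolerance trigger a denser pass of starts — heterogeneous cohorts
can make the objective multi-modal — and the smaller objective wins.

### Numerics of the fractional-order distance

|xᵢ−yᵢ|ᵖ sums over bp-scale gaps can overflow long before p reaches the
lower clamp, so distances are computed in log space:
log d = logsumexp(p·log|Δᵢ|)/p over the non-zero differences, and the
conversion uses the ratio exp(log d − log d_t) directly.  Zero
differences contribute nothing for p > 0; when the diagnostic wide-grid
objective scan evaluates negative orders, zero differences are excluded
by the same continuity convention so the scan stays finite.  Feature
vectors do not depend on p, so the fit precomputes each training pair's
log-differences once and re-evaluates the objective at many orders
cheaply.

## Stratified estimation

Allele-frequency divergence between hidden subgroups biases a single
global calibration, so the stratified workflow first clusters
individuals by k-means on raw dosage rows (0/1/2 counts, uncentered)
under 1 − Pearson-correlation dissimilarity.  Centroids are arithmetic
means of member rows — the natural Lloyd update; the dissimilarity only
enters assignment — with k = 1–5 and ten random initializations per k,
keeping the restart with minimum summed point-to-centroid
dissimilarity.  Individuals with zero-variance dosage rows (undefined
correlation) are assigned by Euclidean distance and flagged.  The
chosen k is the largest whose relative inertia improvement over k−1
reaches 20% (k = 1 when none does); the rule is transparent,
per-k results are always reported, and k can be forced.  A model is
then fitted per cluster (within-cluster training pairs) and per cluster
pair (training pairs spanning the two clusters, i.e. the pooled
individuals), each block requiring at least one unrelated training
pair, and the block estimates are merged into a single table that
covers every pair exactly once.  With k = 1 the workflow reduces
bit-for-bit to the unstratified estimate.

## Synthetic data generator

The simulator provides the study conditions under which the estimator
is validated: non-inbred three-generation pedigrees whose founders are
mutually unrelated, gene-dropped on one synthetic chromosome.

* **Template.** The default unit has 20 members: two grandparental
  couples, a sibship of three and a sibship of two in the middle
  generation, four married-in founders, and seven grandchildren.  Per
  unit this yields 24 parent-offspring, 8 full-sibling, 26
  second-degree (grandparent-grandchild and avuncular), 7 third-degree
  (first-cousin) pairs and a large unrelated remainder — approximately
  the per-pedigree class profile of a ~150-individual, 7-pedigree
  family study.  Any pedigree can be supplied instead; validation
  checks that parents precede children and belong to earlier
  generations.
* **Founders.** Per-site MAF is drawn uniformly from [0.05, 0.5];
  haplotype alleles are independent Bernoulli draws at that frequency
  (linkage equilibrium); positions are drawn uniformly without
  replacement from a 59 Mb window (the scale of a mid-sized human
  chromosome) and sorted.  Phased founder haplotypes from real data can
  be supplied instead.
* **Meiosis.** Crossover counts are Poisson with mean equal to the
  map's genetic length (uniform 1 cM/Mb by default; piecewise-constant
  maps are supported); crossover positions follow the map's cumulative
  rate; the starting haplotype is a fair coin; no crossover
  interference.
* **Truth.** Theoretical kinship comes from the standard recursion
  φ(i,i) = (1 + φ(father, mother))/2,
  φ(i,j) = (φ(father_i, j) + φ(mother_i, j))/2 descending through the
  later-generation member, with founders mutually unrelated; a
  Monte-Carlo gene-dropping oracle in the test suite confirms it to
  |Δ| < 0.01 at 10⁵ drops.  Relationship labels are structural for
  PO/FS and kinship-derived otherwise.

**Fidelity limits.** Real founder haplotypes carry linkage
disequilibrium and a non-uniform site spacing that the default
generator does not reproduce; experiments with a Markov-correlated
founder model showed the estimator's class means behave the same way,
but passing tests here demonstrate correctness of the machinery and
calibration, not performance on any particular real cohort.  A single
~0.6-Morgan chromosome also makes the *realized* genome sharing of
FS/2nd/3rd-degree pairs highly variable (the per-pair spread in the
README example), so class means on small simulations carry sampling
noise of a few hundredths; parent-offspring sharing has no such
variance and is correspondingly tight.  A mild upward pull of the
mid-range class means (≈ +0.01 to +0.03) reflects concavity of the
expected distance in realized sharing at fixed p; it sits well inside
the validation tolerances and would shrink with genome length.

## Problem sizes

The bundled validation runs use 3 pedigree units (60 individuals) at
10,000 SNPs for relationship recovery, 1 unit at 2,000 SNPs for
fast checks, and 10⁵ replicates for Monte-Carlo oracles — sizes chosen
so the full suite completes in well under a minute while leaving the
statistical tolerances comfortably resolvable.

## Known limitations

* The estimator returns a kinship coefficient only; it does not
  classify pairs into named relationships, infer IBD segments, or
  compute Cotterman coefficients.
* d_t is a cohort-level constant; no correction is applied for MAF
  spectrum, linkage disequilibrium, or Hardy-Weinberg departures
  (influences acknowledged but unmodeled — the p calibration absorbs
  them in practice).
* With unrelated-only training the order parameter is not identified
  by the data (see above); the reported p is the canonical midpoint,
  not a measurement.
* PLINK binary input, genotype imputation and phasing are out of
  scope; VCF and a documented tab-separated dosage dialect are the
  supported inputs.
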