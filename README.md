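# snpkin

Kinship coefficient estimation from the spatial distribution of
minor-allele SNPs.

Cryptic relatedness and hidden population structure inflate type I error
in genome-wide association studies, so estimating the kinship
coefficient φ of every sample pair is a standard quality-control step.
`snpkin` implements a distance-based estimator: instead of counting
shared alleles locus by locus, it encodes each individual's genome as a
vector of physical distances between neighboring minor-allele variants
and infers kinship from the dissimilarity of two such vectors.  The
estimator returns a valid numeric φ̂ for every pair, needs only a
handful of labeled pairs for calibration, and is robust to population
stratification when combined with the bundled clustering workflow.

## The model

For a pair of individuals, sites where both are homozygous major (AA)
are dropped.  At each remaining site where an individual carries a minor
allele, its **distance feature** is the bp gap to that individual's
nearest upstream minor-allele site among the retained sites,

    f(b_n) = b_n − b_m            one or both endpoints heterozygous (Aa),
    f(b_n) = 2 (b_n − b_m)        both endpoints homozygous minor (aa),
    f(b_n) = 0                    genotype AA,

with an artificial start of genotype aa anchored just before the first
retained site of each chromosome so the first real site's genotype stays
distinguishable.  The pair's dissimilarity is the Minkowski distance of
order p between the two aligned feature vectors,

    d(X, Y) = ( Σᵢ |xᵢ − yᵢ|ᵖ )^(1/p),

and the estimated kinship coefficient is

    φ̂ = (1 − d / d_t) / 2,

where d_t is the mean distance over training pairs declared unrelated
(so unrelated pairs average φ̂ = 0, identical genotypes give φ̂ = 0.5,
and pairs more dissimilar than the baseline go negative).  The single
free parameter p ∈ (0, 1] is fitted by minimizing the squared error
between class-mean estimates and the theoretical kinship values
(φ_PO = φ_FS = 1/4, φ_2nd = 1/8, φ_3rd = 1/16, φ_UN = 0) over a small
labeled training set, under the box constraint 0 < p ≤ 1 (orders below
one are semi-metrics; that does not harm the estimation).

For stratified cohorts, individuals are first clustered by k-means on
their dosage rows under 1 − Pearson-correlation dissimilarity (k = 1–5,
ten restarts); a separate (p, d_t) is fitted within each cluster and for
each cluster pair, and the per-block estimates are merged.

A recombining pedigree simulator (three-generation non-inbred templates,
Poisson-crossover meiosis under a genetic map, exact recursive kinship)
makes the whole pipeline testable without any external data.

## Worked example

```python
import snpkin as sk

# simulate three 20-member pedigrees on one synthetic chromosome
ped = sk.three_generation_template(3)
g, truth, _ = sk.simulate_pedigree(ped, m=10_000, seed=1)

# declare two cross-pedigree founder pairs unrelated and fit
train = [sk.LabeledPair(("P1_gpA1", "P2_gpA1"), "UN"),
         sk.LabeledPair(("P1_m1", "P3_gpB2"), "UN")]
res = sk.SpatialKinship(g, train).fit()
print(res.summary())
```

```
Spatial-distance kinship model
==============================================
individuals                                 60
SNP sites                                10000
training pairs                               2
unrelated pairs (d_t)                        2
----------------------------------------------
Minkowski order p                     0.500000
baseline d_t                       3.66641e+11
objective (SSE)                      4.930e-32
converged                                 True
==============================================
```

With only unrelated training pairs the objective cannot prefer any
order (their class residual is zero by construction of d_t), so the fit
reports the canonical midpoint of the constraint box; the enormous d_t
is simply the scale of a fractional-order power sum over bp-sized gaps.
Evaluating the fitted model on all labeled pairs outside the training
set:

```python
test = [sk.LabeledPair((r.id1, r.id2), r.relationship)
        for r in truth.itertuples()
        if (r.id1, r.id2) not in [lp.pair for lp in train]]
print(res.evaluate(test).round(4).to_string(index=False))
```

```
relationship      n  phi_true   mean    std    mse
          UN 1573.0    0.0000 0.0044 0.0089    NaN
          PO   72.0    0.2500 0.2541 0.0069    NaN
         2ND   78.0    0.1250 0.1225 0.0983    NaN
          FS   24.0    0.2500 0.2380 0.1367    NaN
         3RD   21.0    0.0625 0.0558 0.0594    NaN
 __overall__    NaN       NaN    NaN    NaN 0.0008
```

The class means sit on the theoretical values — parent-offspring and
full siblings near 0.25, second degree near 0.125, third degree near
0.0625, unrelated near 0 — from just two labeled pairs.  The larger
standard deviations of FS/2ND/3RD reflect genuine variation of realized
genome sharing on a single ~0.6-Morgan chromosome, not estimation noise
(PO pairs, whose sharing is fixed at exactly one haplotype, have σ
below 0.01).

The same workflows are available from the shell:

```sh
snpkin simulate --pedigrees 3 --sites 10000 --seed 1 --out data/
snpkin train -g data/genotypes.tsv -p train.tsv -o model.txt
snpkin estimate -g data/genotypes.tsv -m model.txt -o kinship.tsv
snpkin stratified -g merged.tsv -p train.tsv --seed 1 -o strat/
```

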