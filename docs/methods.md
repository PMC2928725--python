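# Methods

## Genetic models as constrained cell-means tables

The unit of modelling is the 3×3 table of genotypic means θᵢⱼ for two
biallelic diploid loci, indexed by minor-allele count (0 = AA/BB, 1 = Aa/Bb,
2 = aa/bb).  Molecular epistasis is encoded as equality constraints among
cells: a masking genotype forces every cell it covers to one shared value.
The canonical construction starts from the additive surface
θᵢⱼ = (1−i) + (1−j), replaces each constraint group by the unweighted mean
of the base values it merges (overlapping groups are merged transitively —
this is how the dual-recessive pattern's row and column groups collapse
into one five-cell group), recenters to zero mean and rescales so
max − min equals the phenotypic range.  Additive-by-additive epistasis is
the multiplicative surface δ·uᵢ·uⱼ, u = (+1, 0, −1), with δ = range/2.

Two conventions matter and are deliberate:

* **Fixed range, not fixed heritability.**  All six models share
  max θ − min θ = 1.6 in residual-SD units.  Holding the range (effect
  size) constant is what lets epistasis *increase* the explained variance;
  studies that fix the explained variance instead force epistatic effect
  sizes down and reach the opposite conclusion.
* **Equal locus scaling.**  The additive base uses the same per-locus
  effect at both loci; nothing in the study distinguishes locus effect
  sizes, so the symmetric choice is canonical.

The exact numeric means of the masked patterns are one admissible
realization of the stated constraints (group-averaging of the additive
base); any table satisfying the same constraints and range is equivalent
for the qualitative theory, and the constraint checker accepts any such
table.  Equality and centering are checked to 1e−9 absolute in phenotype
units.

## ESS and analytic power

The factor-effects decomposition uses unweighted (equal-cell-weight) means:
μ = grand mean, αᵢ = row mean − μ, βⱼ = column mean − μ, γᵢⱼ the remainder.
For a balanced design with n_c observations per cell, ESS_A = 3n_c Σαᵢ²,
ESS_B = 3n_c Σβⱼ², ESS_AB = n_c Σγᵢⱼ²; the error-variance term common to
all sources is omitted.  The overall F test of the full model has
noncentrality λ = ESS_total/σ² with 8 numerator degrees of freedom, and
power is computed from the noncentral F survival function at the central-F
critical value.  Balanced-theory power is exact only for balanced data;
power under the skewed genotype frequencies of population samples is
estimated by simulation, as the balanced formulas do not transfer.

## Full-model fits and BIC

A "full model" for a marker set fits one mean per *observed* multi-locus
genotype class, so main effects and all interactions are absorbed jointly
and empty cells reduce the model degrees of freedom automatically — the
natural behaviour for unbalanced population samples where rare two- and
three-locus classes are frequently empty.  The overall F statistic is
[(TSS − RSS)/(g − 1)] / [RSS/(n − g)] with g observed classes.  BIC is
n·ln(RSS/n) + (g + 1)·ln n, counting the error variance as a parameter;
only BIC differences at fixed n matter, so the constant convention is
irrelevant.  A perfect fit (RSS = 0, possible at small n with many
classes) is capped at p = 0 and scored −∞ (the model wins outright) with
a warning rather than an exception.  Marker sets with a single observed
class are unfittable and excluded from searches.

Exhaustive searches score batches of candidate models by encoding each
individual's multi-locus genotype class in base 3 and accumulating class
counts and sums with bincount, which keeps 10⁵–10⁶-model searches to
seconds without changing any statistic.

## The synthetic-data generator

The generator emulates unstructured, random-mating populations of constant
size: diploid samples of n ∈ {100, 500, 1000}, genomes of 5 independent
linkage groups × 100 biallelic SNPs, and a population-scaled recombination
rate of 2Nr = 1 between adjacent markers.  Genealogies come from the
coalescent with recombination (msprime) parameterized so branch lengths
are in coalescent units (ploidy 2, population size ½, per-interval
recombination rate equal to the configured 2Nr); one marginal tree is
available at every marker position and multiple recombinations per
interval are permitted.

Mutations are superimposed by this package, one per marker, on a branch of
that marker's marginal tree sampled with probability proportional to
branch length; the leaves below the branch carry the derived allele.  Note
that conditioning on exactly one segregating mutation per marker means the
derived-allele-count spectrum follows E[L_k/L_total] over genealogies,
which tracks but does not exactly equal the unconditional 1/k neutral
spectrum; the tests check the exact per-tree law and a 25% shape bound on
the 1/k law.

At the two designated QTL markers (positions 50 of linkage groups 1 and 2,
so the QTLs are unlinked to each other) placement is conditioned: only
branches whose descendant count k gives a derived-allele frequency k/2n
inside the configured window (low 1–10%, high 20–30%) are eligible, again
sampled proportionally to branch length among eligible branches.  Because
the windows lie below 0.5 the derived allele is the minor allele, which
fixes the orientation of the genotype coding: the rare homozygote is the
*aa*/*bb* class of the means table.  This orientation is what produces the
allele-frequency effects of the theory — recessive-epistasis patterns gain
variance at low MAF relative to the additive model because the masked
class is rare.  If a marginal tree offers no eligible branch, that
chromosome's genealogy is resampled with a fresh deterministic sub-seed
(bounded retries, count recorded on the panel); the MAF window is never
relaxed.

Haplotypes 2k and 2k+1 form individual k; genotypes are derived-allele
counts 0/1/2.  Phenotypes add standard-normal error (SD = 1) to the cell
mean of each individual's two-locus genotype, so the 1.6 range is 1.6 SD.

Replicated experiments hold genealogies constant across settings within a
replicate index: the genealogy seed depends only on (sample size,
replicate), while mutation seeds additionally key on the MAF window and
phenotype seeds on the genetic model.  This removes genealogical noise
from between-setting contrasts, at the cost that a forced resample under
one MAF window can make that one chromosome's genealogy differ between
windows.

What the generator does **not** emulate: population substructure or
relatedness, selection, demography, gene conversion, genotyping error or
missingness, and multi-allelic or structural variation.  Passing tests
therefore speak to the idealized neutral-panmictic setting, not to
confounded real-world association data.

## The two-step scan

Step 1 parses each chromosome greedily left-to-right into blocks in which
*every* marker pair passes the four-gamete compatibility test on the
haplotypes (a block could descend from one gene tree without
recombination).  Within each block all 1- and 2-marker full models are
scored and the minimum-BIC model's markers survive; there is no null model
in step 1 (its purpose is dimension reduction, not testing), so every
block with a fittable marker contributes.  Step 2 fits the intercept-only
model plus every 1-, 2- and 3-marker full model over the union of
survivors and reports the minimum-BIC model; zero loci can be selected.
Ties break toward fewer markers, then lexicographic marker order.

An alternative step-2 family fits additive main-effects regressions
(intercept + 0/1/2 codings, no interactions) for comparing search spaces
on additive traits; its BIC counts the regression rank plus the error
variance.

When only unphased genotypes are available (externally supplied data), a
conservative genotype-based four-gamete test is used: a pair is declared
incompatible only when all four gametes are certain from homozygous
calls, so phase ambiguity can merge but never split truly compatible
blocks.  Step-1/step-2 models are always fitted on diploid genotype
classes (the trait lives on diploids).

## Metrics

Power is the proportion of replicates whose true-two-QTL-model F test has
p < 0.05.  Selection accuracy counts only best models exactly equal to
the specified QTL pair; a marker merely linked to a QTL counts as a false
discovery, so accuracy and detection rates are lower bounds.  The false
discovery rate is the replicate-average of (selected non-QTL markers /
selected markers); replicates selecting zero loci contribute 0, a
conservative convention that keeps the mean defined (their count is
reported separately).  The type-I scan takes ten evenly spaced markers
(indices 1, 12, …, 100 within the chromosome) from each of the three
chromosomes carrying no QTL, fits all 4525 one- to three-marker full
models, and reports the proportion rejecting at α = 0.05; the phenotype
retains its QTL signal from the other chromosomes, so every fitted model
is a true null by independence of unlinked chromosomes.  The trait being
a normal *mixture* (not a single normal) leaves the scan essentially at
the nominal level, with small-sample excursions at n = 100 that stay
within Monte-Carlo error.

## Problem sizes and numerical choices

Default experiment sizes follow the study design (50 replicates per
setting, n up to 1000); the test suite and acceptance script run scaled
sizes chosen to exercise every code path with comfortable statistical
margins: type-I calibration uses 20 replicates at n = 100, power
orderings 50 replicates at n = 500 (power-only runs simulate just the QTL
chromosomes and columns, which is exact for the true-model fit), and
coalescent-law checks use hundreds to thousands of small single-marker
genealogies.  Stochastic assertions use seeded generators and 2–3
standard-error tolerances.  All seeds derive from named SeedSequence
streams, so any replicate is independently reproducible from the manifest.

## Known limitations

* Balanced-design ESS/power formulas are not frequency-weighted; the
  unbalanced case is handled empirically, by simulation.
* The BIC variant (error variance counted, cell-means parameter count) is
  one reasonable convention; alternatives shift all scores by a constant
  or reweight model size and could change selections near ties.
* Step-1 two-marker models never span block boundaries, and the scan
  considers at most three markers, so architectures with more than two
  true loci are out of scope.
* The discrete-marker genome has no intra-marker sequence; "position"
  means marker index, and recombination acts only between adjacent
  markers.
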