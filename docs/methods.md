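# Methods

## The transmission model

An individual is a pair of haplotypes over a linkage map: loci partitioned
into linkage groups, each group ordered, with a recombination fraction
r ∈ [0, 0.5] per adjacent pair.  Gamete formation assumes

* independent assortment between groups,
* within a group, a crossover in each adjacent interval independently
  with probability rᵢ (no interference — the material only supports
  two-point analysis, so a multi-point interference model would add
  parameters nothing could estimate),
* no segregation distortion other than gamete lethality.

A lethality rule is a set of allele combinations; a gamete carrying every
allele of any combination is inviable.  The default rule — {d60, gal},
both sexes, complete penetrance — encodes the complementary gametic
lethality of the semidwarfing system: the observed 75% pollen/seed
fertility of the double heterozygote is exactly the survival of 3 of its
4 gamete classes, which is what complete penetrance predicts.  Fertility
(the pre-lethality surviving fraction) is tracked separately from the
renormalised surviving-gamete frequencies, so population sizes and the
"partially sterile" phenotype are both derivable from a genotype without
extra state.

Zygotes are outer products of surviving-gamete distributions.  Once
formed, genotypes are unordered with respect to parental origin
(reciprocal heterozygotes are never distinguished in this material), but
phase — which alleles co-reside on a chromosome — is retained so a
distribution can seed the next generation.  Exact expected distributions
for a whole cross design (`analytic_genotype_distribution`) propagate
phased-genotype distributions step by step: selfing couples both gametes
through the same random parent; crossing treats parents as independent;
selection conditions the distribution (genotype predicates only).

Phenotype classifiers are total maps from genotype to class label.  The
culm rule: semidwarf iff *d60d60*; partially sterile iff *D60d60·Galgal*;
long-stem otherwise.  The grain rule (incomplete dominance): large iff
*GW2GW2*, medium iff *GW2gw2*, small iff *gw2gw2*; a complete-dominance
mode collapses carriers into "large" for the early-generation
grain-diameter scoring.

*Gal* is unlinked to both *GW2* and *D60* by default: the 6 : 2 : 1 and
1 : 2 : 6 expectations require *Gal* to assort independently, and nothing
in the data constrains its map position.  A custom map may link it.

## Segregation tests

Uncorrected Pearson X² = Σ (obs − exp)²/exp with exp = n·ratio/Σratio;
df = k − 1 by default (minus one per fitted parameter, or overridden —
one published table prints df = 1 beside a three-class test, which the
report reproduces only via explicit override and notes).  No Yates
correction: the published statistics match the uncorrected form.  The
exact p comes from the χ² survival function and is additionally reported
bracketed between neighbouring tabular probabilities (a 0.05-step ladder
plus 0.001/0.005/0.01/0.025 and their complements), mirroring the
conventional "0.35 < P < 0.40" presentation.  Report output rounds X² to
2 decimals; recombination values to 1 decimal.

Two embedded published statistics (0.20 for counts 8:18:10 vs 1:2:1, and
0.01 for 17:36:104 vs 1:2:6) do not equal the uncorrected recomputation
(0.22 and 0.05); the reproduction report prints both values with a flag
rather than asserting agreement.

## Recombination estimators

**Recessive-class counting** is the headline estimator because selecting
the class homozygous for the recessive allele removes the lethality
distortion: every surviving *d60*-bearing gamete carries *Gal*, and among
those gametes P(*gw2*) = r exactly, with the two gametes of an individual
independent.  Hence class probabilities ((1−r)², 2r(1−r), r²) and the
counting formula r̂ = (n_het + 2·n_rec)/(2N) — the conditional MLE.  An
estimate above 0.5 is returned as computed with a phase flag, never
clipped silently.

**Maximum likelihood** maximises the multinomial log-likelihood of any
class-count model over r ∈ [0, 0.5]: dense grid (step 1e-4, ties toward
smaller r) then bounded golden-section refinement; the reported support
interval is {r : logL ≥ logL(r̂) − 1} read off the grid (resolution
1e-4, ample for counts of this size).  A flat likelihood raises a
non-identifiability warning.  Phase is assumed known from the pedigree
(coupling); `phase="unknown"` also fits the reversed class order and
reports the better phase.

**Marker-trait scan**: within the trait-recessive class, each marker's
donor-side alleles are the recombinants; missing genotypes shrink that
marker's N and are reported.  **Haldane**: r = (1 − e^(−2d/100))/2; the
round-trip identity holds to 1e-10, and r = 0.176 maps to 21.7 cM.

## The synthetic-data generator

`simulate_population` draws one surviving gamete per parent per offspring
from the exact gamete distribution — the generator and the analytic code
share a single model, so simulated frequencies converge on the analytic
expectations by construction.  One RNG stream per design step, spawned
hierarchically from the seed, keeps earlier generations' draws invariant
when steps are appended.  Selection steps take the first matching
individual (or the whole matching class with `keep="all"`); genotype
predicates are the default because they make a scheme's genetic state
reproducible, while a callable predicate over the trait columns gives
phenotype-based selection with realistic misclassification.

Builtin designs mirror the study's schemes: the F2s (default n = 186,
the printed F2 size), the Koshihikari backcross BCnF2s (n = 112 / 157 as
printed for BC1F2 and BC4F2), the d60-background backcrosses (n = 24 /
94), and the Nipponbare mapping F2 (n = 1484, ≈ 4 × the 371 recessive
segregants scored).  The selected nonrecurrent segregant is idealised as
the *GW2GW2 d60d60 GalGal* double-donor homozygote in coupling; this is
the genotype the scheme's own description implies for the advanced
backcross parents and reproduces the published expectations (1:2:6, 5:4,
6/36, 2/36) exactly.  The default map uses r(GW2, D60) = 0.176 — the
package's own estimate from the embedded counts.

**Markers.** Markers are promoted to ordinary biallelic loci inserted
into the anchor locus's linkage group at their physical position, with
every adjacent r recomputed from physical distance via Haldane at a
configurable factor (default 4 cM/Mb — an order-of-magnitude rice
average, openly arbitrary, used only for toy maps).  The *D60* locus
carries a toy position of 13.5 Mb back-calculated from r = 0.176 at that
factor so the augmented map is internally consistent.  `attach_markers`
re-runs the recorded design under the recorded seed with the augmented
map: marker and trait genotypes in the returned population come from one
joint gamete sampling, so markers literally inherit from the same
haplotypes as the trait loci (the returned realisations supersede the
input population's).  Founders must be inbred at the anchor locus; each
founder receives donor- or recurrent-side marker alleles accordingly.

**Phenotypes.** Traits are class means plus Gaussian noise, deterministic
per seed.  Grain-area means default to 20.0 / 22.0 / 24.6 mm² (anchored
to the published parental means in the isogenic background: ~20 mm² for
the recurrent parent, ~23–29 mm² for donor-allele carriers, heterozygote
intermediate) with sd 0.5 mm²: the published class ranges in the advanced
backcross generations are non-overlapping, implying a within-class spread
comfortably below the ~2.3 mm² between-class gaps, and sd 0.5 reproduces
that separability (≈98% threshold-classification accuracy at the midpoint
cuts of 21.0 and 23.3 mm²).  Culm-length means default to 49 cm
(semidwarf) and 64 cm (long-stem classes), sd 4 cm, matching the printed
semidwarf/long-stem ranges of the final backcross generation.  Fertility
is never sampled: it is the genotype's gamete-survival fraction, and the
"partially sterile" label attaches to fertility < 0.9 (i.e. the 0.75
genotype under the default rule).

**What the generator does not emulate** — and hence what passing tests do
not show about field data: environmental and spatial variance,
genotype-by-environment interaction, measurement error structure beyond
i.i.d. Gaussian noise, segregation distorters other than the modelled
lethality, marker genotyping error, and real physical-to-genetic map
variation along chromosome 2.  Parameter-recovery results transfer to
real populations only insofar as those features are negligible.

## Numerical choices and degenerate inputs

* Probability bookkeeping is exact enumeration over haplotypes (≤ 2^k per
  k-locus group), not Monte Carlo; distributions are renormalised once
  after lethality and checked to sum to 1 within 1e-12.
* A rule that kills every gamete of a parent raises an error rather than
  returning an empty distribution.
* Chi-square with any zero expected class raises a degenerate-expectation
  error; empty tables raise an empty-class error.
* Threshold rules require strictly increasing cuts; values outside a
  bounded rule are counted as unclassified, never dropped silently.
* ML ties (flat stretches of the likelihood) resolve to the smallest r on
  the grid.
* Seeds are plain integers; every derived stream comes from
  `SeedSequence.spawn`, so results are reproducible across platforms with
  the same numpy generation.

## Problem sizes used in the test suite

Simulation-based checks use populations of 157–50,000 individuals and
25–200 replicates per condition: large enough that sampling error is well
inside the asserted tolerances (e.g. 200 × n = 2,000 BC4F2 replicates put
the standard error of the mean r̂ near 0.0005), small enough that the
whole suite runs in seconds.  These sizes are the package's own choice of
demonstration scale.

## Known limitations

* Two-point analysis only: no multipoint/interval mapping, no QTL effect
  estimation, and no physical-position anchoring of markers beyond the
  toy cM/Mb conversion.
* Lethality penetrance is fixed at complete (the 75% fertility figure
  implies it); partial penetrance would need one extra parameter and data
  that do not exist for this system.
* The analytic propagator supports genotype-predicate selection only;
  phenotype-based selection exists only in the sampling path.
* Marker provenance is binary (donor/recurrent keyed to the anchor
  locus), so founders must be inbred lines — segregating founders are
  rejected.
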