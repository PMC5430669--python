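# Methods

This note records the model, the numerical conventions, and the design
choices behind `imabc`, in enough detail that every number the pipeline
prints can be traced to a definition.

## Demographic models and coalescent scaling

Two populations (west, east) split *T* generations ago from an ancestral
population; all three demes share the effective size implied by
θ = 4N<sub>e</sub>μ per site.  Migration is symmetric at *m* migrant
individuals per generation and operates, backwards in time, over
`[0, τ·T)`: τ = 1 gives the ongoing-migration model, *m* = 0 the
isolation model, 0 < τ < 1 secondary contact.  Population-size constancy,
symmetry of migration, and the absence of recombination within loci and
of population growth are assumptions of the model family, not claims
about any real system.

Genealogies are simulated backwards in time in coalescent units with
these conventions (used identically for data generation and inference):

* within-deme pair coalescence rate 1 per time unit;
* N<sub>e</sub> = θ/(4μ) and split depth T<sub>coal</sub> = T/(4N<sub>e</sub>);
* per-lineage migration rate M/2 with M = 4m (Wright's *Nm* reading of
  *m*, matching its "individuals per generation" units; a
  `migration_convention="scaled"` switch exposes M = m instead);
* infinite-sites mutations at rate θ<sub>locus</sub>/2 per unit branch
  length, θ<sub>locus</sub> = θ · scalar · L with L the locus's
  synonymous-site count and `scalar` its relative rate (mean 1 across
  loci);
* at T<sub>coal</sub> all lineages merge into the ancestral deme.

Degenerate inputs are defined, not rejected: *T* = 0 collapses to a
panmictic standard coalescent, and θ = 0 maps to a zero mutation rate
(the genealogy's time scale is then immaterial).  The simulator is
validated against closed forms (pair TMRCA, Watterson's E[S], per-site
heterozygosity) and distributionally against msprime configured at the
same scaled rates, per model, by KS tests on the number of segregating
sites and each Wakeley–Hey component.

The hot path (genealogy, mutation placement, Wakeley–Hey counting,
rejection counting) is compiled with numba; the per-locus object path and
the fused multi-locus kernel share the same kernels and seed discipline,
and a test asserts they produce identical counts seed-for-seed.

## Summary statistics

A site enters the statistics only if it is a synonymous variable site:
every observed in-frame codon variant (ingroup and outgroup) encodes the
same amino acid.  Codons containing gaps, ambiguity codes or stops are
excluded wholesale; variable codons whose variants change the amino acid
are nonsynonymous and ignored; multi-hit codons with mixed effects count
as nonsynonymous (conservative and order-independent).  Reading frames
are inferred by minimising stop codons over the three offsets (ties to
the smallest offset), matching how exon fragments are usually framed.

Polarization uses the outgroup base as the ancestral state.  A site
polymorphic in one population only is private to it (this includes sites
where the other population is fixed for the derived base — the
polymorphism is what is private); polymorphic in both is shared; fixed
requires monomorphism on both sides with different bases, including the
reciprocally fixed case.  Tri-allelic sites, and sites whose outgroup
base resolves no polarity, are unpolarizable and excluded: infinite-sites
statistics are defined for bi-allelic polarized sites.

## Rejection likelihood

The acceptance rule defaults to per-component: each of the four
across-locus sums must lie within ±ε% of its observed value (ε = 25,
40,000 simulations per grid point at study scale).  A grand-total variant
(`total_sum`) is provided for sensitivity analysis; per-component is the
default because it retains the information in the four separate sums.  An
observed component of zero degenerates the rule to "simulated component
must be zero"; this is logged once per grid search.  With zero
acceptances the likelihood is reported as the bound ln(1/n) and flagged,
and the flag propagates into model comparison, where the p-value becomes
an upper bound.

Grid axes default to: *T* every 10⁶ generations in [0, 2×10⁷]; θ every
0.001 in [0.001, 0.01] and every 0.01 in [0.01, 0.1] (the shared 0.01
de-duplicated, 19 values); *m* every 0.1 in [0, 1] and every integer in
[1, 10] (20 values); τ every 10% in [10%, 100%].  Ties at the maximum
resolve to the first point in grid order.  Profile CIs take, per axis
value, the maximum lnL over the other axes and return the outermost
values within 1.92 lnL units of the maximum; an interval end on the grid
boundary is flagged censored rather than silently truncated.

Seeding: each grid point derives one child seed stream from the master
seed keyed by the parameter *values* (not the grid position), so any two
model grids containing the same parameter combination simulate identical
datasets.  This makes the nested-model ordering
max lnL(secondary) ≥ max lnL(ongoing) ≥ max lnL(isolation) exact whenever
the smaller grid is a point-subset of the larger, rather than
exact-in-expectation.

## Model comparison

Twice the lnL difference of nested fits is referred to the boundary
mixture ½χ²₀ + ½χ²₁ (the nested model fixes one parameter, *m* = 0 or
τ = 1, at the boundary of its space): p = ½·P(χ²₁ ≥ 2ΔlnL) for a positive
statistic and p = 1 otherwise, with negative statistics (possible under
Monte-Carlo noise) reported as-is.  The ½/½ weights are exact only for a
single boundary parameter; other `df_diff` values are accepted with a
warning.  A Monte-Carlo check confirms the test is conservative under the
nested model at desk scale.

## Mutation-rate calibration

μ = d̄ / (2·t/g) with d̄ the across-locus mean synonymous divergence to
the outgroup, t = 65 My the outgroup split and g = 1 yr the generation
time (the factor 2 because divergence accrues on both lineages); with
d̄ ≈ 0.35 this gives μ ≈ 2.69×10⁻⁹ /site/generation.  Divergence is a
raw p-distance at 4-fold degenerate sites — no multiple-hit correction,
consistent with the infinite-sites treatment of polymorphism.  Per-locus
scalars are d<sub>i</sub>/mean(d), normalised to mean exactly 1 so that θ
keeps its per-site average meaning.

Synonymous-site counts (the effective sequence length L given to the
simulator) are integer counts of 4-fold degenerate positions judged from
the reference codon (outgroup where available, else ingroup majority).
This undercounts 2-fold sites in real exons; for the synthetic data it is
exact by construction (below), and since the same rule is applied to the
observed and the simulated scale it cancels to first order in the
likelihood comparison.

## Diversity statistics

π is the mean pairwise difference per comparable site (pairwise deletion
of gaps/ambiguity), averaged across loci with gene-length weights; CIs
are 2.5/97.5 percentiles over 5,000 bootstrap resamples of loci (loci,
not sites, are the resampling unit, because the across-locus mean is the
estimand).  Rarefied allelic richness is the exact hypergeometric
expectation Σ<sub>i</sub>[1 − C(N−N<sub>i</sub>, g)/C(N, g)] at depth g,
defaulting to the smallest sampled-allele count across populations and
loci.  F<sub>ST</sub> is Hudson's 1 − H<sub>w</sub>/H<sub>b</sub>
computed from haplotype sequences pooled across loci (differences and
comparable site-pairs summed per population before dividing), chosen over
an AMOVA formulation because it has a simple exhaustive oracle and the
qualitative conclusions are estimator-agnostic.  Its permutation test
shuffles whole individuals (both phased alleles together) to preserve
within-individual structure, with p = (#{F ≥ F<sub>obs</sub>}+1)/(n+1);
pairwise differences are pre-aggregated into per-individual-pair matrices
so the 10,000 default permutations cost only mask indexing.  Comparing a
population against itself excludes self-pairs, making F<sub>ST</sub>
exactly 0 there.

## Synthetic data

`synthdata` emulates the study design: 13 loci with codon-multiple
lengths uniform in [333, 770] bp, 22 west and 26 east phased alleles
(11/13 diploids), lognormal rate scalars (σ = 0.3, normalised to mean 1),
μ = 2.69×10⁻⁹, and a configurable generating model (default: ongoing
migration at θ = 0.002, *T* = 8.5×10⁶, *m* = 0.7 — the parameter regime
the inference defaults target).  The ancestral sequence is a backbone of
codons whose third position is 4-fold degenerate and whose first and
second positions admit no synonymous change, so every codon carries
exactly one synonymous site and no stop can arise; simulated derived
alleles are embedded at randomly chosen third positions (at most one per
codon) and the outgroup adds Poisson(2μ·scalar·t · L/3) substitutions at
third positions disjoint from the polymorphic ones.  Consequences, by
construction: the synonymous filter recovers exactly the simulated
polymorphism; polarization is unambiguous (no back-mutation); and the
pipeline's Wakeley–Hey sums equal the generator's truth file exactly,
which the tests assert across 50 random designs.  A locus that draws more
segregating sites than synonymous positions is re-simulated with a
warning (500-attempt cap), and the count is recorded in the truth file.

What the generator does **not** emulate: intra-locus recombination,
multiple hits and back-mutation, alignment and phasing error, missing
data, selection on synonymous sites, and temporal (multi-year) sampling
structure.  Green tests therefore certify the pipeline's internal
consistency and its statistical calibration under the model's own
assumptions, not robustness to those real-data complications.

## Problem sizes

Defaults mirror the study scale (ε = 25, 40,000 simulations per grid
point, 5,000 bootstraps, 10,000 permutations).  The bundled analysis
drivers and the replicated recovery experiment run at desk scale as this
package's own reporting choice: 1,000–2,000 simulations per grid point,
thinned *T*/*m*/τ axes in the three-model fit, and 10 recovery
replicates; at these sizes the full analysis reruns in minutes on one
CPU.  The recovery experiment profiles only the θ axis (with *T* and *m*
fixed at the generating values) because θ is the axis the grid resolves
well — *T*'s profile is flat at this data size, as its censored CI shows.

## Known limitations

* The rejection likelihood is a grid approximation; nothing interpolates
  between grid points, and MLE ties resolve by grid order.
* Synonymous-site counting ignores 2-fold degenerate positions for real
  alignments (exact for the synthetic design).
* The π denominator uses pairwise-comparable sites, which differs from
  complete-deletion π when missing data are plentiful.
* The F<sub>ST</sub> estimator is Hudson's, not an AMOVA variant;
  absolute values are not comparable across estimators.
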