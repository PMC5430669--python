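# imabc — two-population isolation-with-migration inference by rejection sampling

`imabc` asks a classic conservation-genetics question: when two diverged
populations share alleles, is that retained ancestral polymorphism
(incomplete lineage sorting) or gene flow — and if gene flow, has it been
ongoing since the split or only resumed recently?  It answers it the way a
multi-locus Sanger-era study would: phased exon alignments from two
populations (here labelled *west* and *east*), an outgroup for
polarization, and coalescent simulation under three nested demographic
models

* **isolation** — split *T* generations ago, no migration (*m* = 0);
* **ongoing migration** — split followed by symmetric migration at *m*
  migrants per generation (τ = 1);
* **secondary contact** — migration only during the most recent fraction
  τ of the time since the split.

All three share the per-site polymorphism parameter θ = 4N<sub>e</sub>μ,
assumed equal in the ancestral and both descendant populations.

## The method

Per locus, polymorphism at **synonymous sites** is polarized against the
outgroup and reduced to the four Wakeley–Hey counts: derived polymorphisms
private to the west, private to the east, shared, and fixed between the
populations.  The likelihood of a parameter combination (θ, *T*, *m*, τ)
is approximated by rejection sampling:

> lnL ≈ ln(*a*/*n*), where *a* of *n* simulated multi-locus datasets have
> all four across-locus sums within ±ε% of the observed ones (ε = 25).

Simulation is a structured coalescent with infinite-sites mutation;
per-locus mutation-rate scalars come from synonymous divergence to the
outgroup, and the absolute rate μ is calibrated from the mean synonymous
divergence over a 65-My outgroup split with a 1-year generation time.
The likelihood is evaluated on a fixed grid (*T* every 10⁶ generations in
0–2×10⁷; θ every 0.001 in 0.001–0.01 and every 0.01 in 0.01–0.1; *m*
every 0.1 in 0–1 and every integer in 1–10; τ every 10% in 10–100%).
Profile 95% CIs use the 1.92 lnL-unit rule; when no simulation is
accepted only the upper bound ln(1/*n*) is reported.  The nested models
are compared by likelihood-ratio tests whose null distribution is the
boundary mixture ½χ²₀ + ½χ²₁ (the nested model pins *m* = 0 or τ = 1 at a
boundary).

Alongside the model fit, the package computes per-population
genetic-diversity summaries: nucleotide diversity π with length-weighted
across-locus means and 5,000-replicate bootstrap CIs, rarefied allelic
richness (hypergeometric expectation at the smallest sampled-allele
count), and pairwise Hudson F<sub>ST</sub> with an individual-level
permutation test.

Because studies of this design rarely deposit raw alignments, the package
includes a first-class synthetic-data generator (`imabc.synthdata`) that
emulates the design — 13 exon loci of 333–770 bp, 22/26 phased alleles
per population, per-locus rate scalars, an outgroup — with a truth file,
so the whole pipeline is testable end to end.

## Worked example

```bash
python analysis/01_simulate_dataset.py   # writes results/dataset/
python analysis/02_fit_models.py         # surfaces, MLEs, CIs, model tests
python analysis/03_diversity.py          # pi, richness, F_ST tables
python analysis/04_theta_recovery.py     # replicated recovery experiment
```

Step 01 simulates a dataset under ongoing migration at θ = 0.002,
*T* = 8.5×10⁶ generations, *m* = 0.7 and prints its truth:

```
truth Wakeley-Hey sums: private west = 10, private east = 19, shared = 15, fixed = 0
```

Step 02 fits all three models to it (desk-scale grid, 1,000 simulations
per point) and prints:

```
            model       lnL  lnL_is_bound  theta     T_gen   m  tau
        isolation -6.907755          True  0.001       0.0 0.0  1.0
ongoing_migration -2.322788         False  0.002 2000000.0 0.3  1.0
secondary_contact -2.322788         False  0.002 2000000.0 0.3  1.0

       full_model      nested_model  ...  statistic  p_value  p_is_upper_bound
secondary_contact ongoing_migration  ...   0.000000  1.00000             False
ongoing_migration         isolation  ...   9.169935  0.00123              True
```

Read: no isolation-model simulation matched the data, so its lnL is only
the zero-acceptance bound (ln(1/1000) here); migration is supported over
isolation (p ≤ 0.00123, itself an upper bound), while secondary contact
adds nothing over ongoing migration (p = 1) — gene flow is detected but
its temporal structure is not resolved, and θ is recovered at its
generating value with *T* only bounded below (its CI is censored at the
grid boundary).  Step 03 prints a west–east F<sub>ST</sub> of 0.17
(permutation p = 1e-4) for this structured dataset and 0.004 (p = 0.31)
for a panmictic null pair.

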