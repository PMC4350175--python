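# chemosweep

Simulation and analysis of whole-population (pooled) sequencing time series
from evolving bacterial cultures.

A large asexual population held in a chemostat under constant selection does
not adapt by a tidy succession of fixations. Deep metagenomic sequencing of
such cultures shows many beneficial alleles of the same genes rising
together (*soft sweeps*), occasional single-allele near-fixations (*hard
sweeps*), lineages held below fixation by negative frequency-dependent
selection, mutator genotypes hitchhiking on beneficial backgrounds, and a
large cloud of low-frequency passengers. `chemosweep` is a tested,
end-to-end implementation of that analysis — from raw read preprocessing
and pooled variant calling through trajectory statistics, linkage-cohort
detection and hard/soft sweep classification — driven by a forward
simulator so every stage can be validated against known ground truth.

It is aimed at experimental-evolution and population-genomics researchers
who want either (a) a reference implementation of the pooled-sequencing
analysis rules, or (b) a calibrated synthetic data generator for testing
their own pipelines.

## Model and statistics

**Population model.** Wright–Fisher generations at constant size *N*; a
dilution rate *D* (h⁻¹) sets the clock at 24·*D*/ln 2 generations per day
(3.46 gen/day at *D* = 0.1). Fitness of a genotype is

> w = ∏₍g ∈ mutated driver genes₎ (1 + s_g) × (1 + s_h − c·x_h)

where the driver product counts each gene once (alleles of one gene are
redundant, loss-of-function-like), and the frequency-dependent factor
applies only to carriers of the freq-dep gene that do not also carry a
driver blocked by epistasis; x_h is the current carrier frequency. Against
a neutral resident the freq-dep lineage equilibrates at x* = s_h/c.
Mutations arrive as Poisson events (rate μ per base per generation,
×100 in mutator carriers), are classified as SNP / small indel / large
indel / duplication, and SNP coding effects are annotated by strand-aware
codon translation.

**Sequencing model.** Site depth ~ Poisson(800) by default, reads split
between strands Bernoulli(½), and each read reports the alt allele with
probability f(1−e) + (1−f)·e/3.

**Calling rules.** A mutant allele is reported in a sample iff the site is
covered on both strands, ≥ 3 reads support the allele, and alt/depth ≥ 1%.
The exact detection probability at fixed depth *Dp* is
P(X ≥ max(3, ⌈0.01·Dp⌉))·(1 − 2·(1/2)^{Dp}) with X ~ Binomial(Dp, f) —
0.548 at f = 1% and 800×.

**Preprocessing rules.** Read pairs sharing the same first 20 bases in both
mates are PCR duplicates (first kept); each read is trimmed to its longest
contiguous segment with per-base error 10^(−Q/10) ≤ 0.05 and discarded
unless the segment is longer than 25 bp.

**Sweep analysis.** Trajectories (absent = 0) are clustered by
single-linkage under the L∞ distance with ε = 0.05 into linked cohorts;
non-driver members of driver-containing cohorts are flagged hitchhikers.
Per gene, the verdict is *hard* (one allele from ≤ 1 % or below detection
to ≥ 90 %, no second allele ≥ 10 %), *soft* (≥ 2 alleles each ≥ 10 %),
*incomplete* (one allele stalling in [10 %, 90 %)) or *none*.

## Worked example

```bash
chemosweep all --seed 4 --outdir demo
```

simulates 60 days (208 generations) at the default desk-scale conditions
(N = 10⁶, 100 kb genome, 11 sampling days, 800× pooled sequencing), then
sequences, calls, assembles trajectories and classifies sweeps. Key
outputs (`demo/gene_summary.tsv`, `demo/sweep_calls.tsv`):

```
gene  n_samples_present  n_alleles  peak_freq
mglD  7                  1          0.991
malT  7                  2          0.825
hfq   7                  2          0.158
rpoS  7                  3          0.105

gene  verdict      n_alleles  max_peak
hfq   incomplete   2          0.158
malT  soft         2          0.825
mglD  hard         1          0.991
rpoS  none         3          0.092
```

Read: the `mglD`-class driver fixed through a single allele that entered
below the 1 % detection limit (a hard sweep); two independent `malT`
alleles rose concurrently (a soft sweep); the frequency-dependent
`hfq`-class lineage persisted near its balancing equilibrium without
fixing (incomplete). Outcomes vary by seed — at this population size the
supply of driver mutations is far smaller than in a real 10¹⁰-cell
culture, so runs range from single hard sweeps to multi-allele soft
sweeps. Every run also writes per-mutation trajectories, the occurrence
spectrum, per-day mutational load, cohort membership, hitchhiker flags, a
minimal VCF of calls, and a JSON manifest (config, derived seeds,
checksums) that makes the run byte-reproducible.

The same stages are importable as a library (`chemosweep.popsim`,
`seqsim`, `preprocess`, `varcall`, `trajdyn`, `sweepscan`, `pipeline`),
and each CLI stage can be re-run in isolation on the written files.

## Data dictionary (TSV outputs)

| file | columns |
| --- | --- |
| `truth.tsv` | mutation_id, position, ref, alt, mut_class, gene, effect, role, lineage_id, one true-frequency column per sample day |
| `linkage.tsv` | mutation_id, lineage_id (genotype of origin) |
| `site_counts.tsv` | mutation_id, sample_day, depth_fwd, depth_rev, alt_fwd, alt_rev |
| `calls.tsv` | mutation_id, sample_day, alt_count, alt_fwd, alt_rev, depth, frequency, strand_ok, support_ok, freq_ok, passed |
| `trajectories.tsv` | metadata plus one estimated-frequency column per sample day (0 = absent) |
| `occurrence_spectrum.tsv` | n_samples_detected, n_mutations |
| `load.tsv` | sample_day, SNP, S-indel, L-indel, duplication, total |
| `gene_summary.tsv` | gene, n_samples_present, n_alleles, peak_freq |
| `cohorts.tsv` | cohort, mutation_id, n_members, driver_genes |
| `sweep_calls.tsv` | gene, verdict, n_alleles, max_peak |
| `hitchhikers.tsv` | mutation_id, cohort_index, driver_genes |
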