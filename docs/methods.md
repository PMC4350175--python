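# Methods

## The population model

The simulator is a discrete-generation Wright–Fisher model of an asexual
population at constant size *N*, standing in for a chemostat culture at
steady state. Continuous culture time is mapped to generations through the
dilution rate: at steady state growth balances dilution, so the population
doubles every ln 2/*D* hours and a day contains 24·*D*/ln 2 generations
(3.4625 at *D* = 0.1 h⁻¹; a 60-day course is 208 generations). Samples are
taken at the generation nearest each configured sampling day.

Each generation has two phases. *Selection/drift*: offspring counts are
drawn from one multinomial with probabilities proportional to
count × fitness, which conserves *N* exactly. *Mutation*: each lineage
acquires Poisson(count · μ·L) new mutation events (μ·L·mutator_fold for
mutator carriers); each event creates a new genotype carrying one new
mutation. Co-occurrence of two new mutations in one cell within one
generation is neglected (the per-genome rate μ·L ≪ 1), the standard
infinite-sites-style simplification.

Fitness is multiplicative over *distinct mutated driver genes* — the
benefit is loss-of-function-like, so a second allele of an already-mutated
gene adds nothing. This is what makes multi-allele soft sweeps of one gene
mutually redundant and is the reason allele number, not allele identity,
carries the signal. The frequency-dependent lineage multiplies its fitness
by (1 + s_h − c·x_h), where x_h is the current total frequency of carriers;
the factor is clipped at zero. Against a neutral resident the deterministic
recursion x' = x·w_h/(x·w_h + 1 − x) has the balancing fixed point
x* = s_h/c, which `freq_dep_equilibrium` iterates to convergence.
Epistasis is modelled as nullification: a genotype carrying both the
freq-dep mutation and a driver mutation in any gene listed in
`epistasis_genes` receives no freq-dep factor at all, in either order of
acquisition, so such double mutants behave as plain driver genotypes and
freq-dep mutations arising on those backgrounds drift as passengers.

Coding effects of SNPs are annotated by translating the affected codon
(standard genetic code, strand-aware) before and after the change. Stop
gain and stop loss count as nonsynonymous, as does disruption of the start
codon. Indels and duplications are carried as abstract records with effect
"noncoding" and are never pushed through codon logic; an indel landing on
a driver target site still activates the driver role (gene inactivation).
Each gene exposes `n_target_sites` positions, spread evenly across it, at
which a nonsynonymous SNP or an indel confers the gene's role; hits
elsewhere are passengers.

## Default study conditions

| parameter | default | meaning |
| --- | --- | --- |
| N | 10⁶ | population size (desk-scale stand-in for ~1.6×10¹⁰ cells) |
| genome_length | 100 kb | compact stand-in for a 4.6 Mb chromosome, ~90 % coding |
| μ | 5×10⁻⁹ /bp/gen | chosen so the whole-genome rate μ·L = 5×10⁻⁴ supplies several independent driver alleles within 208 generations |
| mutator_fold | 100 | genome-wide rate multiplier of the mutator lineage |
| D | 0.1 h⁻¹ | dilution rate; 3.46 generations/day |
| duration, samples | 60 days, days 5–60 | 11 sampling days (5, 7, 14, 20, 28, 35, 40, 45, 50, 56, 60) |
| driver s | 0.15 / 0.12 strong, 0.10 late | free parameters; strong drivers sweep within ~30 days at these values |
| s_h, c | 0.2, 1.0 | freq-dep benefit when rare and its decay slope (x* = 0.2) |
| mean_depth | 800× | pooled sequencing depth, Poisson by default |
| base_error_rate | 0.001 | per-base; effective error toward the tracked alt allele is e/3 |
| class fractions | 0.98158 / 0.01658 / 0.00147 / 0.00037 | SNP / S-indel / L-indel / duplication arrival proportions |

The 11 sampling days are not canonical — published studies of this design
report 11 samples over 60 days without listing the days — so they are
spread to cover early sweeps densely enough and are fully configurable.
Driver selection coefficients are likewise free parameters: the underlying
experiments report which genes are strongly beneficial but not numerical
fitness effects.

The default gene set carries one instance of each role: three strong
drivers with many redundant target sites (30/30/60 — the multi-allele
soft-sweep substrate), a late driver with 12 sites, a single-target-site
late driver (the hard-sweep candidate: with one adaptive position the gene
can essentially only sweep through a single allele), a freq-dep gene, a
mutator, and neutral filler genes tiling ~90 % of the genome so that the
annotated synonymous/nonsynonymous/noncoding split of passenger SNPs is
realistic for a dense bacterial chromosome.

## What the generator emulates, and what it does not

Emulated: constant-size continuous culture, clonal interference among
driver lineages, multi-allele redundancy within driver genes, epistatic
exclusion of the freq-dep lineage from one adapted background, a
fitness-neutral mutator raising its lineage's mutation supply 100-fold,
abundant neutral passengers, strand-split pooled sequencing with Poisson
depth and symmetric base errors, and planted PCR duplicates/quality flanks
in raw read pairs.

Not emulated: the real population and genome scale (N is ~10⁴-fold
smaller, the genome 46-fold shorter). Consequences: genetic drift and
winner-take-all dynamics are much stronger, the supply of simultaneous
driver mutations is smaller, and a 1 % detection threshold corresponds to
10⁴ rather than 10⁸ cells. Desk-scale runs therefore show between one and
a handful of concurrent sweeps and a few dozen detectable mutations, not
thousands, and early samples may predate the first detectable sweep
entirely. Passing tests demonstrate the correctness of the machinery and
the recoverability of planted structure, not that real cultures behave
like the scaled model. Also not modelled: fragment-level read simulation
(site counts are drawn directly), mapping artefacts, indel realignment,
library over-dispersion (depth is Poisson; real libraries are wider),
spatial structure and cross-feeding.

## Preprocessing and calling rules

Duplicate removal keys each pair on (read1[:20], read2[:20]) — both mates
must match, mate order matters, first occurrence wins, order is preserved,
and reads shorter than 20 bp contribute their whole sequence. Trimming
keeps the longest contiguous run with per-base error 10^(−Q/10) ≤ 0.05,
leftmost on ties, and rejects reads whose best run is not *strictly*
longer than 25 bp (kept iff ≥ 26). "Probability ≤ 0.05" is the trimming
convention of the classical Phred-segment tools; dedup runs before
trimming so the key sees untrimmed 5′ ends, and a pair is dropped whole if
either mate fails trimming.

A site is called in a sample iff covered by ≥ 1 read on each strand, ≥ 3
reads support the mutant allele, and alt/depth ≥ 0.01. "Both strands" is
interpreted as site *coverage* on both strands (a
`require_alt_both_strands` switch provides the stricter reading, off by
default since the filter is attached to positions, not alleles). Absent
calls become frequency 0 downstream — an undetectably rare allele, never
missing data — which keeps trajectories totally ordered and distances well
defined. The closed-form detection probability assumes fixed depth; the
sequencing model offers `depth_law="fixed"` so Monte-Carlo checks match
the formula's assumptions exactly (under Poisson depth the threshold
⌈0.01·D⌉ shifts with D and the marginal pass rate near f = 1 % is a few
points lower). Conditioning on passing biases called frequencies upward
near the threshold (winner's curse); the unconditional estimator alt/depth
is unbiased.

## Sweep analysis choices

Cohorts use the L∞ distance because linkage is evidence about *levels*:
two mutations in the same genome must have near-identical frequencies at
every sampled day, not merely correlated shapes. Single linkage matches
the transitivity of same-genome evidence; its chaining risk is mitigated
by clustering only mutations that ever reach `min_peak` = 0.05. ε = 0.05
is roughly 3–4 standard deviations of the difference of two 800×
frequency estimates at mid frequencies; there is no published quantitative
threshold to match, so ε is validated against planted simulations only and
exposed as a flag. Clustering and the dominant-allele succession both
break ties by mutation id, making every output order-independent.

The verdict thresholds (90 % / 10 % / 1 %) encode the verbal definitions
of near-fixation, substantial presence and the detection limit; all are
configurable. The hard-sweep origin condition accepts an allele whose
first *observed* frequency is ≤ 1 % or which was absent at the first
sampled day (origin below detection); a single allele already abundant at
the first sample cannot be distinguished from standing variation and is
not called a de novo hard sweep. When exactly one allele exceeds 10 % but
its origin disqualifies "hard" and its peak is below 90 %, the verdict is
"incomplete"; with a peak ≥ 90 % and a disqualified origin it is "none".

Gene-level summed allele frequencies are capped at 1.0 with a logged
warning: a raw sum above 1 implies two alleles of the gene in one genome
(or correlated estimation error) and is reported rather than silently
truncated. Gene summaries count a gene when at least one nonsynonymous
allele is detected on ≥ 3 days — the "three or more time points"
convention — and report the peak of the *summed* allele frequency, so a
gene served by successive alleles shows its true total sweep size.

## Validation experiments

The planted-lineage generator seeds lineages with known fitness, initial
frequency and private mutations, and runs the same multinomial engine with
mutation switched off, so linkage ground truth is exact. The linkage
benchmark panel uses three beneficial lineages (s = 0.06/0.12/0.18, seeded
at 10⁻³) plus a neutral lineage at 10 %, three private mutations each;
recovery is scored as the Rand index between recovered cohorts and true
lineages over mutations peaking ≥ 0.05, with unclustered mutations as
singletons. The linked-pair check uses a strongly beneficial lineage
(s = 0.2, the freq-dep benefit scale) whose sweep traverses mid
frequencies quickly — trajectories linger where binomial noise is widest
otherwise, which is exactly when linkage inference is genuinely hard.
Planted classifier regimes seed alleles at 10⁻³ (≈100 copies at N = 10⁵:
establishment is near-certain but the lineage stays well below the 1 %
detection limit for the first samples) with s ~ U(0.055, 0.085) so hard
sweeps complete within the 208-generation course; soft regimes seed two
alleles of equal benefit independently.

Statistical tests use 3-standard-error bands around analytic expectations
(binomial tails, the drift martingale, the one-step selection recursion
x(1+s)/(1+sx)), a one-sided rank test for the monotonicity of sweep times
in s, and exact equality against brute-force oracles for trimming,
deduplication and the L∞ distance. Problem sizes (N = 10⁵, 50–200
replicates, 10⁵ Monte-Carlo draws) were chosen so the full suite completes
in well under a minute of simulation time while keeping the 3-SE bands
narrow enough to be informative.

## Reproducibility

A single root seed drives everything: per-stage generators are derived
through `numpy.random.SeedSequence.spawn`, recorded in the run manifest
along with SHA-256 checksums of every tabular output, and re-running a
config with the same seed reproduces the TSVs byte for byte. The genome
sequence is drawn from its own fixed stream so that lazy construction
cannot perturb mutation sampling.

## Known limitations

Allele-frequency trajectories of *different* lineages are treated as
independent at the sequencing step (no shared library noise). The mutation
phase caps events per genotype at its offspring count, a negligible bias
at realistic μ·L. Large indels and duplications are abstract records —
no breakpoint or copy-number modelling. The freq-dep factor uses global
carrier frequency, not pairwise interaction terms. Verdicts are
deterministic functions of noisy trajectories; no uncertainty is attached
to a verdict. At the default scale, run-to-run variability in which driver
gene wins is large — that is a property of the scaled system, not a bug.
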