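# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the design decisions that were genuinely open.

## Genotype analysis

A genotype table holds one row per fish: population, field-observed
reproductive ecotype ("shore" or "stream"), and the diploid genotype at
the diagnostic G/T SNP (GG, GT, TT, or NN for missing). Allele
frequencies are p_G = (2·n_GG + n_GT) / (2n) with NN excluded from every
denominator (never imputed); populations with no non-missing genotypes
are dropped from summaries.

The Mendelian assignment rule is GG → shore, GT or TT → stream, NN →
unassigned. Accuracy is the percentage of non-missing individuals whose
prediction matches the field label; unassigned fish are excluded from
the denominator because the survey's counts are over genotyped
individuals. Reports pool the three miscall classes (GG among
stream-labelled, GT and TT among shore-labelled fish).

Two F<sub>ST</sub> estimators are shipped because the choice is
consequential at extreme frequencies and sample-size imbalance:

- **Nei G<sub>ST</sub>** = 1 − H_S/H_T with *unweighted* means: H_S is the
  average of the two within-population expected heterozygosities and H_T
  uses the unweighted mean allele frequency. This matches the classical
  definition, keeps hand-checked examples exact, and is bounded in [0, 1].
- **Weir–Cockerham (1984)** variance components a (among populations),
  b (between individuals within populations), c (within individuals),
  computed from genotype counts (observed heterozygosity enters through
  h̄); the estimate a/(a+b+c) is reported unclamped and may be slightly
  negative when populations are effectively undifferentiated.

When both populations are fixed for the same allele, H_T = 0 and
F<sub>ST</sub> is undefined; the result is flagged rather than coerced.
LD between phased biallelic sites is the standard r² = D²/(p_A q_A p_B q_B);
monomorphic sites are flagged undefined, and "full linkage" means r² = 1
for every defined pair.

## Alignment and sweep profiling

The two alleles are aligned with Needleman–Wunsch/Gotoh dynamic
programming: match +5, mismatch −4, affine gaps costing
open −12 + length × extend −2 per run, and *free end gaps* (terminal
runs in either sequence cost nothing). The published analysis used a
commercial aligner's "93% similarity" preset, which fixes no reusable
scoring scheme; these values are a standard nucleotide scheme and are
exposed in configuration. Traceback is deterministic: ties prefer
diagonal, then gap-in-B (reference base over a gap), then gap-in-A, and
within a gap state extension over opening; at the free trailing end the
full-span corner is preferred, then the shortest trailing gap. The DP
fill is a numba kernel with a single packed uint8 traceback matrix, so
two ~23 kb alleles align in seconds within ~0.5 GB. `N` never matches
and scores as a mismatch.

Variant calls are reported on the reference (first) allele, 1-based. A
maximal run of contiguous gap columns is **one** indel event whatever its
length — indels are counted as events, not columns — and terminal
free-end runs produce no calls. VCF output anchors indels on the
preceding reference base (or the following base for an event at
position 0).

Percent divergence is 100 × (non-identical internal columns) / (internal
columns), where gap columns count as non-identical and terminal free-end
runs are excluded. This is one consistent reading of a summary figure
whose convention is not fully specified; a `count_gap_columns=False`
switch restricts the statistic to substitution columns. Window
similarity is the percent of identical columns in a w-column window
centred on each column (default w = 500; even widths take the extra
column on the right; windows shrink at the edges rather than emitting
missing values, and a window wider than the alignment broadcasts the
single global value).

Within-group variable sites use an inclusive minor-allele-frequency
threshold: a site is variable in a group when its MAF ≥ 0.25 among that
group's haplotypes; a fixed difference requires both groups below the
threshold with differing consensus (majority; ties alphabetical) bases.

Coding effects translate SNPs through the standard genetic code after
splicing the exon intervals (1-based, inclusive, ordered,
non-overlapping; strand and frame offset respected; coding length minus
frame must be divisible by 3). Exonic indels are flagged frameshift when
length mod 3 ≠ 0.

## Clock dating

The dating model is deliberately minimal: a fixed 3-taxon topology
((shore, stream) at t_split, outgroup at t_cal) with a strict clock.
The published analysis used a relaxed lognormal clock and a Yule tree
prior inside a full Bayesian phylogenetics engine; with a single
calibration and three taxa that machinery is unidentifiable overkill,
and the strict-clock fixed-topology model is the identifiable desk-scale
case. The substitution model is HKY85 with fixed equilibrium frequencies
and sampled κ; transition probabilities use the closed-form (TN93-style)
expressions, verified against `scipy.linalg.expm` to 1e-12. The rate
matrix is normalised to one expected substitution per site per time
unit, so branch lengths are clock_rate × time.

Pairwise HKY distances are maximum-likelihood: the log-likelihood
derivative in t is analytic (P(t) is affine in two exponentials) and its
root is bracketed with `brentq` to machine precision, which makes the
JC69 and K80 closed-form reductions exact to 1e-10. Distances beyond
t = 50 are reported as saturated (+inf).

The sampler is Metropolis–Hastings over (t_split, t_cal, clock_rate, κ)
with multiplicative scale proposals (Hastings-corrected), one parameter
per iteration. Priors: t_cal ~ Normal(11.4, 0.8163) My — the sd chosen
so the central 95% spans the published 9.8–13 My calibration interval;
t_split | t_cal ~ Uniform(0, t_cal); clock_rate ~ log-uniform on
[1e-6, 1e-1] subs/site/My; κ ~ LogNormal(μ=1, σ=1) on log κ. These rate
and κ priors are weakly informative choices the source analysis left
open; all are configurable. Defaults: 3 chains × 200,000 iterations,
25% burn-in, thinning 20, pooled after an arviz R-hat/ESS check — a
desk-scale setting adequate for a 4-parameter model (generation counts
quoted for full phylogenetics engines are not meaningful here). Gapped
or ambiguous alignment columns are excluded (HKY is substitution-only),
and site patterns are compressed to ≤ 64 triples so likelihood cost is
independent of alignment length. A prior-only run (no data) exactly
recovers the calibration prior, which the tests exploit.

The 95% HPD is the shortest contiguous interval containing
⌈0.95·n⌉ sorted samples, ties broken by earliest start, checked against
exhaustive search. Because it is not stated whether the published TMRCA
is a posterior mean or median, summaries report both.

## Synthetic generator

The generator is the package's study-conditions definition, not a test
fixture. An ancestral sequence is drawn i.i.d. from the HKY equilibrium
frequencies (stationarity); lineages then evolve along the 3-taxon clock
tree: root → outgroup (t_cal), root → ingroup ancestor (t_cal − t_split),
ancestor → shore and ancestor → stream (t_split each). Substitutions are
endpoint-sampled per site from P(clock_rate · t) — multiple hits are
thereby handled exactly — and logged per branch as net changes. Indels
are deletions only (relative to each branch's entering sequence),
Poisson(indel_rate · t · L) per branch, geometric lengths capped at
400 bp; deletion-only keeps true-event bookkeeping unambiguous.
Within-group polymorphism is site-independent: each site is polymorphic
with probability theta_within, carrying one alternative base at a
uniform random minor count — adequate because the analyses consume only
site counts, not haplotype structure.

Default scenario (chosen once to mirror the study region, with the
reasoning below): L = 22,773 bp; t_split = 3.8 My; t_cal = 11.4 My;
clock_rate = 9.2e-4 subs/site/My, which gives ≈ 158 expected fixed
substitutions between the alleles over the 7.6 My of separating branch
length — the observed 181 fixed differences minus the 23 indel events;
indel_rate = 1.33e-4 events/site/My (≈ 23 expected shore–stream indel
events); geometric length parameter 0.026 (mean ≈ 38 bp, max 400,
consistent with multi-bp indels up to ~308 bp and ≈ 880 expected gap
columns, putting column-level divergence near 4.6%); theta_within =
4.4e-4 (≈ 10 variable sites per allele class); κ = 3.0 (a typical
vertebrate nuclear transition bias); base frequencies (0.3, 0.2, 0.2,
0.3) (mild AT richness). Genotype tables draw each individual as two
independent Bernoulli(p_G) alleles (Hardy–Weinberg) at the packaged
per-population frequencies.

What the generator does **not** emulate: recombination (the real region
presumably recombines; the sweep analysis treats the alleles as
non-recombining haplotypes), selection itself (only its outcome — deep
divergence — is modelled), coalescent genealogy within groups, insertion
events, sequencing error, and rate variation among branches or sites.
Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness of the biological
conclusions to these violations. In particular, real-data dating
inherits the caveat that a region under selection violates the neutral
clock; the synthetic recovery results quantify estimator behaviour, not
that bias.

## Problem sizes used in tests and the acceptance script

The acceptance script runs every stage at full scale: the 22,773 bp
scenario, three ~23 kb alignments (shore–stream, and shore/stream vs
outgroup for the dating frame) and the default 3 × 200,000-iteration
MCMC. The test suite uses smaller instances chosen for statistical
adequacy: the alignment oracle enumerates all alignments for sequences
up to length 8; likelihood oracles use 20 bp toys; the HPD-coverage
check runs 20 replicates at L = 3,000 with 30,000-iteration chains
(shorter chains only add Monte-Carlo error to the coverage estimate);
prior-recovery uses 2 × 30,000 iterations. Divergence calibration
compares 20 replicates at L = 10,000 against the matrix-exponential
expectation within three standard errors.

## Known limitations

- The aligner's O(nm) memory (one packed byte per cell) limits practical
  inputs to ~50 kb × 50 kb; the target region is ~23 kb.
- Adjacent opposite-sequence gap columns are not representable in the
  DP's transition set; under the default scoring such alignments are
  always strictly suboptimal, but exotic scorings where a double gap
  beats a mismatch would need a different state machine.
- The dating frame projects the three sequences onto columns where all
  carry a base (via two pairwise alignments to the shore allele); with
  deletion-only indels this recovers homologous columns well, but it is
  not a joint multiple alignment.
- The Weir–Cockerham estimator is implemented for the two-population
  biallelic case the analysis needs, not the general r-population,
  multi-locus form.
- `hpd_interval` requires ≥ 20 samples and assumes a unimodal enough
  posterior for a contiguous interval to be meaningful.
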