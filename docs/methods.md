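# Methods

## The model

`motiffoot` analyzes short mutable motifs — the sequence contexts
preferred by mutator enzymes such as the cytosine deaminase AID
(consensus WRC/GYW) and the translesion DNA polymerases eta (WA) and
theta — with mononucleotide weight matrices rather than consensus
strings.

Given a collection of mutation sites aligned on the mutated base,
nucleotide frequencies `f(b, j)` are tallied at positions
`j = -5..+5`.  The background `e(b)` is the mean of `f(b, j)` over the
outermost positions `{-5, -4, +4, +5}`, i.e. flanks assumed far enough
from the lesion to be context-neutral.  The weight matrix is

    W(b, j) = log2( f(b, j) / e(b) )

A candidate site's matching score is `S = sum_j W(b_j, j)` over the
scoring span `j = -3..+3` (center included), normalized to a percent
scale by the minimal and maximal attainable sums over that span:

    percent = 100 * (S - Smin) / (Smax - Smin)

Throughout the package "weight" means this percent matching score.

### Strand convention

Matrices are defined with the pyrimidine (C) at the center for the G:C
site class and with A at the center for the A:T class.  A G-centered
(or T-centered) site is scored on the reverse complement of its
11-mer, which is exactly the WRC/GYW symmetry of the motif notation.
Palindromic contexts therefore score identically on both strands
(asserted in tests).

### Association test

For every base substitution the 121-bp reference slice centered on it
(the DNA neighborhood) is extracted.  Group 1 holds the percent
weights at the mutated central positions; group 2 pools the weights at
every non-mutated position of the same class across all neighborhoods
(offsets within 5 bp of a window edge are excluded so each candidate
has a full scoring context).  Three numbers summarize the contrast:

- **ratio** = mean(group 1) / mean(group 2);
- a **two-tailed Welch t** statistic (the unequal-variance form; a
  pooled-variance option exists);
- a **one-tailed Monte-Carlo p**: 10,000 random subsets of group 2 of
  size |group 1| are drawn without replacement within each subset, and
  the p-value is the fraction of subset means that reach mean(group 1),
  floored at 1/10,000 when the count is zero.

An association is called significant when *both* tests fall below
alpha = 0.05.  Because this is an intersection of a two-tailed and a
one-tailed test, the joint rule is mildly conservative under the null:
its analytical rejection rate lies between alpha/2 and alpha, and
measured rates in our null simulations fall in 0.025-0.05.

The Monte-Carlo subset sampler draws a slightly over-long i.i.d.
index stream per replicate and keeps its first k distinct values; this
yields exactly uniform without-replacement subsets (the first
occurrences of an i.i.d. uniform stream form a uniform random
permutation prefix) while staying fully vectorized.  Dense draws
(k > m/2) sample the complement instead.

### Shuffled-matrix control

The false-positive behavior of the whole chain is estimated by
independently permuting the flanking bases of each source window
(center fixed, per-window base multisets conserved), rebuilding the
frequency and weight matrices, and re-running the association test.
Note that replicates of this control share the target mutation
catalog, so a single-catalog false-positive estimate is heavily
overdispersed relative to binomial sampling: catalogs with an
unusually large (or small) composition contrast reject shuffled
matrices much more (or less) often than alpha.  Calibration checks
therefore pool control replicates over independent simulated
catalogs; pooled rates match alpha closely, single-catalog rates need
not.

### Matrix comparison

Two mutation collections are compared by a Pearson chi-square summed
over the ten flanking positions (the 2x4 table of base counts per
position; the central column is excluded because it is fixed by the
site class).  Under the per-position convention the degrees of freedom
are 10 x (4 - 1) = 30; a legacy "positions x 4" convention (df = 40)
is selectable because published tables sometimes use it.  The
statistic itself is convention-independent, and the df = 30 version is
the one that calibrates correctly in null simulations (rejection rate
0.05 +/- 0.01 at alpha = 0.05).

## Methylation analyses

Bisulfite coverage records (per-strand cytosine read counts) are
pooled across samples by summing reads per position, filtered to
`total_reads >= 10` ("more than nine reads"), and converted to the
methylation ratio `100 * meth/total`.  Because no natural control set
exists for CpG methylation, sites are contrasted across ratio
thresholds of 25% and 75%: at 25% group 1 is the hypo-methylated side
(ratio < 25), at 75% the hyper-methylated side (ratio > 75); both
inequalities are strict, ties fall in group 2.  The ratio/t/MC
machinery above is then applied to the motif weights of the two
groups; when group 1 is the larger side, the MC test resamples
size-|group 2| subsets from group 1 and the one-tailed direction still
follows group 1's mean.

For CpG sites coinciding with somatic mutations, a mutation matches a
CpG when its position equals either base of the dyad (CpG symmetry
makes either hit biologically equivalent).  The analysis reports the
counts above/below the 75% threshold, the fraction below, and the
weight contrast between the below- and above-threshold mutated sites
(group 1 = below, per the reading that the motifs correlate with the
less methylated mutated sites; the opposite orientation is the
reciprocal of the reported ratio).

## Driver / non-driver classification

Prediction tables are consumed, not produced: each recurrent mutation
(>= 2 carriers by default) carries two MutaGene background-model
labels and a CHASMplus score.  A mutation is a *driver* when MutaGene
calls it driver/potential-driver (either model by default — together
with the score cutoff this still satisfies at least two criteria; a
stricter both-models mode exists) *and* its CHASMplus score exceeds
0.5.  It is a *passenger* only when both MutaGene labels are
passenger/neutral and the CHASMplus score is present and at or below
the cutoff; anything else (including missing scores) is *unresolved*.
A driver gene has at least one recurrent driver mutation; a non-driver
gene has only recurrent passenger mutations; genes with any unresolved
recurrent mutation join neither set, so the sets are disjoint by
construction and shrink monotonically as the score cutoff rises.

Expression is compared on per-gene summaries across samples: a Welch t
on `log2(mean FPKM + 1)` for the means, and for the variances either a
Welch t on log per-gene variances (default) or a classical
variance-ratio F on the pooled gene-centered log2 values.

## The synthetic-data generator

The generator emulates the statistical structure of a lymphoma-like
cohort study; it makes no attempt to reproduce real genomic sequence.

- **Genome**: i.i.d. bases at 42% GC over a 100-kb contig (a
  first-order chain up/down-weights CpG dyads when requested).
- **Mutations**: 500 substitutions over 26 samples, drawn without
  replacement from the class-eligible sites with probability
  proportional to `exp(lambda * percent/100)` under a planted matrix.
  The exponential-in-percent form makes the bias intensity `lambda`
  comparable across matrices; `lambda = 2` is the "signal present"
  condition and `lambda = 0` the null.  Sites are kept 60 bp from
  contig ends so every simulated mutation has a full neighborhood.
- **Planted matrices**: WRC-like (deaminase), WA-like (polymerase
  eta), and an anti-correlated SYC control, each built from 2,000
  windows sampled under the stated composition profiles.
- **Methylation**: every CpG cytosine (both strands) draws a latent
  ratio from a two-mode beta mixture — Beta(2, 18) low mode,
  Beta(20, 2) high mode, high-mode weight 0.84, chosen so the cohort
  mean is ~78% — then Poisson(30) total reads (floor 1) and binomial
  methylated reads.  A coupling parameter shifts high-weight sites
  toward the low-methylation mode, the structure the threshold
  association is designed to detect.
- **Predictions/expression**: a planted 20-gene driver subset receives
  driver-consistent labels and scores and a 4-fold inflated
  across-sample log-normal expression variance; all other genes carry
  only passenger-consistent recurrent mutations.

What the generator does *not* model: chromatin context, replication
timing, regional mutation-rate covariates, read-level bisulfite
errors, copy-number distortion of methylation estimates, or linkage
between neighboring CpGs.  Passing tests therefore demonstrate that
the estimators recover planted structure under their own model
assumptions, not that those assumptions hold in real tumors.

## Numerical choices and degenerate inputs

- Add-0.25 pseudocounts per matrix cell (one pseudo-observation per
  column) keep all frequencies positive before the log; raw counts are
  preserved untouched for the chi-square comparison.
- A constant (all-zero) weight matrix has Smax = Smin; every percent
  score is then defined as 50 and flagged, the ratio is exactly 1, and
  tests report t = 0, p = 1.
- Non-ACGT bases anywhere in a scoring span invalidate that candidate
  only; invalidated candidates, edge exclusions, and reference
  mismatches are counted in an exclusion census that must sum back to
  the input size.
- Welch t degenerate cases (zero variance) map to t = 0, p = 1 rather
  than NaN.
- UPGMA clustering uses Euclidean distances with average linkage;
  NaN cells are imputed with the row mean and flagged.

## Problem sizes used in the checks

Simulation-based checks run at the defaults above (100-kb genome, 500
mutations) with 200 replicates for null calibration, 50 per arm for
power, 200 pooled shuffle-control replicates over 40 catalogs, and
10,000 Monte-Carlo resamples per test; the Monte-Carlo estimator is
validated against exhaustive subset enumeration for contrast groups of
up to 12 values.

## Known limitations

- The neighborhood design corrects for local composition only; it
  inherits the assumption that 121 bp is "local enough".
- Other mutated positions falling inside a window are not removed from
  the non-mutated candidate pool; at realistic densities the
  contamination is negligible.
- Per-sample analyses require at least two scoreable mutations per
  sample; smaller samples are skipped and logged.
- The package consumes externally produced driver predictions and
  does not run MutaGene or CHASMplus itself.
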