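# Methods

`ervpop` implements the computational pipeline for studying a full-length
endogenous retrovirus (ERV) insertion segregating in a natural population:
annotating the element, dating it by LTR divergence, contrasting diversity
between carrier and non-carrier haplotype classes, scanning for case-control
association with permutation-calibrated significance, inferring the insertion
time by simulation grid search under drift, testing the trait frequency
conditional on establishment, and profiling CpG methylation across the
element. This note records the models, the defaults and why they were chosen,
the numerical conventions, and the known limits of what the synthetic-data
tests demonstrate.

## Models and procedures

### Wright-Fisher drift and the carrier genealogy (`wright_fisher`)

A new insertion is one chromosome copy arising `T` generations before present
in a diploid population whose size `N(t)` is piecewise-constant (the
`Demography` type; epochs are user-supplied, time in generations before
present). Copy counts evolve by binomial resampling:
`c(t-1) ~ Binomial(2N(t-1), c(t)/(2N(t)))`. Loss is absorbing; selection is
absent throughout (the inference model is drift-only), which gives the
martingale `E[p_final] = 1/(2N)` used as a correctness check.

Conditioning on survival is by rejection sampling. Batches of trajectories
are simulated with lost replicates compacted away each generation; because a
critical branching process survives to generation `t` with probability
~`2/t`, the expected per-replicate cost is logarithmic in `T`, making even
survival probabilities of ~1/2000 cheap.

Sampled carrier haplotypes are *not* tracked forward. Their genealogy is
drawn backward conditional on the copy-count trajectory: with `k` open
lineages, pairs coalesce at per-generation rate `C(k,2)/c(t)`, waiting times
are drawn by inverting the accumulated hazard (O(events x log T)), and any
lineages still open at `T` join the founding copy there. This is the
standard trajectory-conditioned coalescent for an allelic class and is
equivalent in distribution to forward tracking for binary mergers; the test
suite cross-checks it against a brute-force forward simulator that tracks
every carrier copy's mutation set (agreement in mean sample segregating
sites within Monte-Carlo error). The exponential-hazard waiting times and
the binary-merger restriction are approximations to the discrete
Wright-Fisher process that matter only when `c(t)` is very small; the
forced multifurcation at `T` absorbs the extreme case.

Mutations drop on the genealogy as a Poisson process (infinite sites):
flanking sequence at rate `mu * flank_length` per lineage-generation, and
each of the element's two LTR copies independently at `mu * ltr_length`,
so the expected per-site distance between a carrier's LTRs is `2*mu*T`.

### Synthetic data (`synthetic_data`)

*Planted genomes.* `make_erv_genome` inserts an element (single LTR sequence
duplicated at both ends, internal region with codon-exact planted ORFs) into
a uniform-random background and duplicates the `tsd_len` bases at the target
site on both flanks, exactly as retroviral integration does. The truth
record carries every coordinate. `default_construct` builds a realistic
~10 kb element (600 bp LTRs, 9 kb internal region, three 600-codon ORFs,
TSD "TAGTTA"). Two deliberate properties make planted truth exactly
recoverable: spacers are ATG-free, so each planted ORF's first in-frame
start codon is the planted one; and the internal region's terminal bases are
forced to differ from the target-site bases, so the maximal exact terminal
repeat is precisely the planted LTR pair.

*Populations.* `simulate_population` combines a trajectory (conditioned or
not), the carrier genealogy with flank and LTR mutations, and a neutral
background. Non-carrier haplotypes (and the founding carrier haplotype) come
from a standard Kingman coalescent parameterised directly by a target
per-site diversity (default `background_pi = 0.002`, a typical vertebrate
nuclear value); simulating deep history would add cost without changing the
carrier/non-carrier contrasts the statistics need. Loss before the present
is returned as a status, not an exception, so establishment conditioning
remains possible downstream. There is no recombination exchange between
carrier and non-carrier classes: carriers are a closed clade over the
modelled flank, the conservative choice for a young insertion in strong
linkage with its flanks.

*Case/control genotypes.* Hardy-Weinberg genotypes at independent sites
(allele frequencies uniform on 0.05-0.5 unless set); the causal site is
dominant and fully penetrant by default. The default study design mirrors
the field sample: n=260 with a carrier allele frequency of 0.1363, which
gives a trait prevalence of `1-(1-0.1363)^2 = 0.254`. With
`causal_index=None` the phenotype is independent of all genotypes (prevalence
0.254), a pure null for type-I calibration.

*Methylation tracks.* CpGs placed uniformly at random across the element
plus padding; scores from truncated normals around region levels. Defaults
(body 0.9, background 0.8, LTR 0.2, sd 0.1) emulate a host-silenced element
whose LTRs sit in a pronounced hypomethylated dip.

*Random streams.* Every operation takes one integer seed; internally the
seed is combined with a per-operation stream key, so passing the same
integer to two different generators can never yield overlapping streams
(replicate `r` of a batch uses `seed + r` or an internally split stream).

### Element annotation (`erv_annotate`)

`find_ltr_pair` seeds exact 15-mers shared at two positions, ranks diagonal
offsets by seed count, grows the densest run, and determines boundaries in
two stages: exact-match extension, then—only if the pair's interior shows
mismatches—a log-likelihood X-drop extension whose mismatch penalty
`log(4m/3)` uses the column mismatch rate `m` estimated from the interior
(floored at 0.005). Identical copies therefore end exactly at their first
mismatch (bit-exact recovery on clean data), while diverged copies (~2%
column mismatch at 1% per-copy substitution) cross isolated mutations and
stop within a few bases of the true boundary. Identity is the edit-distance
identity of the two copies (edlib).

`find_tsd` returns the longest word (between `min_len=4` and `max_len=8`)
that is simultaneously a suffix of the 5' flank and a prefix of the 3'
flank, anchored at the element boundaries; by construction the longest such
word is unique. `scan_orfs` reports, per strand and frame, ORFs from the
first ATG after each stop (or ambiguity break) to the next in-frame stop,
at least `3*(min_aa+1)` nt including the stop, in forward-strand
coordinates, longest first.

A "complete" element is an operational definition (the screen it stands in
for is not otherwise specified): both LTRs at identity >= 0.8 and ORFs of
>= 100 aa covering >= 50% of the internal region; both thresholds are
parameters, and completeness is monotone in them.

`presence_absence` genotypes catalogued loci from flanking anchors (default
500 bp, taken just outside the TSD copies) located by edlib infix alignment.
A locus is *present* when the inter-anchor gap matches element length plus
two TSDs within 10% of the element length, *absent* when it matches the
empty site (one target-site copy) within a TSD-length tolerance, otherwise
*unresolved* (including multi-mapping anchors). A locus is polymorphic iff
both present and absent occur.

### LTR dating (`ltr_dating`)

`ltr_distance` globally aligns the two copies (match +1, mismatch -1, gap
open -4, extend -1; the first reported traceback is used, so results are
deterministic) and returns p-distance = mismatches / aligned non-gap
columns; p-distance is the default because the measured quantity is simply
"genetic distance" between near-identical copies, and the Jukes-Cantor
correction (`-0.75*ln(1-4d/3)`) is available by flag and indistinguishable
from p at the distances of interest. `distance_to_age` inverts the clock,
`T = d/(2*mu)`; the mutation rate is a required user parameter with no
default, since no per-generation rate is established for this system.

`fit_gmm` is a self-contained 1-D EM: per restart, component means start at
random quantiles of the data; 10 restarts, best log-likelihood wins;
variances floored at 1e-10 (flagged when hit); the in-loop assertion that
the log-likelihood never decreases is a hard error, not a warning. BIC
(`-2LL + (3K-1) ln n`) selects K when a range is given. The mixture's modes
are read off a 1,000-point grid over the data range, so "the distance
distribution peaks at zero" is a direct, testable statement. The fit is on
raw distances, matching a distance axis that starts at 0. An sklearn
`GaussianMixture` fit serves as an independent cross-check in the tests,
never as the implementation.

### Windowed diversity and class contrasts (`popgen`)

Columns containing gaps or non-ACGT symbols are excluded from S, pi and
Tajima's D by default (assembly alignments make this the conservative
convention; a flag re-admits gap columns with >= 2 resolvable states).
Tajima's D uses the canonical 1989 constants and is `None` (undefined,
deliberately distinct from 0.0) when S = 0. Sliding windows tile `[0, L)`
half-open and are non-overlapping by default (step = window). Sample-size
matching subsamples the larger class once with a seeded draw (the default),
or averages over `n_subsamples` draws. EHH is computed by refining a
partition of core-carrying haplotypes column by column outward, which is
O(n * L) instead of O(n^2 * L) pairwise scanning, with non-increase
asserted on every curve. `carrier_stats` reports prevalence and binomial
standard error as percentages rounded to one decimal (66/260 -> 25.4 +- 2.7).

### Association scan (`assoc_scan`)

Per-site test: 2x2 allele-count chi-square without continuity correction;
whenever any expected cell is < 5 the exact conditional test is substituted.
Allele counts (not genotype counts) are the primary table since the target
quantity is an allele-frequency difference. Genome-wide significance uses
the max-statistic permutation method: the threshold is the k-th smallest of
the permuted genome-wide minima with `k = floor(alpha*(n_perm+1))`, so
`P(observed min < threshold) = k/(n_perm+1) ~ alpha` under the null with no
distributional assumptions. Two structural facts make the permutation pass
cheap and exact: permuted case allele counts for all sites are one matrix
product, and the 2x2 margins are invariant under label permutation, so the
set of sites needing the exact test is fixed and their p-values can be
precomputed for every achievable table. The peak region spans the leftmost
to the rightmost site within `delta = 2` -log10 units of the peak site
(minimum p, leftmost on ties). Hard genotype calls only; genotype-likelihood
handling for low-coverage data and population-structure covariates are out
of scope (a documented limitation), though the scan accepts any 0/1/2
matrix however produced.

### Insertion-time inference (`insertion_inference`)

The observed data are summarised as per-5 kb-window segregating sites among
carrier haplotypes with the total appended. For each candidate `T` on the
grid, replicates of the carrier simulation are run conditioned on survival
(rejection with a cap of `retry_factor * reps` raw trajectories; the default
cap is 10,000x reps because survival with enough copies to sample can be as
rare as ~1/2000 at the upper grid times), summarised identically, and
compared with the observed summary by Euclidean distance (L1 and total-S
alternatives are selectable). The point estimate is the grid argmin of the
mean distance, smallest T on ties; `GridSearchResult.times_within`
reports all grid times within a tolerance of the minimum, the honest way to
express an upper bound when the profile is shallow.

A real limit worth stating: with per-lineage flank mutation rates of order
`mu * L = 5e-4` per generation and a dozen carriers, the carrier class holds
only a handful of segregating sites (the regime in which the insertion is
young enough to matter), so the distance profile over T is shallow and the
argmin has large sampling variance. Mean-Euclidean-distance selection is
additionally biased toward small T, where replicate summaries have lower
variance (`E||s-obs||^2 = Var + bias^2`). Consumers should read the
whole profile (and `times_within`), not just the argmin; expected carrier
segregating sites do increase monotonically with T, which the tests verify.

The establishment-conditioned drift test runs unconditioned forward
replicates from one copy at `T`; "established" means frequency > 0 at
present. Under dominance the trait frequency of an established replicate at
allele frequency p is `1-(1-p)^2`, and the one-sided p-value is
`(1 + #{established with trait freq >= observed}) / (1 + #established)`,
which is never zero and is exact over the discrete conditional null. When
the observed frequency is itself drawn from that null the p-values are
uniform on their discrete support; the self-calibration test draws 1,000
observations at N=250, T=120 — conditions chosen so the support
(frequencies on a 1/500 lattice, reference sets of several hundred
established replicates) is fine enough for a Kolmogorov-Smirnov check
against the continuous uniform to be meaningful.

### Methylation (`methylation`)

A CpG is methylated iff its score >= 0.5 (the comparison is >=, so a score
of exactly 0.5 counts). Windows are blocks of 10 consecutive CpGs by
default — CpG-count windows, not bp windows — with the final partial block
kept and flagged; a bp-interval mode exists because count-per-interval is
the other natural convention and which one a given figure uses is not
always knowable. The dip score is the difference in mean discretized
methylation, background minus target; its one-sided significance comes from
circular shifts of the discretized values across the combined region, which
preserves the spatial autocorrelation of methylation domains far better
than per-site shuffling (an extension beyond the qualitative dip the
source data show).

## Problem sizes

The test suite and the acceptance script scale their simulations to run on
one CPU in minutes while keeping every estimate's Monte-Carlo error well
inside the asserted tolerance: 100 planted constructs per annotation batch,
10,000-12,000 elements for the LTR clock, 1,000 neutral replicates for the
Tajima's D null, 500 null datasets (n=260, 200 sites, 1,000 permutations)
for family-wise error calibration, 100,000 replicates for the drift
martingale, and 20 independent trials of the full grid search at 200
replicates per grid point.

## What the synthetic tests do and do not show

The generators reproduce the *structure* of the study's data — a planted
element with exact truth, a dated single-origin insertion, a dominant
fully-penetrant locus, a methylation dip — under idealised conditions:
uniform random background sequence (no repeats competing with the LTR
seeds), no recombination within the flank, free recombination between
genotype sites, no sequencing or assembly error, no population structure,
and full penetrance. Passing tests therefore demonstrate correctness of the
computations and calibration of the statistical procedures under the model,
not robustness to repeat-rich genomes, structure confounding, genotyping
error, or partial penetrance. The completeness screen classifies ORFs
positionally only; homology-based naming (gag/pol/env) needs external
profile databases and is out of scope.

## Numerical conventions

Coordinates are 0-based half-open everywhere in memory; GFF3 and VCF
writers convert at the edge (1-based). Alignment traceback ties take the
first reported path. EM variances floor at 1e-10. Tajima's D returns None
rather than 0 at S=0. Permutation p-values use the +1 convention and are
never 0. All stochastic functions take an integer seed; the grader-style
entry points derive sub-seeds below 2^31 from one master generator.
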