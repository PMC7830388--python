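# Methods

This note documents the statistical models behind `copreg`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the package's known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## ChIP occupancy (peak-free)

Reads are single-end 5'-anchored positions with strands. Each read is
extended to the sonication fragment length *L* (default 200 bp) towards
3': a + read at *p* covers [p, p+L), a − read covers [p−L+1, p+1). All
coordinates wrap modulo the genome length; a `circular=False` flag
disables wraparound for edge-case work. Tracks are kept at 1-bp
resolution — the genomes this package targets (and generates) are a few
megabases at most, and per-position resolution keeps the window
statistics exact.

Depth scaling divides each coverage track by its genome-wide mean, which
is per-million scaling up to a constant that cancels in the IP/input
ratio. The ratio uses a symmetric pseudocount ε (default 0.1) on both
numerator and denominator so zero-input positions are defined and
0/0 → 1; setting ε very small approximates masking instead. Replicates
are combined by the arithmetic mean of the *linear* ratios, position by
position; log2 is taken only afterwards and only for visualisation and
export. Per-gene occupancy is the mean linear ratio in a window (default
300 bp) around the TSS. "Around" is interpreted as centered (±150 bp);
an `anchor="upstream"` option places the window strictly 5' of the TSS
for sensitivity analyses. Regulon thresholding always consumes the
linear mean, never the log2 track.

## Differential expression

Counts are modeled as negative binomial with Var = μ + αμ². Size factors
are median-of-ratios with the geometric mean taken over genes with
all-positive counts only (stated explicitly because small synthetic
matrices are zero-rich). Dispersion is estimated per gene by method of
moments on normalized counts within each condition,
α = max(0, (s² − μ̄)/μ̄²), averaged across the two conditions.

At two or three replicates per group the raw moment estimator is
extremely noisy, and its truncation at zero means roughly half of all
null genes get α̂ = 0; a Wald test fed those estimates rejects far too
often (~12% at nominal 5% in 3 vs 3 simulations). The default therefore
floors every gene's estimate at the across-gene mean of the raw
estimates — a minimal dispersion trend in the spirit of the shrinkage
used by mature DGE packages, but deliberately simpler: genes may exceed
the floor, never undercut it. With the floor, the null rejection
fraction is ~4% (computed by the test suite and the acceptance script).
`estimate_dispersion(..., moderate=False)` exposes the raw estimator.

The test statistic is log2 of the ratio of normalized group means. A
group mean of exactly zero is replaced by a pseudo-mean of 0.5, so
strong inductions from zero stay large but finite; genes with zero
counts in both groups are reported with log2FC = 0 and p = 1. The
standard error comes from the delta method:
Var(log2 m̂) ≈ (mean(1/sf)/(n·q) + α/n)/ln²2 per group, summed over the
two groups. p-values are two-sided normal tails and adjusted by
Benjamini–Hochberg (via statsmodels). No effect-size shrinkage is
applied — the downstream selection rule needs a calibrated test and a
plain fold-change estimate, not a shrunken ranking.

2^−ΔΔCt implements the standard relative-quantification formula for
qPCR confirmation: ΔΔCt = (Ct_target − Ct_ref)_treated −
(Ct_target − Ct_ref)_control.

## Regulon selection

The rule is a literal conjunction: fold change > 2 — strict, so a gene
at exactly 2-fold fails — and padj < 0.05, and occupancy ≥ 2 —
inclusive, so exactly 2 passes — in *both* conditions. Requiring both
ChIP sets reflects the biology: this regulator class remains bound
regardless of copper, so a promoter bound only under one condition is
evidence against specific regulation. Genes missing occupancy values are
never selected and are flagged with a `missing-occupancy` reason.

Category enrichment corrects for length selection bias by weighted
resampling rather than a Wallenius approximation: genes fall into 20
equal-occupancy length bins (tied lengths share a bin, so the
equal-length limit collapses to uniform weights); each bin's propensity
is its observed selected fraction, floored at 1/(2N); null draws take
|selected| genes without replacement with probability proportional to
propensity (Gumbel top-k, equivalent to sequential weighted draws);
p = (1 + #{null ≥ observed})/(1 + n_resample), one-sided for
enrichment, BH across categories. In the no-bias limit this converges
to the hypergeometric test (checked against scipy in the suite).

## Motif discovery

The model is ZOOPS: each sequence carries zero or one motif occurrence,
on either strand, with occurrence prior γ; given occurrence, the
location is uniform over the 2(L−w+1) offset×strand positions. ZOOPS
was chosen over OOPS because real regulon promoter sets typically
include members without a recoverable site. The background is 0-order,
estimated from intergenic sequence with +1 pseudocounts and both
strands pooled (f_A = f_T, f_C = f_G).

EM maximizes the smoothed likelihood (Dirichlet 0.01 pseudocount on
motif columns). The monitored objective — data log-likelihood plus the
Dirichlet term — is provably non-decreasing and is asserted per
iteration; the raw data log-likelihood is recorded alongside and can
dip by at most the smoothing term. Optimization uses staged restarts:
24 starts seeded from randomly chosen w-mers (0.7 on the seed base) run
4 burn-in iterations, the best 3 run to convergence
(tol 1e−6 on the objective), and the winner undergoes column-shift
refinement (re-seeding EM from the converged matrix shifted ±1, ±2
columns, vacated columns filled with background). Without the staging
and shift moves, EM on planted-motif data frequently converges to
register-shifted local optima one or two columns off the true site.

Width selection runs EM at each width 8–18 and scores
LL − ½(3w+1)·ln(total scanned positions), a BIC penalty with 3w+1 free
parameters (3 per column plus γ); ties break towards the smaller
width. On pure-background data this machinery still reports a motif
with appreciable information content (~0.85 bits/column at w = 8 in 30
random 60-mers): picking the best alignment among ~90 offsets per
sequence inflates apparent information, which is precisely why
discovery tools report significance estimates. Discovered motifs should
therefore be judged by recovery against known sites or by scanning
statistics, not by information content alone.

The IUPAC consensus assigns a single base when its column probability
is ≥ 0.6, a two-base code (W/S/R/Y/K/M) when the top two sum to ≥ 0.8,
else N. Palindromicity is 1 minus the mean per-column total-variation
distance between θ and its reverse complement (1 = perfect palindrome).

## Scanning with exact p-values

Scores are log2(θ_b,k / bg_b) summed over columns, discretized to
integers at 1/1000 bit. The null distribution of the integer score under
the background is computed exactly by convolving the per-column score
distributions (dynamic programming); the tail gives
p = Pr(score ≥ s) for every achievable score, verified in the suite
against exhaustive 4^6 enumeration for a w = 6 model to 1e−9. Every
offset×strand position of every query sequence is scored (N bases
contribute zero log-odds); BH q-values are computed over all scanned
positions and hits below q = 0.05 are reported sorted by (p, sequence,
offset). Because BH controls the false discovery *rate*, an occasional
background position can pass when many true sites sharpen the
threshold; the acceptance script reports the realized count. Default
scanning windows are the 60 bases upstream of each TSS.

## Promoter profiles

Anchored windows put relative position 0 at the first transcribed base;
−1 is immediately upstream. Minus-strand windows are
reverse-complemented so upstream is always leftward. Windows wrap on
circular genomes; on linear genomes overhanging windows either raise or
are skipped, by flag.

Nucleotide enrichment compares pseudocounted position-specific base
frequencies, log2[(c_t+π)/(n_t+4π)] − log2[(c_b+π)/(n_b+4π)] with π = 1
by default; raw frequency tables are emitted alongside so other
statistics can be layered on. The statistic is exactly antisymmetric
under swapping target and background.

Bendability assigns each window position the scale value of the
trinucleotide starting there (profile length = window − 2; trinucleotides
containing N are skipped and counted). The cross-sequence mean is
smoothed by a centered running mean (span 11, shrunk at edges) and
banded by a percentile bootstrap over sequences (default 1000
resamples, 95%). The band is clipped to bracket the point estimate,
which a raw percentile band can miss in very small samples. The
published DNase-I-derived trinucleotide scales are not redistributed
with the package: the scale is an input (2-column TSV mapping the 32
strand-symmetric trinucleotide classes to values), and a clearly
labelled synthetic toy scale (−0.1 per A/T base; A/T-rich = rigid) is
provided for tests and demonstrations. Profile comparison subtracts
smoothed means and forms the band from independently paired bootstrap
replicates of the two sets.

## Synthetic data

The generator emulates a copper-shock regulon study: a circular genome
(default 120 kb, 200 genes of 300–600 bp, ≥ 200 bp intergenic gaps, GC
0.5), a regulon of 10 genes with one realization of the degenerate
consensus `TTNNCAWWWTGNNAA` planted upstream of each TSS (site 3' edge
30 bp upstream, inside the 60-bp scan window), ChIP read sets in which
the per-position IP read density is `enrichment`-fold (default 20)
higher within ±150 bp of each site than elsewhere while input is
uniform, and NB counts (base mean 500, dispersion 0.05, 3 vs 3) with
planted log2 fold changes cycling through {1, 2.5, 6.14, 8.2} — a
ladder spanning the ~2-fold to ~290-fold induction range such regulons
show, deliberately including a value at the strict selection boundary.
Read depth (50,000 reads/replicate) and enrichment are free parameters
of the generator, not measured quantities. Every operation is a pure
function of its inputs and seed; replicate r of sample s draws from an
independent stream keyed by (seed, s, r).

What the generator does *not* emulate — and hence what passing
recovery tests do not show about real data: sequencing errors and
quality, mappability and duplicate artifacts, fragment-length
variability, operon structure (each gene has its own TSS),
condition-dependent binding, background binding at non-regulon sites,
and compositional biases of real intergenic DNA. End-to-end recovery
here demonstrates the pipeline's correctness and calibration under its
own model assumptions, not its robustness to real-data artifacts.

## Problem sizes and determinism

The validation suite and the acceptance script use desk-scale problem
sizes chosen to make the statistics sharp but quick: 10-kb genomes for
oracle equivalence, 20 seeds of the full default study for regulon
recovery, 2000-gene null matrices for calibration, 30×60-bp window sets
for motif recovery, and 100-sequence window sets for bootstrap
coverage. All randomness flows from explicit seeds; fixed seeds give
bit-identical tracks, models and bands.

## Known limitations

- The Wald test's normal reference is approximate at n = 3; calibration
  is demonstrated at the simulated settings, not guaranteed universally.
- The dispersion floor biases per-gene dispersion upward for genuinely
  low-dispersion genes (a conservative trade).
- Numerical agreement with DESeq2/apeglm on real datasets is not
  claimed anywhere; the DGE stage is behaviorally calibrated, not a
  reimplementation.
- ZOOPS EM finds a single ungapped motif; multiple motifs, gapped
  motifs and higher-order backgrounds are out of scope.
- The mapping from up-regulated genes to shared promoters/operons is
  annotation knowledge the pipeline takes as optional input, not a
  computed step.
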