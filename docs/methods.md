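# Methods

This note documents the models and procedures `oricycle` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Coordinates and fragment records

All internal coordinates are 0-based half-open; BED is native, BAM is
converted on read, and 1-based genomic citations (e.g. the rDNA locus,
chrXII:451,575–489,469 1-based inclusive → [451574, 489469) half-open) are
converted at the boundary.  A fragment's midpoint uses the floor convention
`start + length // 2`; the paper trail for every choice of this kind is a
test.  From BAM, one record is kept per properly paired fragment (the
forward-strand mate's outer span), mirroring the forward-strand-only
convention used when fragments are defined by one end plus the insert
length.  Exclusion filtering (chrM, rDNA) removes fragments by *midpoint*
membership, consistent with the midpoint-based scoring downstream; the
size filter [20, 250] bp is applied at the V-plot/equalization stages, not
at read time, so raw size histograms (e.g. the modal-size statistic) see
every recovered fragment.

## Depth equalization

MNase digestion extent shifts the fragment-size spectrum between samples,
and size-dependent library/sequencing efficiency compounds it.  Within each
biological replicate, for every fragment size s ∈ [20, 250] bp the minimum
count across the time points, m_s, is the subsampling depth: each time
point retains exactly m_s uniformly chosen s-length fragments.  Replicates
are equalized independently (their sequencing depths may legitimately
differ) and matched time points are merged afterwards — never the reverse
order.  One child RNG per fragment size is derived from the stage seed
(`numpy` `SeedSequence.spawn`), so per-size draws are independent and any
subsample is reproducible in isolation.

## Nucleosome kernel and scoring

The model nucleosome is learned from data rather than assumed: fragments
are piled up in a (midpoint offset ∈ [−100, +100] bp) × (size ∈ [20, 250])
matrix around reference dyads — a chemically mapped dyad list for real
yeast data, the generator's planted dyads in synthetic mode.  The kernel is
the product of two 1D Gaussians whose means are the count-weighted marginal
means of this pileup and whose variances are the marginal variances shrunk
by 1/4 (position) and 1/16 (size).  The shrinkage sharpens the
single-nucleosome model relative to the aggregate, which convolves the
true footprint with dyad-to-dyad positioning variability.  Choices the
construction leaves open, fixed here:

- grid half-width W = 100 bp (covers the nucleosome footprint and >2.5
  kernel positional SDs for typical pileups);
- zero correlation between the two dimensions (only marginals are
  parameterized);
- the kernel is renormalized to sum 1 after truncation to the grid, so
  scores are comparable across kernels — only relative scores are used
  downstream, so any positive scaling would be equivalent.

The score at position p is the cross-correlation
Σ_{δ,s} kernel(δ, s) · counts(s, p + δ), with zero-padding within W of a
boundary.  Because the kernel is separable, genome-scale scoring reduces to
a size-weighted midpoint profile convolved with the positional factor; a
test pins this fast path to the direct 2D computation, and both to a naive
double loop over fragments.

## Copy-number normalization

Replication doubles template copy number behind a fork, inflating MNase
coverage irrespective of chromatin state.  The copy number at a position is
the ratio of windowed RPKM (1001 bp centered window; fragments counted by
midpoint; windows clipped at chromosome ends use their covered width)
between the sample and the α-factor (G1) reference, computed per base
(windows overlap).  Nucleosome scores and footprint densities are divided
by it.  An empty reference window yields a flagged missing value, never
±∞.  Note the ratio is *relative*: because RPKM normalizes by the sample
total, a genome that is fraction f replicated shows ratio 2/(1+f) at
replicated loci; for mid-S yeast samples (and the synthetic benchmarks,
which keep the replicated fraction ≈1%) this bias is small, and it cancels
entirely in quantities normalized per time point.

## Footprint density

Per chromosome, the midpoints of fragments *strictly* shorter than 120 bp
are density-estimated with a Gaussian kernel of SD 50 bp — "bandwidth"
here means the kernel SD, not FWHM — evaluated at every base and multiplied
by the chromosome length, so a uniform background sits at 1.  Tracks are
copy-number normalized first; then the per-sample calibration factor is
computed as the reciprocal of the mean occupancy over all bases within
±100 bp of the Abf1p binding sites (each covered base weighted equally;
clipped windows contribute their covered part) and applied
multiplicatively.  Abf1p occupancy is cell-cycle independent, so the factor
absorbs sample-to-sample differences in MNase digestion.  Both corrections
are multiplicative and commute.  The per-origin read-out is the calibrated
track value at the single ACS base.

## Shannon entropy of nucleosome organization

For a window X of n bases with nucleosome scores nuc_i, P(x_i) =
nuc_i / Σ_j nuc_j and H(X) = −Σ_i P(x_i) ln P(x_i), with 0·ln 0 := 0.
Natural logarithm (the base only rescales H and cancels in z-scores).
Windows with zero total score are *missing*, not zero-entropy — absence of
coverage is not organization; NaN bases (undefined copy number) are
dropped from the window.  H is exactly invariant to positive rescaling of
the scores, bounded by [0, ln n], and nondecreasing under mixing toward
uniform — all property-tested.  Around origins, entropy is computed on the
copy-number-normalized nucleosome tracks in 1 kb windows spanning 30 kb,
pooled across origins by the absolute distance of the window center from
the ACS (15 bins), and each distance bin's time series is standardized to
z-scores; numerically flat rows (SD below 1e-12 relative) are emitted as
zeros with a flag.  The per-origin, per-window matrix is also exported.
Active vs. passively replicated origin sets are the top and bottom 20% by
activation efficiency among footprint-class origins.

## Origin-level analyses

All origin-relative coordinates are oriented by the T-rich ACS strand, so
"+1" is always the first nucleosome downstream in that orientation.  Dyads
are called on aggregate nucleosome profiles as the position of maximal
score within [ACS+10, ACS+500] (+1) and [ACS−500, ACS−10] (−1): 500 bp
covers the −1/+1 positions at yeast origins, 10 bp excludes the ACS
footprint itself, and ties break toward the ACS (the innermost nucleosome
is the one biologically named ±1).  Both aggregate-profile and per-origin
calls are available; aggregate is the default because single-origin argmax
calls on an equal-occupancy array are ambiguous between genuine
neighboring nucleosomes — aggregation across origins stacks the
consistently placed ±1 dyads while the unphased genomic array averages
out.  The footprint peak average fixes the peak as the argmax of the
*time-averaged* class profile, then averages ±100 bp around it at each
time point.  The footprint–efficiency association is the Spearman
correlation of log2(density + ε) against efficiency per time point, with
ε = half the smallest positive density (Spearman is rank-based, so the
transform matters only through ε on zeros); origins with missing
efficiency are excluded pairwise and n is reported.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is tested.
It emulates, on a small genome:

- a regular nucleosome array (spacing 165 bp; fragment sizes ~ truncated
  Normal(166, 15) on [120, 250], matching the ~166 bp modal size of real
  digests; midpoints jittered around dyads with positional fuzziness SD
  10 bp at baseline);
- origins of the two footprint classes with NFR half-widths 129 bp
  ("G1&G2") and 110 bp ("G1only") — planted dyad-to-dyad widths 258 and
  220 bp, echoing the ~258/~221 bp difference between the classes in real
  data — with the +1 nucleosome of "G1&G2" origins transiently displaced
  (+25 bp, Gaussian in time around the G1/S transition);
- sub-120 bp footprint fragments (sizes uniform on [60, 119], midpoint
  jitter SD 15 bp) at each ACS, whose expected occupancy is
  base + amplitude·bump(t) with bumps at 20 min (G1/S) and, dampened by
  half, 95 min (second cycle); the "G1only" class has its bump scaled by
  0.3; Abf1p-like sites carry constant occupancy for calibration;
- deterministic bidirectional replication: each active origin's fork moves
  outward at 750 bp/min from its activation time (20 min for "G1&G2"
  origins by default; "G1only" origins are passive), doubling the sampling
  weight of every locus behind the front, clipped where converging forks
  would merge.  A disruption band trailing the fork (7500 bp — one 10-min
  sampling interval of travel, so the band is visible at the sampling
  cadence) transiently raises nucleosome fuzziness to SD 40 bp; once the
  fork passes (or merges), chromatin is restored.  Fork speed and
  activation times are conventions of the simulation, not measured facts;
- optional coupling between origin efficiency and footprint-bump amplitude
  at a configurable population Spearman correlation, via a Gaussian copula
  (r_pearson = 2 sin(π ρ_s / 6)).  The coupling applies to the bump only,
  so the correlation carries the planted cell-cycle timing;
- 16 time points (α-factor plus every 10 min to 150 min) in two
  replicates; uniform background fragments.

Sampling is multinomial over all sources, so per-source counts sum to the
requested depth exactly, and every sample regenerates byte-for-byte from
its recorded seed.

What it does **not** emulate: sequence (no FASTA/FASTQ, read errors, or
alignment), MNase sequence bias, transcription-coupled chromatin,
stochastic per-cell firing (replication is a deterministic population
front), or a second round of replication — copy number follows a single S
phase while footprint occupancy stays periodic over both cycles.  Passing
tests therefore demonstrate that the *quantification* recovers planted
chromatin features at realistic depths and noise, not that the simulation
reproduces every property of real digests.

## Problem sizes and benchmarks

The self-checks in `oricycle.evaluation` (driven by the test suite and
`scripts/acceptance.py`) use desk-scale problem sizes chosen to make the
statistical tolerances meaningful: 50 nucleosomes × 30 fragments for dyad
recovery (≥95% of score maxima within ±15 bp at fuzziness 10 bp); 10⁵
fragments for equalization exactness; ~10⁴ fragments in the copy-number
window (3-SD agreement with ratio 2; the benchmark layout keeps the
replicated fraction ≈1% of the sampling weight so the relative-RPKM bias
stays below the tolerance); 10⁴ uniform midpoints on 100 kb for KDE mass
conservation (interior mean within 1% of 1, excluding 3-bandwidth
margins); 300 origins at planted Spearman 0.6 for correlation recovery
(±0.1, with a 100-permutation null); and a 40-origin, 16-time-point,
two-replicate course for the end-to-end orderings.  The end-to-end
assertions are orderings, not magnitudes: the class-average footprint curve
peaks at the planted time point, the footprint–efficiency correlation is
maximal in early S of the first cycle (the dampened second-cycle bump can
host the global maximum, which is why the assertion is restricted to the
first cycle), and distal 1 kb windows reach peak z-entropy one sampling
interval after origin-proximal ones.  The modal fragment size is reported
from a 10⁶-fragment draw with a 3 bp moving average over the size
histogram, because a 1 bp-resolution argmax on a distribution this flat at
its top is otherwise dominated by bin noise.

## Known limitations

- Copy-number estimates are relative (see above); absolute 2× recovery is
  only expected when the replicated fraction is small or after per-sample
  normalization.
- Dyad calls on single origins at uniform nucleosome occupancy are
  ambiguous by construction; use aggregates or deeper data.
- The Abf1p calibration assumes site occupancy is constant across the
  course; violations would fold into every footprint density.
- Real-data mode expects externally supplied origin annotations, reference
  dyads and Abf1p sites; the package does not call origins or scan for ACS
  motifs.
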