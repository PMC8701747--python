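# oricycle

Quantification of cell-cycle chromatin dynamics at DNA replication origins
from paired-end MNase-seq fragment data.

## The problem

In budding yeast, replication origins are selected and activated through a
choreography of chromatin events: ORC binds the T-rich ARS consensus
sequence (ACS) inside a nucleosome-free region (NFR), the Mcm2-7 helicase is
loaded in G1 (the pre-RC), activation factors assemble the CMG holohelicase
at the G1/S transition, and the moving replication fork transiently evicts
and repositions nucleosomes.  Micrococcal-nuclease digestion followed by
paired-end sequencing reads all of this out at once: each recovered fragment
is a protected particle whose *length* reports the bound factor (~150–180 bp
for nucleosomes, <120 bp for ORC/pre-RC-scale factors) and whose *midpoint*
reports where it sat.

`oricycle` turns time courses of such fragment data (BED/BEDPE/BAM) into
quantitative origin-level summaries:

- **V-plots** — fragment size × midpoint occupancy matrices per region;
- **depth equalization** — for each fragment size *s* ∈ [20, 250] bp, every
  time point of a replicate is randomly subsampled to
  *m*ₛ = minₜ count(*s*, *t*), removing digestion/depth bias, then matched
  time points of the two replicates are merged;
- **nucleosome scoring** — a separable bivariate-Gaussian kernel over
  (midpoint offset, fragment size) is moment-matched to the fragment pileup
  at reference dyads, with the marginal variances shrunk to 1/4 (position)
  and 1/16 (size); the per-base score is the cross-correlation
  score(*p*) = Σ<sub>δ,s</sub> kernel(δ, s) · counts(s, p + δ);
- **copy-number normalization** — scores are divided by the ratio of
  windowed RPKM (1001 bp) between the sample and the α-factor (G1)
  reference, removing the 2× coverage gain behind replication forks;
- **footprint density** — Gaussian-KDE (bandwidth = SD = 50 bp) of sub-120 bp
  fragment midpoints per chromosome, scaled by chromosome length,
  copy-number normalized and calibrated by the reciprocal of the mean
  occupancy at Abf1p binding sites (±100 bp);
- **nucleosome disorganization** — Shannon entropy of windowed scores,
  P(x<sub>i</sub>) = nuc<sub>i</sub> / Σ nuc<sub>j</sub>,
  H = −Σ P log P, pooled in 1 kb windows over 30 kb around origins and
  z-scored per distance bin across time;
- **origin summaries** — ACS-oriented aggregation, −1/+1 dyad calls and NFR
  widths, footprint peak averages per origin class, and the per-time-point
  Spearman correlation between log2 ACS footprint density and origin
  activation efficiency.

A first-class synthetic-data module generates fragment time courses with
planted nucleosome arrays, origin footprints, replication fronts, and
fork-coupled disorganization, so every stage is testable against known
truth without downloading anything.

## Worked example

`examples/05_full_pipeline.py` runs the whole pipeline on a synthetic
16-time-point course (α-factor plus every 10 min to 150 min, two
replicates, 20 origins):

```
median NFR width (dyad-to-dyad) by footprint class:
class
G1&G2     258.5
G1only    221.5

Spearman rho: ACS footprint density vs origin efficiency, by time:
alpha    0.120
t10      0.651
t20      0.675
t30      0.700
t40      0.615
t50      0.337
t60      0.006
...
```

Origins with a persistent ("G1 & G2") ORC footprint have the wider NFR
(~258 bp dyad-to-dyad vs ~221 bp for the "G1 only" class), and the
correlation between ACS footprint density and origin efficiency peaks in
early S phase — the time when CMG assembly at efficient origins is
strongest — exactly the structure planted by the generator.  The other
examples each exercise one capability (simulation, V-plot/kernel, footprint
density, the entropy fork wave).

There is also a thin CLI:

```sh
oricycle simulate --outdir sim --seed 1
oricycle run-all --config run.yaml --outdir out --seed 1
```

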