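# Methods

This note documents the models, conventions, parameters and numerical
choices behind `orichrom`, and what the synthetic validation does and
does not demonstrate about real data.

## Coordinates and orientation

All in-memory coordinates are 0-based half-open; GFF3 (1-based
inclusive) and bedGraph conversions live exclusively in `orichrom.io`.
The 5' end of a minus-strand read is stored at its last covered base
(BED `end - 1`).  A consequence worth knowing: for a perfectly
protected 147-bp fragment the plus boundary sits at `dyad - 73` and the
minus boundary at `dyad + 73`, so the estimated boundary spacing is
`footprint - 1` = 146 bp.  Dyad midpoints are unaffected, and every
claim about spacing carries a ±1 bp tolerance for this reason.
Midpoints of even-length spans round down.

Origin-anchored analyses use the ACS interval midpoint as position 0
and orient every window along the strand whose forward reading of the
ACS is T-rich, so "left of the ACS" means the same thing at every
origin.  A motif hit's oriented offset is the position of its first
base read along that strand.

## Positioning profile

The mononucleosome evidence is a pair of per-base counts per
chromosome: plus-strand and minus-strand read 5' ends (fragment
boundaries).  The profile is built in four steps:

1. Each strand's count vector is smoothed with a multilevel 1-D
   biorthogonal wavelet decomposition/reconstruction in which all
   detail bands are zeroed.  The *stationary* (undecimated) transform
   is used rather than the decimated one: it is linear, preserves
   constants, and — unlike the decimated transform — is exactly
   shift-invariant and reflection-symmetric, so smoothing never moves a
   peak.  Default wavelet `bior3.5`, default level 4 (suppresses
   structure finer than ~16 bp, well below nucleosome scale); both are
   configuration keys.  Input is symmetric-padded to a multiple of
   2^level and trimmed after reconstruction.
2. Boundary peaks are local maxima of the smoothed strand profile above
   a noise floor of mean + 1 sd (the data are mostly baseline, so this
   floor sits just above the smoothed background), with a minimum
   separation of 80 bp to suppress ripple.
3. Each plus peak is paired with the nearest minus peak 100-200 bp
   downstream; the mean paired distance is the average boundary
   spacing.  Pairs give discrete nucleosome calls at the rounded-down
   midpoint with score = min of the two peak heights; calls closer than
   60 bp (sub-footprint artifacts) merge to their score-weighted mean.
4. The combined profile shifts plus starts right and minus 5' ends left
   by half the spacing so both strands vote at the inferred dyad,
   spreads each vote over the 147-bp nucleosome footprint, smooths and
   normalizes to genome mean 1 (the mean is global, not
   per-chromosome).  The footprint spread is deliberate: the
   depleted-region rule below is a statement about *fragment coverage*,
   and a bare dyad-density track would dip below threshold in every
   linker.  Reads are only boundary evidence; the 40-nt read length
   never enters the profile.

Small negative excursions from wavelet ringing are clipped to zero
before normalization.

## NDR rule

An NDR is a maximal run of at least `min_len` = 80 consecutive bases
with normalized signal strictly below `threshold` = 0.4.  There is no
gap tolerance: a single base at or above threshold splits the run.  The
79-base run and the exact value 0.4 are rejected by construction, and
the caller is tested for exact equivalence against an independent
brute-force scanner.

Origin association: an NDR is eligible for an origin if it overlaps the
ACS or lies within `max_dist` = 150 bp of it (the NDR rule itself fixes
no distance; 150 bp sits well below typical inter-NDR spacing).
Each origin claims at most one NDR — the one nearest the ACS midpoint,
ties broken by larger ACS overlap, then lower coordinate.  An origin
with no claimable NDR is reported as the distinct sentinel `CLOSED`,
never as width 0, so averages over open origins must exclude it
explicitly.  Per-origin width is the full NDR width even when the
region extends beyond the ±600 bp aggregate window (logged when it
does).

## Origin classes

Windows are the 1201 signal values over [-600, +600] around the ACS
midpoint, oriented; origins closer than 600 bp to a chromosome end are
excluded with a log line.  Clustering is plain Euclidean k-means on the
raw window vectors (no per-row scaling; a row-scaling switch exists but
defaults off), best of 8 seeded restarts with a 10,000-iteration
budget.  Empty clusters from degenerate inputs are dropped with a
warning.  Classes are then relabeled so class-mean NDR width strictly
decreases from class 1 to class k; widths come from the genome-wide NDR
calls when supplied, else are measured inside each window by the same
run rule.  Ties order the larger class first.

## Genomic context

Overlapping genes merge into blocking intervals before IGR
construction; the merged block carries the strand of the gene reaching
furthest right, since that gene faces the following IGR.  Categories
are a pure function of flanking strands — same strands: tandem; (-,+)
left-to-right: divergent; (+,-): convergent — and under independent
equiprobable strands the expectation is (0.5, 0.25, 0.25).  An origin's
category is that of the IGR containing its ACS midpoint (half-open
containment); origins inside gene bodies get the `INTRAGENIC` sentinel
and drop out of enrichment denominators.  Enrichment is reported
descriptively (observed fraction, expected, ratio) with a chi-square
goodness-of-fit p-value as an optional statistic.

## Fkh motifs

Scanning is exact IUPAC matching of RTAAAYA (R = A/G, Y = C/T) on both
strands via regex lookahead (overlapping hits are all reported); `N` in
the genome never matches.  The dual-site configuration is: two hits,
one within `proximal_max` = 50 bp of the ACS midpoint ("close
proximity" is otherwise unquantified), start-to-start separation within
[60, 120] bp, bounds inclusive.  Separation is measured between
oriented motif start coordinates.  A stricter mode additionally
requires both sites inside the origin's called NDR.  Density profiles
count oriented motif starts per offset and smooth with a Gaussian
kernel (default 10 bp bandwidth); mass is conserved up to truncation of
hits within ~4 bandwidths of the window edge.

## Replication dynamics

The differential track is the elementwise S-phase minus G1 positioning
profile (both mean-1, so the genome-wide differential mean is ~0 and
copy-gained regions stand out against a slightly negative baseline).

Copy-number correction divides raw nucleosomal coverage by a naked-DNA
copy-number estimate: the naked track rescaled to genome mean 1 and
smoothed with a centered 1000-bp sliding mean at 1-bp step.  Smoothing
is applied to the *naked* track, not to the corrected ratio — the
estimate should be smooth at the replicon scale while the corrected
profile must keep its nucleosome-scale structure.  Zero or missing
naked positions propagate as NaN (never infinity) and sliding windows
average over the available bases, shrinking at edges.

Replicated extent around an origin: the differential is averaged with
the 1000-bp window over ±6 kb of the ACS and the maximal contiguous run
containing the ACS above 0.25x the origin's peak averaged differential
is returned.  A fired origin's plateau sits near the local signal
amplitude (copy number doubles), while sampling-noise peaks of the
window-averaged differential stay below ~0.2 at the coverages analyzed,
so peaks under a floor of 0.3 are treated as not fired and give extent
0.  The crossing of a relative threshold on a 1-kb-averaged edge adds a
few hundred bp to the true replicated span; measured extents for a
±2250 bp planted replicon center near 4.9 kb.

The shift report compares G1 and S aggregate profiles per origin group:
the ACS-proximal minimum is located within ±300 bp of the window
center, the -1/+1 nucleosome peaks are the nearest flanking local
maxima within 300 bp of that minimum, and the report gives S-minus-G1
deltas of NDR width, peak offsets and peak heights.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *design* of a G1/HU-S MNase-seq study:
single-end 40-nt reads whose 5' ends mark mononucleosome boundaries,
~50-95x coverage, naked-DNA controls, origins with annotated T-rich ACS
elements and early/late labels, and exact 2x copy number over ±2250 bp
of early origins in S phase (an idealized HU arrest; late origins have
not fired).  Genes tile chromosomes with random equiprobable strands;
origins occupy well-separated intergenic slots; nucleosomes tile the
rest of the genome at 165-bp spacing (occupancy 0.9, 5-bp dyad jitter).

Six architecture classes are planted with NDR widths 193, 180, 167,
154, 141, 129 bp (per-origin jitter ±4 bp), flanking-nucleosome
occupancy 0.98 down to 0.64, dyad fuzziness 3 to 11 bp, and — because
real origin NDRs cover the ACS asymmetrically — a class-specific NDR
center offset from +80 to -55 bp.  The offsets and occupancy/fuzziness
grades were chosen once so the six classes are *structurally distinct
patterns* rather than a bare width gradient; with a pure gradient the
within-class sampling spread exceeds the between-class centroid
distance and no clustering method could separate adjacent classes.
These are free design parameters of the generator, not measurements.

Read sampling: each dyad emits Poisson-many fragments (rate set by
coverage, thinned by occupancy, doubled in replicated regions in S
phase); each fragment jitters its dyad by the planted fuzziness, spans
the 147-bp footprint with ~2 bp length noise, and contributes both
boundary 5' ends.  Background (linker) reads default to 0 and are
configurable; mono:di digestion ratios are modeled only as boundary
noise, never as dinucleosome fragments.  There is no sequence-dependent
MNase bias, no mappability structure, no GC bias, and no transcription.
Recovery results on this generator therefore demonstrate correctness of
the *pipeline* under its stated read model — they do not certify
performance on real MNase-seq libraries, where digestion bias and
fuzzier positioning will widen all error bars.

Fkh configurations are planted only at early origins: a dual
configuration (proximal site 12-40 bp from the ACS, partner at the NDR
border 60-120 bp away, on whichever side has room) at the configured
rate (default 25.6%), a single proximal site at 30%, otherwise none.
To keep detection exactly equal to the planted truth, spurious
consensus matches within ±700 bp of each ACS are scrubbed by single-
base mutation outside planted features (a ~17-bp window per 4 kb of
random sequence would otherwise match by chance); the rest of the
genome keeps its chance hits.

All randomness flows from one seed; sampling uses fixed per-(sample,
phase) substreams so each sample is reproducible regardless of call
order.

## Problem sizes used in validation

The recovery suite runs on a 2.6-Mb genome with 600 origins (100 per
class) at 80x coverage for width/dyad/class recovery; a 1.3-Mb genome
with 40 well-separated origins at 50x for the replication analyses; a
10,000-gene genome for the intergenic expectation; 1,000 random 10-kb
tracks for NDR-caller oracle equivalence; and a 250-kb, 16-origin study
for end-to-end determinism.  These sizes keep the full suite and the
acceptance script within a couple of minutes on one CPU while leaving
every per-origin statistic well-powered.

## Known limitations

- The exact wavelet family/level of any particular published track is
  not recoverable; only structural equivalence on planted truth is
  claimed.  Family and level are configuration keys.
- Window-averaged extent measurement biases replicated spans upward by
  a few hundred bp (threshold crossing on a smoothed edge).
- The NDR rule with no gap tolerance fragments shallow depleted regions
  in noisy data; the caller is faithful to the rule rather than robust
  to it.
- `combined_profile` interprets the construction as "shift boundary
  evidence onto dyads, then measure footprint coverage"; summing
  already-smoothed shifted profiles instead would differ only by the
  linearity of the smoother, but the footprint spread is an
  interpretation (see the NDR-rule rationale above).
- Timing labels are inputs; the package never infers replication
  timing from sequencing signal.
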