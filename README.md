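# orichrom

Nucleosome architecture at budding-yeast replication origins, from
MNase-seq boundary reads.

In *S. cerevisiae*, replication origins (ARS elements) carry a
nucleosome-depleted region (NDR) next to the essential ACS sequence,
flanked by positioned nucleosomes, and the shape of this architecture
tracks replication timing: early-firing origins tend to have broad,
well-organized NDRs, late origins narrow ones, with late origins biased
toward intergenic regions between convergent genes.  `orichrom`
implements the full genome-wide analysis behind those observations as a
reusable, tested pipeline for people working on chromatin organization
and replication timing:

- **Positioning profiles** from stranded mononucleosome read 5' ends:
  the 5' end of a plus-strand read marks a nucleosome's left boundary,
  a minus-strand 5' end its right boundary.  Boundary peaks are picked
  on wavelet-smoothed per-strand profiles, their average plus-to-minus
  spacing estimates the protected fragment size, and both strands are
  shifted half a spacing onto the dyad, extended over the 147-bp
  footprint, smoothed (stationary biorthogonal wavelet transform) and
  normalized to genome mean 1.
- **NDR calling** with the exact rule: maximal runs of at least 80
  consecutive bases with normalized signal strictly below 0.4, split by
  any single base at or above threshold; origin association, per-origin
  width or a CLOSED verdict.
- **Origin architecture classes**: [-600, +600] windows centered on the
  ACS midpoint, oriented along the T-rich ACS strand, clustered by
  Euclidean k-means (k = 6, 10,000-iteration budget, multiple seeded
  restarts) and relabeled so class-mean NDR width decreases from class
  1 to class 6; early/late timing composition per class.
- **Genomic context**: intergenic regions classified tandem / divergent
  / convergent from flanking gene strands (expected 50/25/25 under
  random strands) and origin-context enrichment.
- **Fkh motifs**: exact IUPAC scanning of the Forkhead consensus
  RTAAAYA on both strands, ACS-anchored motif density, and the
  early-origin dual-site detector (one site within 50 bp of the ACS,
  separation within [60, 120] bp inclusive).
- **Replication dynamics**: S-minus-G1 differential tracks, naked-DNA
  copy-number correction (naked track rescaled to genome mean 1,
  smoothed with a 1000-bp window at 1-bp step, then divided out),
  replicated-extent measurement around origins, and per-group
  nucleosome shift reports.
- **Synthetic data**: a first-class generator that plants six origin
  architecture classes (NDR widths 193 down to 129 bp, graded occupancy
  and positioning), G1 and HU-arrested S-phase samples with 2x copy
  number over ±2.25 kb of early origins, naked-DNA controls, and Fkh
  site configurations — all recorded as ground truth for recovery
  tests.

## Worked example

```python
import numpy as np
import orichrom as oc
from orichrom.nucleosome_calling import genome_average_spacing

cfg = oc.SimConfig(genome_length=250_000, n_chroms=2, n_genes=180,
                   n_origins=16, mean_coverage=50.0, seed=5)
truth = oc.generate_genome_and_annotations(cfg)
reads = oc.sample_mononucleosome_reads(truth, phase="G1")

spacing = genome_average_spacing(reads)
profile = oc.combined_profile(reads, spacing)
ndrs = oc.call_ndrs(profile, min_len=80, threshold=0.4)
origin_ndrs, other = oc.associate_ndrs_with_origins(ndrs, truth.origins)

print(f"reads: {reads.total_reads}")
print(f"boundary spacing: {spacing:.1f} bp")
print(f"NDRs: {len(ndrs)} total, {len(origin_ndrs)} origin-associated")
errors = [abs(w - truth.architecture[o.name].ndr_width)
          for o in truth.origins
          if (w := oc.origin_ndr_width(o, origin_ndrs)) is not oc.CLOSED]
print(f"NDR width error: mean {np.mean(errors):.1f} bp over {len(errors)} origins")
hits = oc.scan_motif(truth.genome, "RTAAAYA")
print(f"dual-Fkh early-origin fraction: "
      f"{oc.fraction_with_configuration(truth.origins, hits):.3f}")
```

prints

```
reads: 274662
boundary spacing: 146.0 bp
NDRs: 28 total, 16 origin-associated
NDR width error: mean 5.8 bp over 16 origins
dual-Fkh early-origin fraction: 0.333
```

The 146-bp spacing is the distance between the left and right boundary
piles of a 147-bp protected fragment (last covered base convention).
All 16 planted origin NDRs are found and their widths recovered to ~6 bp;
the dual-Fkh fraction equals the generator's planted rate for this seed
exactly, because detection of strict-consensus configurations is
deterministic.

## Command line

Every stage is also a subcommand reading/writing standard formats
(FASTA, GFF3, BED, bedGraph, TSV):

```sh
orichrom simulate --outdir sim --seed 3          # synthetic study + truth tables
orichrom all --config run.yml --outdir results   # full pipeline
orichrom profile|ndr|classify|context|motifs|dynamics ...
```

`run.yml` holds a seed, the analysis parameters (NDR rule, window
halfwidth, k, motif, separation bounds, smoothing window...) and either
file inputs or a `synthetic:` section with generator settings; unknown
keys are rejected, and the output bundle's `manifest.json` records
everything needed to reproduce a run exactly.

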