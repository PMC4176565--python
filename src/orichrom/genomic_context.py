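"""Intergenic regions and the genomic context of origins.

Each IGR between two adjacent (non-overlapping, merged if needed) genes
is classified by the flanking transcription directions: tandem when both
genes point the same way, divergent when they transcribe away from the
IGR ((-,+) left to right) and convergent when they transcribe into it
((+,-)).  Under independent equiprobable gene strands the expected
category frequencies are 50/25/25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneAnnotation, OriginRecord

logger = logging.getLogger("orichrom.context")

CATEGORIES = ("tandem", "divergent", "convergent")

INTRAGENIC = "INTRAGENIC"


@dataclass(frozen=True)
class IGRRecord:
    chrom: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    left_strand: str
    right_strand: str

    @property
    def category(self) -> str:
        if self.left_strand == self.right_strand:
            return "tandem"
        if self.left_strand == "-":  # (-,+): both transcribe away from the IGR
            return "divergent"
        return "convergent"


def _merge_overlapping(genes: list[GeneAnnotation]) -> list[GeneAnnotation]:
    """Merge overlapping genes into single blocking intervals for IGR
    construction.  The merged block keeps the id/strand of the gene that
    reaches furthest right (it is the one facing the next IGR)."""
    merged: list[GeneAnnotation] = []
    n_merged = 0
    for gene in sorted(genes, key=lambda g: (g.start, g.end)):
        if merged and gene.start < merged[-1].end:
            prev = merged[-1]
            n_merged += 1
            keep = gene if gene.end >= prev.end else prev
            merged[-1] = GeneAnnotation(
                keep.gene_id, prev.chrom, prev.start, max(prev.end, gene.end), keep.strand
            )
        else:
            merged.append(gene)
    if n_merged:
        logger.warning("merged %d overlapping genes into blocking intervals", n_merged)
    return merged


def build_igrs(genes: list[GeneAnnotation]) -> list[IGRRecord]:
    """One IGR between each adjacent gene pair per chromosome.

    Chromosome-terminal gaps are excluded; a chromosome with fewer than
    two genes yields no IGRs (warning).
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    igrs: list[IGRRecord] = []
    for chrom in sorted(by_chrom):
        ordered = _merge_overlapping(by_chrom[chrom])
        if len(ordered) < 2:
            logger.warning("chromosome %s has < 2 genes; no IGRs built there", chrom)
            continue
        for left, right in zip(ordered, ordered[1:]):
            if left.end >= right.start:
                continue  # adjacent blocks touching; no intergenic gap
            igrs.append(
                IGRRecord(
                    chrom, left.end, right.start,
                    left.gene_id, right.gene_id, left.strand, right.strand,
                )
            )
    return igrs


def expected_category_frequencies() -> tuple[float, float, float]:
    """Analytic (tandem, divergent, convergent) expectation under
    independent equiprobable gene strands: tandem is ++ or --, hence
    (0.5, 0.25, 0.25)."""
    return (0.5, 0.25, 0.25)


def origin_igr_category(origin: OriginRecord, igrs: list[IGRRecord]) -> str:
    """Category of the IGR containing the ACS midpoint (half-open
    containment), or the INTRAGENIC sentinel."""
    mid = origin.acs_mid
    for igr in igrs:
        if igr.chrom == origin.chrom and igr.start <= mid < igr.end:
            return igr.category
    return INTRAGENIC


def category_enrichment(
    origin_categories: list[str],
    expected: tuple[float, float, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Observed vs expected IGR-category fractions for a set of origins.

    INTRAGENIC origins are excluded from the denominator.  Returns, per
    category, the observed fraction, the expected fraction, and their
    ratio.  A chi-square goodness-of-fit p-value against the expectation
    is included under the 'chi2_pvalue' key of each entry (identical for
    all three; provided as an optional descriptive statistic).
    """
    if expected is None:
        expected = expected_category_frequencies()
    categorized = [c for c in origin_categories if c in CATEGORIES]
    if not categorized:
        raise ValueError("no origins fall inside an IGR; cannot compute enrichment")
    n = len(categorized)
    counts = {c: categorized.count(c) for c in CATEGORIES}
    exp_counts = [e * n for e in expected]
    chi2_p = float(stats.chisquare(list(counts.values()), exp_counts).pvalue)
    out: dict[str, dict[str, float]] = {}
    for cat, e in zip(CATEGORIES, expected):
        obs = counts[cat] / n
        out[cat] = {
            "observed": obs,
            "expected": e,
            "ratio": obs / e,
            "chi2_pvalue": chi2_p,
        }
    return out


def empirical_category_frequencies(igrs: list[IGRRecord]) -> dict[str, float]:
    """Empirical IGR-category frequencies of an annotation set."""
    if not igrs:
        raise ValueError("no IGRs supplied")
    n = len(igrs)
    return {c: sum(1 for i in igrs if i.category == c) / n for c in CATEGORIES}
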