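"""Genomic-feature characterization of lncRNAs versus protein-coding genes:
exon counts and lengths, transcript lengths, antisense overlap fractions,
inter-locus distances, intron lengths, and expression-distribution contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DataError,
    ExpressionMatrix,
    GenomeAnnotation,
    TranscriptModel,
)


@dataclass
class ClassStats:
    n_transcripts: int
    mean_exon_count: float
    exon_count_distribution: dict[int, int]
    fraction_spliced: float
    median_exon_length: float
    median_transcript_length: float
    median_fpkm: float | None


@dataclass
class FeatureSummary:
    """Per-class (lincRNA / lncNAT / coding) structural and expression stats.

    A class with no transcripts is simply absent from ``classes``.
    "Expression level" of a transcript is its maximum FPKM over samples,
    matching the detection criterion used at the identification stage.
    """

    classes: dict[str, ClassStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, cs in self.classes.items():
            rows.append(
                {
                    "class": name,
                    "n_transcripts": cs.n_transcripts,
                    "mean_exon_count": cs.mean_exon_count,
                    "fraction_spliced": cs.fraction_spliced,
                    "median_exon_length": cs.median_exon_length,
                    "median_transcript_length": cs.median_transcript_length,
                    "median_fpkm": cs.median_fpkm,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DistanceSummary:
    """Distances in bp between annotation features (Fig-1F-style contrast).

    Gap between 1-based inclusive intervals [a,b] and [c,d] with c > b is
    c - b - 1 (the count of intervening bases), so touching or overlapping
    features are at distance 0.
    """

    lncrna_to_gene: list[int]
    gene_to_gene: list[int]
    intron_lengths: list[int]

    @property
    def medians(self) -> dict[str, float | None]:
        def med(xs):
            return float(np.median(xs)) if xs else None

        return {
            "lncrna_to_gene": med(self.lncrna_to_gene),
            "gene_to_gene": med(self.gene_to_gene),
            "intron_length": med(self.intron_lengths),
        }


def feature_summary(
    transcripts: list[TranscriptModel], expr: ExpressionMatrix | None = None
) -> FeatureSummary:
    """Compute per-biotype structural statistics (and median expression if
    a matrix is given); biotypes 'lincRNA', 'lncNAT' and 'coding' are
    summarized, others ignored."""
    summary = FeatureSummary()
    for cls in ("lincRNA", "lncNAT", "coding"):
        members = [t for t in transcripts if t.biotype == cls]
        if not members:
            continue
        exon_counts = np.array([t.n_exons for t in members])
        exon_lengths = np.concatenate([np.array(t.exon_lengths()) for t in members])
        tx_lengths = np.array([t.length for t in members])
        median_fpkm = None
        if expr is not None:
            present = [t.id for t in members if t.id in expr.values.index]
            if present:
                median_fpkm = float(expr.values.loc[present].max(axis=1).median())
        dist = dict(zip(*np.unique(exon_counts, return_counts=True)))
        summary.classes[cls] = ClassStats(
            n_transcripts=len(members),
            mean_exon_count=float(exon_counts.mean()),
            exon_count_distribution={int(k): int(v) for k, v in dist.items()},
            fraction_spliced=float((exon_counts >= 2).mean()),
            median_exon_length=float(np.median(exon_lengths)),
            median_transcript_length=float(np.median(tx_lengths)),
            median_fpkm=median_fpkm,
        )
    return summary


def antisense_overlap_fraction(nat: TranscriptModel, ref: GenomeAnnotation) -> float:
    """Fraction of a lncNAT's mature length overlapping opposite-strand gene loci."""
    if nat.biotype != "lncNAT":
        raise DataError(f"{nat.id}: antisense overlap fraction requires a lncNAT")
    overlap_bases = 0
    for s, e in nat.exons:
        covered: set[int] = set()
        for gene_id, strand in ref.genes_overlapping(nat.chrom, s, e):
            if strand == nat.strand or nat.strand == "." or strand == ".":
                continue
            gs, ge = ref.gene_by_id(gene_id).span
            lo, hi = max(s, gs), min(e, ge)
            covered.update(range(lo, hi + 1))
        overlap_bases += len(covered)
    if overlap_bases == 0:
        raise DataError(f"{nat.id}: no antisense overlap found despite lncNAT biotype")
    return overlap_bases / nat.length


def _gap(a_end: int, b_start: int) -> int:
    return max(0, b_start - a_end - 1)


def locus_distances(
    lncrnas: list[TranscriptModel], ref: GenomeAnnotation
) -> DistanceSummary:
    """Gene-level distance lists: each lncRNA to its nearest coding gene,
    consecutive coding gene to gene, and all intron lengths of coding
    transcripts.  A chromosome with one gene contributes no gene-gene
    interval; a lncRNA overlapping a gene is at distance 0."""
    genes_by_chrom: dict[str, list] = {}
    for g in ref.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g.span)
    for spans in genes_by_chrom.values():
        spans.sort()

    lnc_to_gene = []
    for tx in lncrnas:
        spans = genes_by_chrom.get(tx.chrom, [])
        if not spans:
            continue
        ts, te = tx.span
        best = None
        for gs, ge in spans:
            if ge < ts:
                d = _gap(ge, ts)
            elif te < gs:
                d = _gap(te, gs)
            else:
                d = 0
            best = d if best is None else min(best, d)
        lnc_to_gene.append(best)

    gene_to_gene = []
    for spans in genes_by_chrom.values():
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            gene_to_gene.append(_gap(e1, s2) if s2 > e1 else 0)

    intron_lengths = []
    for g in ref.genes:
        for t in g.transcripts:
            intron_lengths.extend(ie - is_ + 1 for is_, ie in t.introns)

    return DistanceSummary(lnc_to_gene, gene_to_gene, intron_lengths)


def compare_expression_distributions(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test; returns (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("KS comparison requires two non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
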