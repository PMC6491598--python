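"""lncRNA identification: class-code assignment against a reference annotation
and the five-criterion filter funnel (length, coding potential, protein
domains, strand, expression), with a per-step audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model import (
    DataError,
    ExpressionMatrix,
    GenomeAnnotation,
    TranscriptModel,
    collapse_replicates,
)

LNC_CLASS_CODES = ("u", "x", "i")


@dataclass
class IdentificationConfig:
    """Thresholds of the lncRNA filter funnel.

    ``min_length_nt`` is an exclusive bound (a transcript must be strictly
    longer); ``max_cpc_score`` is a strict upper bound (CPC score must be
    strictly below it, so the default rejects score 0); the FPKM thresholds
    are inclusive and applied to the maximum over samples ("in at least one
    sample"), with single-exon transcripts held to the higher bar.
    """

    min_length_nt: int = 200
    max_cpc_score: float = 0.0
    require_no_pfam: bool = True
    require_strand: bool = True
    min_fpkm_multiexon: float = 0.5
    min_fpkm_monoexon: float = 2.0

    def __post_init__(self) -> None:
        if self.min_fpkm_monoexon < self.min_fpkm_multiexon:
            raise DataError(
                "single-exon FPKM threshold must be >= multi-exon threshold"
            )


@dataclass
class FunnelStep:
    name: str
    n_in: int
    n_out: int
    rejected_ids: list[str] = field(default_factory=list)


@dataclass
class FilterFunnel:
    """Ordered audit of the filter: survivors of step k enter step k+1."""

    steps: list[FunnelStep] = field(default_factory=list)

    def add(self, name: str, entrants: list[str], survivors: list[str]) -> None:
        rejected = sorted(set(entrants) - set(survivors))
        step = FunnelStep(name, len(entrants), len(survivors), rejected)
        if self.steps:
            prev = self.steps[-1]
            if step.n_in != prev.n_out:
                raise DataError(
                    f"funnel step {name}: entrants {step.n_in} != previous survivors {prev.n_out}"
                )
        if step.n_out > step.n_in:
            raise DataError(f"funnel step {name}: survivors exceed entrants")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": s.name, "entering": s.n_in, "surviving": s.n_out,
                 "rejected": len(s.rejected_ids)}
                for s in self.steps
            ]
        )


def _class_code_one(tx: TranscriptModel, ref: GenomeAnnotation) -> tuple[str, bool]:
    """Classify one candidate; returns (code, antisense_locus_overlap)."""
    if tx.chrom not in ref.chromosomes:
        raise DataError(f"candidate {tx.id}: chromosome {tx.chrom} absent from reference")
    loci = []
    for s, e in tx.exons:
        loci.extend(ref.genes_overlapping(tx.chrom, s, e))
    loci = sorted(set(loci))
    antisense = any(
        strand != tx.strand and tx.strand != "." and strand != "."
        for _, strand in loci
    )
    if not loci:
        return "u", False

    exon_hits = []
    for s, e in tx.exons:
        exon_hits.extend(ref.exons_overlapping(tx.chrom, s, e))
    sense_exonic = any(st == tx.strand for _, _, st in exon_hits)
    antisense_exonic = any(
        st != tx.strand and tx.strand != "." and st != "." for _, _, st in exon_hits
    )
    if sense_exonic:
        return "other", antisense
    if antisense_exonic:
        return "x", True

    # fully inside one intron of some reference transcript?
    span_s, span_e = tx.span
    for gene_id, _ in loci:
        gene = ref.gene_by_id(gene_id)
        for rtx in gene.transcripts:
            for is_, ie in rtx.introns:
                if is_ <= span_s and span_e <= ie:
                    return "i", antisense
    return "other", antisense


def assign_class_codes(
    candidates: list[TranscriptModel], ref: GenomeAnnotation
) -> list[TranscriptModel]:
    """Assign exactly one class code to every candidate.

    'u': no base overlaps any reference gene locus; 'x': >=1 bp exonic
    overlap with a reference exon on the opposite strand; 'i': contained
    entirely within a reference intron; 'other': sense exonic overlap or
    any remaining partial structure.
    """
    out = []
    for tx in candidates:
        code, antisense = _class_code_one(tx, ref)
        out.append(tx.copy(class_code=code, antisense_overlap=antisense))
    return out


def filter_lncrna(
    candidates: list[TranscriptModel],
    scores: pd.DataFrame,
    expr: ExpressionMatrix,
    cfg: IdentificationConfig | None = None,
) -> tuple[list[TranscriptModel], list[TranscriptModel], FilterFunnel]:
    """Run the filter funnel over class-coded candidates.

    ``scores`` must have columns ``id, cpc_score, pfam_hit`` covering every
    candidate.  Steps, in order: class code in {u,x,i}; length > 200 nt;
    CPC score < 0 (strict); no Pfam domain hit; strand known; expression
    (max FPKM over collapsed conditions >= 0.5 for multi-exon, >= 2 for
    single-exon transcripts).

    Returns (accepted, low_confidence, funnel).  ``low_confidence`` holds
    transcripts that pass every sequence-level criterion but fail only the
    strand or expression step.
    """
    cfg = cfg or IdentificationConfig()
    stab = scores.set_index("id") if "id" in scores.columns else scores
    missing = [t.id for t in candidates if t.id not in stab.index]
    if missing:
        raise DataError(f"no coding-potential scores for: {missing[:5]}")
    missing_expr = [t.id for t in candidates if t.id not in expr.values.index]
    if missing_expr:
        raise DataError(f"no expression rows for: {missing_expr[:5]}")

    if expr.samples["replicate"].notna().any():
        expr = collapse_replicates(expr)
    row_max = expr.row_max()

    funnel = FilterFunnel()
    current = list(candidates)

    def run_step(name: str, predicate) -> None:
        nonlocal current
        entrants = [t.id for t in current]
        survivors = [t for t in current if predicate(t)]
        funnel.add(name, entrants, [t.id for t in survivors])
        current = survivors

    run_step("class_code", lambda t: t.class_code in LNC_CLASS_CODES)
    run_step("length", lambda t: t.length > cfg.min_length_nt)
    run_step("cpc", lambda t: float(stab.loc[t.id, "cpc_score"]) < cfg.max_cpc_score)
    if cfg.require_no_pfam:
        run_step("pfam", lambda t: not bool(int(stab.loc[t.id, "pfam_hit"])))
    survivors_pre_strand = {t.id for t in current}
    if cfg.require_strand:
        run_step("strand", lambda t: t.strand in ("+", "-"))
    run_step(
        "expression",
        lambda t: float(row_max[t.id])
        >= (cfg.min_fpkm_multiexon if t.n_exons >= 2 else cfg.min_fpkm_monoexon),
    )

    accepted = list(current)
    accepted_ids = {t.id for t in accepted}
    low_confidence = [
        t
        for t in candidates
        if t.id in survivors_pre_strand and t.id not in accepted_ids
    ]
    return accepted, low_confidence, funnel


def classify_biotype(accepted: list[TranscriptModel]) -> list[TranscriptModel]:
    """Partition accepted lncRNAs into lincRNA and lncNAT.

    lncNAT: >=1 bp overlap with a coding-gene locus on the opposite strand
    (class 'x', and 'i' when the host gene is antisense); lincRNA otherwise
    ('u', and sense-intronic 'i').  Requires class codes (and the antisense
    flag set by :func:`assign_class_codes`).
    """
    out = []
    for tx in accepted:
        if tx.class_code not in LNC_CLASS_CODES:
            raise DataError(f"transcript {tx.id}: class code not assigned or not u/x/i")
        if tx.class_code == "x" or (tx.class_code == "i" and tx.antisense_overlap):
            biotype = "lncNAT"
        else:
            biotype = "lincRNA"
        out.append(tx.copy(biotype=biotype))
    return out
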