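"""Core domain types and readers/writers for annotation, expression and binding data.

Coordinates are GTF-style throughout: 1-based, inclusive on both ends.
The only place half-open coordinates appear is inside the interval index
(:mod:`intervaltree` wants them), and the conversion is confined to
:class:`GenomeAnnotation`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")
VALID_CLASS_CODES = ("u", "x", "i", "other", "none")
VALID_BIOTYPES = ("coding", "lincRNA", "lncNAT", "candidate", "rejected")
BINDING_MODES = ("perfect", "mimic")


class DataError(ValueError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A file failed to parse; carries a line number when known."""


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome.

    ``exons`` are 1-based inclusive ``(start, end)`` pairs, sorted and
    non-overlapping.  ``class_code`` follows the reference-comparison
    convention: 'u' intergenic, 'x' exonic antisense overlap, 'i' intronic
    containment, 'other' anything else, 'none' not yet assigned.
    ``antisense_overlap`` records whether the transcript overlaps a
    reference gene locus on the opposite strand (set during class-code
    assignment; used for the lincRNA/lncNAT split of intronic transcripts).
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    class_code: str = "none"
    biotype: str = "candidate"
    antisense_overlap: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise DataError(f"transcript {self.id}: invalid strand {self.strand!r}")
        if self.class_code not in VALID_CLASS_CODES:
            raise DataError(f"transcript {self.id}: invalid class code {self.class_code!r}")
        if self.biotype not in VALID_BIOTYPES:
            raise DataError(f"transcript {self.id}: invalid biotype {self.biotype!r}")
        if not self.exons:
            raise DataError(f"transcript {self.id}: no exons")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in exons:
            if s < 1 or e < s:
                raise DataError(f"transcript {self.id}: bad exon ({s},{e})")
            if s <= prev_end:
                raise DataError(f"transcript {self.id}: overlapping exons")
            prev_end = e
        self.exons = exons
        if self.strand == "." and self.biotype not in ("candidate", "rejected"):
            raise DataError(
                f"transcript {self.id}: unknown strand is only allowed for candidates"
            )

    @property
    def length(self) -> int:
        """Mature transcript length: sum of exon lengths (nt)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def copy(self, **changes) -> "TranscriptModel":
        return replace(self, exons=list(self.exons), **changes)


@dataclass
class GeneModel:
    """A gene locus: one or more transcripts sharing an id, chromosome, strand."""

    id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


class GenomeAnnotation:
    """A validated gene annotation with per-chromosome interval indexes.

    ``chromosomes`` maps name -> length in bp.  Two indexes are kept per
    chromosome: gene loci (spans) and individual exons, both as interval
    trees keyed half-open internally.
    """

    def __init__(self, chromosomes: dict[str, int], genes: list[GeneModel]):
        self.chromosomes = dict(chromosomes)
        self.genes = list(genes)
        self._locus_index: dict[str, IntervalTree] = {}
        self._exon_index: dict[str, IntervalTree] = {}
        self._validate_and_index()

    def _validate_and_index(self) -> None:
        seen_genes: set[str] = set()
        seen_tx: set[str] = set()
        for gene in self.genes:
            if gene.id in seen_genes:
                raise DataError(f"duplicate gene id {gene.id}")
            seen_genes.add(gene.id)
            if gene.chrom not in self.chromosomes:
                raise DataError(f"gene {gene.id}: unknown chromosome {gene.chrom}")
            clen = self.chromosomes[gene.chrom]
            for tx in gene.transcripts:
                if tx.id in seen_tx:
                    raise DataError(f"duplicate transcript id {tx.id}")
                seen_tx.add(tx.id)
                for s, e in tx.exons:
                    if e > clen:
                        raise DataError(
                            f"transcript {tx.id}: exon ({s},{e}) outside "
                            f"chromosome {gene.chrom} (length {clen})"
                        )
                tree = self._exon_index.setdefault(gene.chrom, IntervalTree())
                for s, e in tx.exons:
                    # 1-based inclusive -> half-open
                    tree.addi(s, e + 1, (gene.id, tx.id, gene.strand))
            s, e = gene.span
            self._locus_index.setdefault(gene.chrom, IntervalTree()).addi(
                s, e + 1, (gene.id, gene.strand)
            )

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts]

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, str]]:
        """Gene loci overlapping [start, end] (1-based inclusive) as (gene_id, strand)."""
        tree = self._locus_index.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def exons_overlapping(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[str, str, str]]:
        """Reference exons overlapping [start, end] as (gene_id, transcript_id, strand)."""
        tree = self._exon_index.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def _sniff_format(path: str) -> str:
    """Return 'gtf' or 'gff3' by inspecting the attribute column."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9:
                attrs = fields[8]
                if "=" in attrs and ' "' not in attrs:
                    return "gff3"
                return "gtf"
    return "gtf"


def _prevalidate(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected >=8 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")


def read_transcripts(path: str) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Read transcripts from a GTF or GFF3 file.

    Returns the transcript list plus declared chromosome lengths
    (``##sequence-region`` pragmas when present, else inferred as the
    maximum end coordinate per chromosome).
    """
    _prevalidate(path)
    fmt = _sniff_format(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    declared: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            declared[parts[1]] = int(parts[3])

    # transcript-level attributes (class_code/biotype round-trip)
    tx_attrs: dict[str, dict[str, str]] = {}
    tx_parent: dict[str, str] = {}
    for ftype in ("transcript", "mRNA", "lnc_RNA", "ncRNA"):
        for f in db.features_of_type(ftype):
            if fmt == "gff3":
                tid = f.attributes.get("ID", [f.id])[0]
                parent = f.attributes.get("Parent", [tid])[0]
            else:
                tid = f.attributes.get("transcript_id", [f.id])[0]
                parent = f.attributes.get("gene_id", [tid])[0]
            tx_parent[tid] = parent
            attrs = {}
            for key in ("class_code", "biotype"):
                if key in f.attributes:
                    attrs[key] = f.attributes[key][0]
            tx_attrs[tid] = attrs

    grouped: dict[str, dict] = {}
    for f in db.features_of_type("exon"):
        if fmt == "gff3":
            tid = f.attributes.get("Parent", [None])[0]
            gid = tx_parent.get(tid, tid)
        else:
            tid = f.attributes.get("transcript_id", [None])[0]
            gid = f.attributes.get("gene_id", [tid])[0]
        if tid is None:
            raise ParseError(f"{path}: exon feature without a transcript identifier")
        rec = grouped.setdefault(
            tid, {"gene": gid, "chrom": f.seqid, "strand": f.strand or ".", "exons": []}
        )
        rec["exons"].append((f.start, f.end))

    transcripts = []
    for tid, rec in grouped.items():
        attrs = tx_attrs.get(tid, {})
        transcripts.append(
            TranscriptModel(
                id=tid,
                gene_id=rec["gene"],
                chrom=rec["chrom"],
                strand=rec["strand"] if rec["strand"] in VALID_STRANDS else ".",
                exons=sorted(rec["exons"]),
                class_code=attrs.get("class_code", "none"),
                biotype=attrs.get("biotype", "candidate"),
            )
        )
    transcripts.sort(key=lambda t: t.id)

    chrom_lengths = dict(declared)
    for t in transcripts:
        if t.chrom not in chrom_lengths:
            chrom_lengths[t.chrom] = 0
        if not declared:
            chrom_lengths[t.chrom] = max(chrom_lengths[t.chrom], t.span[1])
        elif t.chrom not in declared:
            chrom_lengths[t.chrom] = max(chrom_lengths.get(t.chrom, 0), t.span[1])
    return transcripts, chrom_lengths


def read_annotation(path: str) -> GenomeAnnotation:
    """Read a GTF/GFF3 reference annotation into a validated :class:`GenomeAnnotation`."""
    transcripts, chrom_lengths = read_transcripts(path)
    genes: dict[str, GeneModel] = {}
    for t in transcripts:
        t = t.copy(biotype="coding" if t.strand != "." else t.biotype)
        g = genes.setdefault(t.gene_id, GeneModel(t.gene_id, t.chrom, t.strand))
        if g.chrom != t.chrom:
            raise DataError(f"gene {t.gene_id}: transcripts on multiple chromosomes")
        g.transcripts.append(t)
    return GenomeAnnotation(chrom_lengths, sorted(genes.values(), key=lambda g: g.id))


def write_gtf(transcripts: list[TranscriptModel], path: str, source: str = "camlnc") -> None:
    """Write transcripts as GTF (transcript + exon lines, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.span[0], t.id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
            if t.class_code != "none":
                attrs += f' class_code "{t.class_code}";'
            attrs += f' biotype "{t.biotype}";'
            s, e = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for es, ee in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{es}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Transcripts x samples matrix of non-negative FPKM with sample metadata.

    ``values``: DataFrame indexed by transcript id, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``tissue``,
    ``time_hour`` (float or NaN; all present or all absent) and
    ``replicate`` (nullable integer).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        values = values.astype(float)
        if values.index.has_duplicates:
            raise DataError("duplicate transcript ids in expression matrix")
        if values.columns.has_duplicates:
            raise DataError("duplicate sample ids in expression matrix")
        if (values.values < 0).any():
            bad = values[(values < 0).any(axis=1)].index[0]
            raise DataError(f"negative FPKM for transcript {bad}")
        missing = [c for c in values.columns if c not in samples.index]
        if missing:
            raise DataError(f"samples missing from sample sheet: {missing}")
        samples = samples.loc[list(values.columns)]
        th = samples["time_hour"]
        if th.notna().any() and th.isna().any():
            raise DataError("time_hour must be present for all samples or none")
        self.values = values
        self.samples = samples

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def has_time(self) -> bool:
        return bool(self.samples["time_hour"].notna().all()) and len(self.samples) > 0

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        ids = [t for t in transcript_ids if t in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.samples)

    def row_max(self) -> pd.Series:
        return self.values.max(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy())


def _condition_label(tissue: str, time_hour) -> str:
    if pd.isna(time_hour):
        return str(tissue)
    th = float(time_hour)
    return f"{tissue}@{th:g}h"


def collapse_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns into one column per (tissue, time point).

    Columns are labelled ``tissue`` or ``tissue@<hour>h``; the replicate
    field is cleared.  Order of first appearance is preserved.
    """
    keys = [
        (row.tissue, row.time_hour if pd.notna(row.time_hour) else None)
        for row in m.samples.itertuples()
    ]
    order: list[tuple] = []
    groups: dict[tuple, list[str]] = {}
    for sample, key in zip(m.samples.index, keys):
        if key not in groups:
            order.append(key)
            groups[key] = []
        groups[key].append(sample)
    cols = {}
    meta_rows = []
    for key in order:
        members = groups[key]
        if not members:
            raise DataError(f"no replicates for condition {key}")
        label = _condition_label(key[0], key[1] if key[1] is not None else np.nan)
        cols[label] = m.values[members].mean(axis=1)
        meta_rows.append(
            {"sample": label, "tissue": key[0],
             "time_hour": key[1] if key[1] is not None else np.nan,
             "replicate": pd.NA}
        )
    values = pd.DataFrame(cols, index=m.values.index)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values, samples)


def average_by_tissue(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average all columns of each tissue into a single tissue column.

    Used to fold multi-stage tissues (e.g. six fruit development stages)
    into one profile component per tissue before specificity scoring.
    """
    collapsed = collapse_replicates(m)
    tissues: list[str] = []
    for t in collapsed.samples["tissue"]:
        if t not in tissues:
            tissues.append(t)
    cols = {}
    for tissue in tissues:
        members = collapsed.samples.index[collapsed.samples["tissue"] == tissue]
        cols[tissue] = collapsed.values[list(members)].mean(axis=1)
    values = pd.DataFrame(cols, index=m.values.index)
    samples = pd.DataFrame(
        {"sample": tissues, "tissue": tissues,
         "time_hour": np.nan, "replicate": pd.NA}
    ).set_index("sample")
    return ExpressionMatrix(values, samples)


def concat_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-wise concatenation of two matrices over the same transcripts."""
    if list(a.values.index) != list(b.values.index):
        raise DataError("matrices have different transcript sets")
    values = pd.concat([a.values, b.values], axis=1)
    samples = pd.concat([a.samples, b.samples], axis=0)
    return ExpressionMatrix(values, samples)


def read_expression(path: str, sample_sheet: str | None = None) -> ExpressionMatrix:
    """Read a transcripts x samples TSV (+ optional sample sheet TSV).

    The sheet has columns ``sample, tissue, time_hour, replicate``; without
    a sheet each column is treated as its own tissue.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    for col in values.columns:
        try:
            values[col] = pd.to_numeric(values[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col}: {exc}") from None
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t", dtype={"sample": str, "tissue": str})
        sheet = sheet.set_index("sample")
        if "time_hour" not in sheet.columns:
            sheet["time_hour"] = np.nan
        if "replicate" not in sheet.columns:
            sheet["replicate"] = pd.NA
        sheet["replicate"] = sheet["replicate"].astype("Int64")
        missing = [c for c in values.columns if c not in sheet.index]
        if missing:
            raise DataError(f"{path}: samples not in sheet {sample_sheet}: {missing}")
        samples = sheet
    else:
        samples = pd.DataFrame(
            {"sample": list(values.columns), "tissue": list(values.columns),
             "time_hour": np.nan, "replicate": pd.NA}
        ).set_index("sample")
    return ExpressionMatrix(values, samples)


def write_expression(
    m: ExpressionMatrix, path: str, sample_sheet: str | None = None
) -> None:
    out = m.values.copy()
    out.index.name = "transcript_id"
    # no float_format: full repr keeps write->read an exact round trip
    out.to_csv(path, sep="\t")
    if sample_sheet is not None:
        sheet = m.samples.copy()
        sheet.index.name = "sample"
        sheet.to_csv(sample_sheet, sep="\t", float_format="%g")


# ---------------------------------------------------------------------------
# miRNA binding tables
# ---------------------------------------------------------------------------


@dataclass
class BindingTable:
    """(miRNA, transcript, mode) records; mode is 'perfect' or 'mimic'."""

    records: pd.DataFrame  # columns: mirna, transcript, mode

    def __post_init__(self) -> None:
        df = self.records
        required = ["mirna", "transcript", "mode"]
        if list(df.columns)[:3] != required:
            df = df[required]
        bad = set(df["mode"]) - set(BINDING_MODES)
        if bad:
            raise DataError(f"invalid binding modes: {sorted(bad)}")
        if df.duplicated().any():
            raise DataError("duplicate (mirna, transcript, mode) records")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def transcripts(self) -> list[str]:
        return sorted(set(self.records["transcript"]))

    def mirnas(self) -> list[str]:
        return sorted(set(self.records["mirna"]))


def read_bindings(path: str) -> BindingTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return BindingTable(df)


def write_bindings(table: BindingTable, path: str) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
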