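"""Domain types, coordinate conventions and readers/writers for the standard formats.

All genomic coordinates are GTF-style: 1-based, inclusive on both ends.
Sequences are upper-case DNA over {A,C,G,T,N}; spliced transcript sequences
are reported 5'->3' on the transcript strand (i.e. reverse-complemented for
minus-strand transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = {"+", "-", "."}
TISSUES = ("T", "E", "DD")


class ValidationError(ValueError):
    """Raised when a domain object or input file violates an invariant."""


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval (1-based, inclusive)."""

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(
                f"interval start must be >= 1 (1-based), got {self.start}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"interval end ({self.end}) < start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript's exon structure plus (optionally) its spliced sequence.

    Exons are sorted by start, non-overlapping, and share one chromosome and
    strand. ``sequence`` is the exon-ordered spliced sequence on the
    transcript strand; when present its length equals the summed exon length.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    sequence: str | None = None
    biotype: str = "other"  # protein_coding | known_lncRNA | novel | other

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chromosome for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons on multiple chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValidationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"spliced length {self.spliced_length}"
            )

    @property
    def chromosome(self) -> str:
        return self.exons[0].chromosome

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chromosome, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneModel:
    """A gene locus: the union span of its member transcripts."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene needs >= 1 transcript")
        chroms = {t.chromosome for t in self.transcripts}
        if len(chroms) > 1:
            raise ValidationError(f"{self.gene_id}: transcripts on multiple chromosomes")

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        strands = {t.strand for t in self.transcripts}
        strand = strands.pop() if len(strands) == 1 else "."
        return GenomicInterval(self.transcripts[0].chromosome, start, end, strand)


# ---------------------------------------------------------------------------
# GTF


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read an exon-feature GTF into one :class:`GeneModel` per gene_id.

    Only ``exon`` features are used. Coordinates are kept 1-based inclusive.
    Raises :class:`GtfParseError` (with the line number) on malformed lines
    and :class:`ValidationError` on coordinate violations.
    """
    per_transcript: dict[str, dict] = {}
    transcript_order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"expected 9 tab-separated fields, got {len(fields)}", ln)
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", ln)
            if start < 1:
                raise ValidationError(f"line {ln}: start {start} violates 1-based convention")
            if end < start:
                raise ValidationError(f"line {ln}: exon end {end} < start {start}")
            attrs = _parse_attributes(attr)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError("exon lacks gene_id/transcript_id attribute", ln)
            tid = attrs["transcript_id"]
            if tid not in per_transcript:
                per_transcript[tid] = {
                    "gene_id": attrs["gene_id"],
                    "biotype": attrs.get("transcript_biotype", attrs.get("gene_biotype", "other")),
                    "exons": [],
                }
                transcript_order.append(tid)
            per_transcript[tid]["exons"].append(GenomicInterval(chrom, start, end, strand))

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in transcript_order:
        rec = per_transcript[tid]
        tm = TranscriptModel(tid, rec["gene_id"], rec["exons"], biotype=rec["biotype"])
        if rec["gene_id"] not in genes:
            genes[rec["gene_id"]] = []
            gene_order.append(rec["gene_id"])
        genes[rec["gene_id"]].append(tm)
    return [GeneModel(gid, genes[gid]) for gid in gene_order]


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "lncreg") -> None:
    """Write exon-feature GTF that :func:`read_gtf` round-trips."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for exon in t.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'transcript_biotype "{t.biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.chromosome,
                                source,
                                "exon",
                                str(exon.start),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (wrapped or unwrapped) multi-FASTA into an ordered id->sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_transcript_sequences(
    genome: Mapping[str, str], genes: Sequence[GeneModel]
) -> Sequence[GeneModel]:
    """Fill each transcript's spliced sequence from a genome id->sequence map.

    The sequence is the exon-ordered concatenation (exons sorted by start),
    reverse-complemented for minus-strand transcripts. Modifies the gene
    models in place and returns them.
    """
    for gene in genes:
        for t in gene.transcripts:
            if t.chromosome not in genome:
                raise LookupError(f"chromosome {t.chromosome!r} missing from genome")
            chrom_seq = genome[t.chromosome]
            parts = []
            for exon in t.exons:
                if exon.end > len(chrom_seq):
                    raise IndexError(
                        f"{t.transcript_id}: exon end {exon.end} beyond chromosome "
                        f"{t.chromosome} length {len(chrom_seq)}"
                    )
                parts.append(chrom_seq[exon.start - 1 : exon.end])
            seq = "".join(parts)
            if t.strand == "-":
                seq = reverse_complement(seq)
            t.sequence = seq
    return genes


# ---------------------------------------------------------------------------
# Count / expression matrices


@dataclass
class CountMatrix:
    """Integer fragment counts, features x samples, with tissue/replicate metadata.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    ``samples`` is a DataFrame indexed by sample id with columns
    ``tissue`` (one of T/E/DD by default) and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValidationError("count matrix row/column labels must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("count matrix contains negative entries")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("count columns do not match sample sheet order")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_for_tissue(self, tissue: str) -> list[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(counts_path, sep="\t", index_label="feature_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        return cls(values=values, samples=samples)


@dataclass
class ExpressionMatrix:
    """FPKM values with the same layout as :class:`CountMatrix`."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def compute_fpkm(counts: CountMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """FPKM[i,j] = counts[i,j] / ((length_i/1e3) * (libsize_j/1e6)).

    The library size is the per-sample total count over all matrix features.
    Zero-length features and all-zero sample columns are rejected.
    """
    lens = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    if (lens <= 0).any():
        bad = [f for f in counts.feature_ids if lengths[f] <= 0]
        raise ValidationError(f"zero/negative feature length for {bad[:3]}")
    libsize = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (libsize <= 0).any():
        raise ValidationError("all-zero sample column: library size undefined")
    fpkm = counts.values.to_numpy(dtype=float) / (
        (lens[:, None] / 1e3) * (libsize[None, :] / 1e6)
    )
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        samples=counts.samples,
    )
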