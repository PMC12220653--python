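"""GFF3/FASTA I/O, longest-isoform selection and CDS translation.

Internal coordinates are 0-based half-open throughout; GFF3's 1-based
inclusive convention is converted at the file boundary. "Longest isoform"
is measured in translated protein length (amino acids), with ties broken
by lexicographically smallest transcript ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FastaError, FrameError, Gff3ParseError, Gff3StructuralError

logger = logging.getLogger(__name__)

_VALID_STRANDS = frozenset("+-")


@dataclass(frozen=True)
class GenomeSequence:
    """One nucleotide sequence of an assembly, upper-cased on input."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of CDS genome intervals with phase.

    ``cds_segments`` holds ``(start, end, phase)`` triples in 0-based
    half-open genome coordinates, sorted by start and non-overlapping.
    """

    transcript_id: str
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def total_cds_length(self) -> int:
        return sum(end - start for start, end, _ in self.cds_segments)

    def coding_length(self, strand: str) -> int:
        """CDS length in bases after trimming the first segment's phase."""
        if not self.cds_segments:
            return 0
        return self.total_cds_length - self.first_phase(strand)

    def first_phase(self, strand: str) -> int:
        """Phase of the first CDS segment in transcription order."""
        if not self.cds_segments:
            return 0
        seg = self.cds_segments[0] if strand == "+" else self.cds_segments[-1]
        return seg[2]

    def protein_length(self, strand: str) -> int:
        """Translated length in amino acids (a trailing stop still counts
        one codon here; the comparison is uniform across isoforms)."""
        return self.coding_length(strand) // 3


@dataclass
class GeneModel:
    """A gene with its transcripts on a named sequence; the audited unit."""

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def cds_footprint(self) -> list[tuple[int, int]]:
        """Union of all CDS intervals across transcripts, merged and sorted."""
        ivs = sorted(
            (s, e) for t in self.transcripts for s, e, _ in t.cds_segments
        )
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein with provenance."""

    protein_id: str
    sequence: str
    source: str = "reference"  # reference | alternate | database
    gene_id: str = ""
    transcript_id: str = ""
    internal_stop: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


class AnnotationSet:
    """Collection of :class:`GeneModel` keyed by gene_id, order-preserving."""

    def __init__(self, genes: list[GeneModel] | None = None):
        self._genes: dict[str, GeneModel] = {}
        for g in genes or []:
            if g.gene_id in self._genes:
                raise Gff3StructuralError(f"duplicate gene ID {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self._genes.values())


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"found {len(cols)}"
                )
            if "=" not in cols[8] and cols[8] != ".":
                raise Gff3ParseError(
                    f"{path}:{lineno}: malformed attribute column {cols[8]!r}"
                )


def parse_gff3(path: str | Path) -> AnnotationSet:
    """Read a GFF3 file with gene → mRNA → CDS features into an AnnotationSet.

    Coordinates are converted from GFF3 1-based inclusive to internal
    0-based half-open. Genes or transcripts on an unknown strand ('.') and
    CDS features without a resolvable gene ancestor are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise Gff3ParseError(f"GFF3 file not found: {path}")
    _prevalidate_gff3(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises bare ValueError on bad lines
        raise Gff3ParseError(f"could not parse {path}: {exc}") from exc

    genes: list[GeneModel] = []
    transcript_index: dict[str, TranscriptModel] = {}
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        if gf.strand not in _VALID_STRANDS:
            raise Gff3StructuralError(
                f"gene {gf.id!r} has unknown strand {gf.strand!r}"
            )
        gene = GeneModel(
            gene_id=gf.id,
            seq_id=gf.seqid,
            strand=gf.strand,
            start=gf.start - 1,
            end=gf.end,
        )
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), order_by="start"):
            if tf.strand != gf.strand:
                raise Gff3StructuralError(
                    f"transcript {tf.id!r} strand differs from gene {gf.id!r}"
                )
            tm = TranscriptModel(transcript_id=tf.id)
            for cf in db.children(tf, featuretype="CDS", order_by="start"):
                phase = int(cf.frame) if cf.frame in {"0", "1", "2"} else 0
                tm.cds_segments.append((cf.start - 1, cf.end, phase))
            tm.cds_segments.sort()
            gene.transcripts.append(tm)
            transcript_index[tf.id] = tm
        genes.append(gene)

    # orphan CDS check: every CDS must reach a gene through its Parent chain
    for cf in db.features_of_type("CDS"):
        parents = cf.attributes.get("Parent", [])
        if not parents:
            raise Gff3StructuralError(f"CDS {cf.id!r} has no Parent attribute")
        for pid in parents:
            if pid not in transcript_index:
                try:
                    db[pid]
                except gffutils.FeatureNotFoundError:
                    raise Gff3StructuralError(
                        f"CDS {cf.id!r} references missing Parent {pid!r}"
                    ) from None
                raise Gff3StructuralError(
                    f"CDS {cf.id!r} has no resolvable gene ancestor "
                    f"(Parent {pid!r} is not an mRNA/transcript)"
                )
    return AnnotationSet(genes)


def write_gff3(annotations: AnnotationSet, path: str | Path) -> None:
    """Write gene/mRNA/CDS features back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotations:
            fh.write(
                f"{gene.seq_id}\tchimeraudit\tgene\t{gene.start + 1}\t"
                f"{gene.end}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for tm in gene.transcripts:
                t_start = min(s for s, _, _ in tm.cds_segments) if tm.cds_segments else gene.start
                t_end = max(e for _, e, _ in tm.cds_segments) if tm.cds_segments else gene.end
                fh.write(
                    f"{gene.seq_id}\tchimeraudit\tmRNA\t{t_start + 1}\t{t_end}\t.\t"
                    f"{gene.strand}\t.\tID={tm.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, (s, e, phase) in enumerate(tm.cds_segments):
                    fh.write(
                        f"{gene.seq_id}\tchimeraudit\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t{phase}\t"
                        f"ID={tm.transcript_id}.cds{i};Parent={tm.transcript_id}\n"
                    )


def select_longest_isoform(annotations: AnnotationSet) -> AnnotationSet:
    """Keep one transcript per gene: the one with the longest translated
    protein, ties broken by lexicographically smallest transcript ID.

    Genes with no coding transcript are dropped with a logged warning.
    """
    kept: list[GeneModel] = []
    n_dropped = 0
    for gene in annotations:
        coding = [t for t in gene.transcripts if t.total_cds_length >= 3]
        if not coding:
            n_dropped += 1
            logger.warning("gene %s has no coding transcript; dropped", gene.gene_id)
            continue
        best = max(
            coding,
            key=lambda t: (t.protein_length(gene.strand), _neg_lex(t.transcript_id)),
        )
        kept.append(
            GeneModel(
                gene_id=gene.gene_id,
                seq_id=gene.seq_id,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                transcripts=[best],
            )
        )
    if n_dropped:
        logger.info("dropped %d non-coding genes during isoform selection", n_dropped)
    return AnnotationSet(kept)


class _neg_lex(str):
    """Reverses lexicographic order so max() prefers the smallest ID."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_protein(gene: GeneModel, genome: GenomeSequence) -> ProteinRecord:
    """Translate the gene's single transcript with the standard genetic code.

    CDS segments are concatenated in transcription order (reverse-complement
    for '-' strand), the first segment's phase is trimmed, a single trailing
    stop is removed, and codons containing N translate to 'X'. An internal
    stop leaves '*' in the sequence and flags the record.
    """
    if len(gene.transcripts) != 1:
        raise ValueError(
            f"gene {gene.gene_id} has {len(gene.transcripts)} transcripts; "
            "run select_longest_isoform first"
        )
    tm = gene.transcripts[0]
    for s, e, _ in tm.cds_segments:
        if s < 0 or e > genome.length:
            raise Gff3StructuralError(
                f"CDS [{s},{e}) of {tm.transcript_id} outside sequence "
                f"{genome.seq_id} (length {genome.length})"
            )
    parts = [genome.residues[s:e] for s, e, _ in tm.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    phase = tm.first_phase(gene.strand)
    cds = cds[phase:]
    if len(cds) % 3 != 0:
        raise FrameError(
            f"CDS of transcript {tm.transcript_id} has length {len(cds)} "
            f"after phase trim; not a codon multiple"
        )
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    internal_stop = "*" in aa
    if internal_stop:
        logger.warning(
            "internal stop codon in translation of %s", tm.transcript_id
        )
    return ProteinRecord(
        protein_id=gene.gene_id,
        sequence=aa,
        source="reference",
        gene_id=gene.gene_id,
        transcript_id=tm.transcript_id,
        internal_stop=internal_stop,
    )


def extract_proteins(
    annotations: AnnotationSet,
    genome: dict[str, GenomeSequence],
    source: str = "reference",
) -> list[ProteinRecord]:
    """Translate every gene of a longest-isoform-reduced annotation set."""
    records = []
    for gene in annotations:
        if gene.seq_id not in genome:
            raise Gff3StructuralError(
                f"gene {gene.gene_id} is on unknown sequence {gene.seq_id!r}"
            )
        rec = extract_protein(gene, genome[gene.seq_id])
        records.append(
            ProteinRecord(
                protein_id=rec.protein_id,
                sequence=rec.sequence,
                source=source,
                gene_id=rec.gene_id,
                transcript_id=rec.transcript_id,
                internal_stop=rec.internal_stop,
            )
        )
    return records


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a nucleotide FASTA into seq_id → GenomeSequence (upper-cased)."""
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaError(f"duplicate sequence ID {rec.id!r} in {path}")
        out[rec.id] = GenomeSequence(seq_id=rec.id, residues=str(rec.seq).upper())
    return out


def read_protein_fasta(path: str | Path, source: str = "database") -> list[ProteinRecord]:
    """Read a protein FASTA; full headers are kept for name-based screens."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=str(rec.seq).upper(),
                source=source,
                gene_id=rec.description,
            )
        )
    return records


def read_fasta_headers(path: str | Path) -> dict[str, str]:
    """Map record ID → full header line (without '>') for a FASTA file."""
    return {rec.id: rec.description for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write proteins as 60-column-wrapped FASTA.

    Headers follow ``>protein_id gene_id=... length=...``. Duplicate IDs and
    empty sequences are rejected before anything is written.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.protein_id in seen:
            raise FastaError(f"duplicate protein_id {rec.protein_id!r}")
        if rec.length == 0:
            raise FastaError(f"protein {rec.protein_id!r} has length 0")
        if any(c.isspace() for c in rec.sequence):
            raise FastaError(f"protein {rec.protein_id!r} contains whitespace")
        seen.add(rec.protein_id)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} gene_id={rec.gene_id} length={rec.length}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
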