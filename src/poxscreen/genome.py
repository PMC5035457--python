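"""Genome sequence and gene-model handling.

Reads a multi-contig genome (FASTA) together with gene models (GFF3),
reconstructs spliced coding sequences strand-aware, and computes the
summary statistics usually reported for a draft fungal genome (size, GC
content, gene count, mean gene/intron/exon geometry).

Coordinates are 0-based half-open internally; the GFF3/VCF readers and
writers convert at the boundary.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Raised on malformed or inconsistent genome inputs."""


@dataclass(frozen=True)
class Contig:
    """A single assembled sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A strand-aware protein-coding gene model.

    ``segments`` are CDS segments as 0-based half-open ``(start, end)``
    intervals on the contig, sorted by start and non-overlapping.  For a
    minus-strand gene the first codon of the transcript lies in the
    *last* segment (highest coordinates).
    """

    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    segments: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        segs = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if e1 > s2:
                raise GenomeError(f"gene {self.gene_id}: overlapping CDS segments")
        for s, e in segs:
            if e <= s:
                raise GenomeError(f"gene {self.gene_id}: empty CDS segment ({s},{e})")
        self.segments = segs
        if self.cds_length < 3:
            raise GenomeError(f"gene {self.gene_id}: total CDS length < 3")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first CDS base to last, 0-based half-open)."""
        return self.segments[0][0], self.segments[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def n_introns(self) -> int:
        return len(self.segments) - 1

    @property
    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.segments, self.segments[1:])
        ]

    def translation_start(self) -> int:
        """0-based position of the first base of the start codon."""
        if self.strand == "+":
            return self.segments[0][0]
        return self.segments[-1][1] - 1

    def stop_end(self) -> int:
        """0-based position of the last base of the stop codon."""
        if self.strand == "+":
            return self.segments[-1][1] - 1
        return self.segments[0][0]


class GenomeAnnotation:
    """Contigs plus gene models with per-contig interval lookup."""

    def __init__(self, contigs: list[Contig], genes: list[GeneModel]):
        self.contigs: dict[str, Contig] = {}
        for c in contigs:
            if c.id in self.contigs:
                raise GenomeError(f"duplicate contig id {c.id!r}")
            if len(c.sequence) < 1:
                raise GenomeError(f"contig {c.id!r}: empty sequence")
            self.contigs[c.id] = c
        self.genes: dict[str, GeneModel] = {}
        self._span_index: dict[str, IntervalTree] = {c: IntervalTree() for c in self.contigs}
        self._cds_index: dict[str, IntervalTree] = {c: IntervalTree() for c in self.contigs}
        for g in genes:
            self.add_gene(g)

    def add_gene(self, g: GeneModel) -> None:
        if g.gene_id in self.genes:
            raise GenomeError(f"duplicate gene id {g.gene_id!r}")
        if g.contig_id not in self.contigs:
            raise GenomeError(f"gene {g.gene_id}: unknown contig {g.contig_id!r}")
        clen = len(self.contigs[g.contig_id])
        for s, e in g.segments:
            if s < 0 or e > clen:
                raise GenomeError(
                    f"gene {g.gene_id}: CDS segment ({s},{e}) outside contig "
                    f"{g.contig_id} (length {clen})"
                )
        if g.cds_length % 3 != 0:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3", g.gene_id, g.cds_length
            )
        self.genes[g.gene_id] = g
        s, e = g.span
        self._span_index[g.contig_id][s:e] = g.gene_id
        for cs, ce in g.segments:
            self._cds_index[g.contig_id][cs:ce] = g.gene_id

    def genes_overlapping(self, contig_id: str, start: int, end: int) -> set[str]:
        """Gene ids whose genomic span intersects [start, end)."""
        if contig_id not in self._span_index:
            return set()
        return {iv.data for iv in self._span_index[contig_id].overlap(start, end)}

    def cds_overlapping(self, contig_id: str, start: int, end: int) -> set[str]:
        """Gene ids with a CDS segment intersecting [start, end)."""
        if contig_id not in self._cds_index:
            return set()
        return {iv.data for iv in self._cds_index[contig_id].overlap(start, end)}

    def genes_on(self, contig_id: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.contig_id == contig_id]

    def spliced_cds(self, gene_id: str) -> str:
        """Spliced coding sequence in 5'->3' transcript orientation."""
        return spliced_cds(self, gene_id)


def read_fasta(path: str) -> list[Contig]:
    """Read a multi-record FASTA into Contigs, validating the alphabet."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise GenomeError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise GenomeError(f"{path}: record {rec.id!r} contains U (RNA alphabet)")
        if not _VALID_SEQ.match(seq):
            bad = next(ch for ch in seq if ch not in "ACGTN")
            raise GenomeError(
                f"{path}: record {rec.id!r} contains non-IUPAC-DNA character {bad!r}"
            )
        contigs.append(Contig(rec.id, seq))
    if not contigs:
        raise GenomeError(f"{path}: no FASTA records found")
    return contigs


def read_gff3(path: str, contigs: list[Contig]) -> GenomeAnnotation:
    """Parse gene/mRNA/CDS features into a GenomeAnnotation.

    One gene model per protein-coding gene; when a gene carries several
    mRNA isoforms the first one in file order is retained and a warning
    is logged.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    contig_len = {c.id: len(c.sequence) for c in contigs}
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        if len(mrnas) > 1:
            logger.warning(
                "gene %s: %d mRNA isoforms, keeping first (%s)",
                gene.id, len(mrnas), mrnas[0].id,
            )
        mrna = mrnas[0]
        segments = []
        strand = None
        for cds in db.children(mrna, featuretype="CDS", order_by="start"):
            if cds.strand not in "+-":
                raise GenomeError(
                    f"{path}: CDS of {gene.id} has unknown strand {cds.strand!r}"
                )
            strand = cds.strand
            if gene.seqid not in contig_len:
                raise GenomeError(f"{path}: gene {gene.id} on unknown contig {gene.seqid}")
            if cds.end > contig_len[gene.seqid] or cds.start < 1:
                raise GenomeError(
                    f"{path}: CDS of {gene.id} at {gene.seqid}:{cds.start}-{cds.end} "
                    f"outside contig bounds"
                )
            segments.append((cds.start - 1, cds.end))  # GFF3 1-based inclusive -> 0-based half-open
        if not segments:
            continue
        genes.append(
            GeneModel(gene_id=gene.id, contig_id=gene.seqid, strand=strand, segments=segments)
        )
    # orphan CDS check: every CDS must reach a gene through an mRNA parent
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            raise GenomeError(f"{path}: CDS at {cds.seqid}:{cds.start} has no mRNA parent")
    return GenomeAnnotation(contigs, genes)


def spliced_cds(annotation: GenomeAnnotation, gene_id: str) -> str:
    """Concatenated CDS in transcript order (reverse-complemented for '-')."""
    if gene_id not in annotation.genes:
        raise GenomeError(f"unknown gene id {gene_id!r}")
    g = annotation.genes[gene_id]
    seq = annotation.contigs[g.contig_id].sequence
    plus = "".join(seq[s:e] for s, e in g.segments)
    if g.strand == "+":
        return plus
    return reverse_complement(plus)


def translate(cds: str) -> str:
    """Translate with the standard code, stopping at the first stop codon.

    The terminating stop is rendered as '*'; codons containing N become 'X'.
    """
    if len(cds) < 3:
        raise GenomeError("cannot translate a sequence shorter than one codon")
    usable = cds[: len(cds) // 3 * 3]
    prot = str(Seq(usable).translate(table=1))
    stop = prot.find("*")
    return prot[: stop + 1] if stop >= 0 else prot


def gc_percent(seq: str) -> float:
    """GC percentage over A/C/G/T only (N excluded from the denominator)."""
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    return 100.0 * gc / atgc if atgc else math.nan


@dataclass
class GenomeStats:
    genome_size_bp: int
    gc_genome_pct: float
    gene_count: int
    gc_coding_pct: float
    mean_gene_length_bp: float
    mean_introns_per_gene: float
    mean_intron_size_bp: float
    mean_exon_size_bp: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def genome_stats(annotation: GenomeAnnotation) -> GenomeStats:
    """Draft-genome feature summary.

    Gene length is the genomic span (first to last CDS base); introns are
    the gaps between consecutive CDS segments of a gene.  With zero genes
    the gene-dependent fields are NaN, not zero.
    """
    size = sum(len(c) for c in annotation.contigs.values())
    gc_genome = gc_percent("".join(c.sequence for c in annotation.contigs.values()))
    genes = [g for g in annotation.genes.values() if g.biotype == "protein_coding"]
    if not genes:
        nan = math.nan
        return GenomeStats(size, gc_genome, 0, nan, nan, nan, nan, nan)
    coding = "".join(spliced_cds(annotation, g.gene_id) for g in genes)
    gene_lengths = [g.span[1] - g.span[0] for g in genes]
    intron_sizes = [e - s for g in genes for s, e in g.intron_intervals]
    exon_sizes = [e - s for g in genes for s, e in g.segments]
    return GenomeStats(
        genome_size_bp=size,
        gc_genome_pct=gc_genome,
        gene_count=len(genes),
        gc_coding_pct=gc_percent(coding),
        mean_gene_length_bp=sum(gene_lengths) / len(genes),
        mean_introns_per_gene=sum(g.n_introns for g in genes) / len(genes),
        mean_intron_size_bp=(sum(intron_sizes) / len(intron_sizes)) if intron_sizes else math.nan,
        mean_exon_size_bp=sum(exon_sizes) / len(exon_sizes),
    )


def write_gff3(path: str, annotation: GenomeAnnotation) -> None:
    """Emit gene/mRNA/CDS rows (1-based inclusive, correct CDS phase)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in annotation.contigs.values():
            fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        genes = sorted(
            annotation.genes.values(), key=lambda g: (g.contig_id, g.span[0])
        )
        for g in genes:
            s, e = g.span
            base = (g.contig_id, "poxscreen")
            fh.write(
                "\t".join(
                    [*base, "gene", str(s + 1), str(e), ".", g.strand, ".",
                     f"ID={g.gene_id};biotype={g.biotype}"]
                ) + "\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(
                    [*base, "mRNA", str(s + 1), str(e), ".", g.strand, ".",
                     f"ID={mrna_id};Parent={g.gene_id}"]
                ) + "\n"
            )
            segs = g.segments if g.strand == "+" else list(reversed(g.segments))
            consumed = 0
            rows = []
            for cs, ce in segs:
                phase = (3 - consumed % 3) % 3
                rows.append((cs, ce, phase))
                consumed += ce - cs
            for cs, ce, phase in sorted(rows):
                fh.write(
                    "\t".join(
                        [*base, "CDS", str(cs + 1), str(ce), ".", g.strand,
                         str(phase), f"ID={mrna_id}.cds;Parent={mrna_id}"]
                    ) + "\n"
                )


def write_fasta(path: str, contigs: list[Contig], width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")
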