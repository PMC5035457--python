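"""Variant consequence and regulatory-window annotation.

Each variant called in the mutant strain against the wild-type reference
is classified three ways:

* genomic region — CDS / intron / intergenic, a strict partition with
  precedence CDS > intron > intergenic;
* coding consequence per overlapped gene — synonymous, missense,
  stop_gain, stop_loss, start_loss, frameshift, inframe_indel;
* regulatory windows — membership in the promoter window (default
  1500 bp upstream of the translation start) or terminator window
  (default 200 bp downstream of the stop codon) of any gene, evaluated
  on the gene's coding orientation.

VCF anchor bases on InDels are stripped internally so that every variant
is a pure substitution, insertion or deletion event on the reference.
``apply_variant_oracle`` provides the brute-force mutate/re-splice/
retranslate path used to cross-check the direct consequence caller.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pysam

from .genome import (
    COMPLEMENT,
    Contig,
    GeneModel,
    GenomeAnnotation,
    GenomeError,
    reverse_complement,
    spliced_cds,
    translate,
)

logger = logging.getLogger(__name__)

NONSYN = frozenset({"missense", "stop_gain", "stop_loss", "start_loss", "frameshift"})
SNV_CONSEQUENCES = frozenset(
    {"synonymous", "missense", "stop_gain", "stop_loss", "start_loss"}
)


class VariantError(ValueError):
    """Raised on malformed variants or reference mismatches."""


@dataclass(frozen=True)
class Variant:
    """One ref->alt edit in VCF convention (1-based, anchored InDels)."""

    contig_id: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VariantError(f"{self.contig_id}:{self.pos}: empty ref or alt")
        for s in (self.ref, self.alt):
            if any(ch not in "ACGTN" for ch in s):
                raise VariantError(f"{self.contig_id}:{self.pos}: non-DNA allele {s!r}")

    @property
    def event(self) -> tuple[int, str, str]:
        """Normalized pure event: (start0, deleted_seq, inserted_seq).

        The common prefix shared by ref and alt (the VCF anchor) is
        stripped.  For an insertion ``deleted_seq`` is empty and
        ``start0`` is the insertion point (bases are inserted *before*
        position ``start0``); for a deletion ``inserted_seq`` is empty
        and the deleted reference span is [start0, start0+len(deleted)).
        """
        ref, alt = self.ref, self.alt
        k = 0
        while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
            k += 1
        return self.pos - 1 + k, ref[k:], alt[k:]

    @property
    def vclass(self) -> str:
        _, dele, ins = self.event
        if len(dele) == 1 and len(ins) == 1:
            return "SNV"
        if not dele and ins:
            return "insertion"
        if dele and not ins:
            return "deletion"
        return "other"

    @property
    def affected_span(self) -> tuple[int, int]:
        """Reference interval touched by the event (0-based half-open).

        For an insertion this is the zero-length insertion point.
        """
        start, dele, _ = self.event
        return start, start + len(dele)


@dataclass
class WindowConfig:
    """Regulatory window sizes in bp (upstream of ATG / downstream of stop)."""

    upstream_bp: int = 1500
    downstream_bp: int = 200

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window sizes must be >= 0")


@dataclass
class AnnotatedVariant:
    variant: Variant
    region: str  # CDS | intron | intergenic
    gene_hits: list[tuple[str, str, str]] = field(default_factory=list)
    # (gene_id, consequence, aa_change) -- aa_change empty for indels
    promoter_of: list[str] = field(default_factory=list)
    terminator_of: list[str] = field(default_factory=list)


def read_vcf(path: str, annotation: GenomeAnnotation) -> list[Variant]:
    """Read VCF v4.x, split multi-allelic rows, validate REF vs the genome."""
    variants: list[Variant] = []
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VariantError(f"{path}: cannot parse VCF ({exc})") from exc
    with vcf:
        for rec in vcf:
            if rec.contig not in annotation.contigs:
                raise VariantError(f"{path}: unknown contig {rec.contig!r} at row {rec.pos}")
            seq = annotation.contigs[rec.contig].sequence
            ref = rec.ref.upper()
            genome_ref = seq[rec.pos - 1 : rec.pos - 1 + len(ref)]
            if genome_ref != ref:
                raise VariantError(
                    f"{path}: REF mismatch at {rec.contig}:{rec.pos} "
                    f"(VCF {ref!r}, genome {genome_ref!r})"
                )
            for alt in rec.alts or ():
                variants.append(Variant(rec.contig, rec.pos, ref, alt.upper()))
    return variants


def classify_region(v: Variant, annotation: GenomeAnnotation) -> str:
    """CDS / intron / intergenic with precedence CDS > intron > intergenic."""
    start, end = v.affected_span
    qstart, qend = (start, end) if end > start else (start, start + 1)
    if annotation.cds_overlapping(v.contig_id, qstart, qend):
        return "CDS"
    for gid in annotation.genes_overlapping(v.contig_id, qstart, qend):
        g = annotation.genes[gid]
        for is_, ie_ in g.intron_intervals:
            if qstart < ie_ and qend > is_:
                return "intron"
    return "intergenic"


def _cds_position(g: GeneModel, genome_pos: int) -> int | None:
    """Map a 0-based genome position to a 0-based spliced-CDS index."""
    offset = 0
    if g.strand == "+":
        for s, e in g.segments:
            if s <= genome_pos < e:
                return offset + (genome_pos - s)
            offset += e - s
        return None
    for s, e in reversed(g.segments):
        if s <= genome_pos < e:
            return offset + (e - 1 - genome_pos)
        offset += e - s
    return None


def _codon_aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate(table=1))


def coding_consequence(
    v: Variant, annotation: GenomeAnnotation
) -> list[tuple[str, str, str]]:
    """Consequence per overlapped gene: list of (gene_id, consequence, aa_change).

    SNVs are re-translated at the affected codon; InDels fully inside the
    CDS are frameshift when the length change is not a multiple of 3,
    otherwise inframe_indel; InDels spanning a CDS boundary are called
    frameshift by convention.
    """
    start, end = v.affected_span
    qstart, qend = (start, end) if end > start else (start, start + 1)
    hits: list[tuple[str, str, str]] = []
    for gid in sorted(annotation.cds_overlapping(v.contig_id, qstart, qend)):
        g = annotation.genes[gid]
        if v.vclass == "SNV":
            hits.append((gid, *_snv_consequence(v, g, annotation)))
        else:
            hits.append((gid, _indel_consequence(v, g), ""))
    return hits


def _snv_consequence(
    v: Variant, g: GeneModel, annotation: GenomeAnnotation
) -> tuple[str, str]:
    start, dele, ins = v.event
    cds = spliced_cds(annotation, g.gene_id)
    if g.cds_length % 3 != 0:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3; consequence computed "
            "on the truncated codon frame", g.gene_id, g.cds_length,
        )
    cpos = _cds_position(g, start)
    if cpos is None:  # pragma: no cover - guarded by caller
        return "none", ""
    alt_base = ins if g.strand == "+" else ins.translate(COMPLEMENT)
    codon_i = cpos // 3
    codon_start = codon_i * 3
    old_codon = cds[codon_start : codon_start + 3]
    if len(old_codon) < 3:
        return "none", ""
    within = cpos - codon_start
    new_codon = old_codon[:within] + alt_base + old_codon[within + 1 :]
    old_aa = _codon_aa(old_codon)
    new_aa = _codon_aa(new_codon)
    aa_change = f"{old_aa}{codon_i + 1}{new_aa}"
    if codon_i == 0 and new_codon != "ATG":
        return "start_loss", aa_change
    if old_aa == new_aa:
        return "synonymous", aa_change
    if old_aa == "*" and new_aa != "*":
        return "stop_loss", aa_change
    if new_aa == "*":
        return "stop_gain", aa_change
    return "missense", aa_change


def _indel_consequence(v: Variant, g: GeneModel) -> str:
    start, dele, ins = v.event
    delta = len(ins) - len(dele)
    if delta == 0:
        return "none"  # complex substitution, no length change
    fully_inside = False
    if dele:
        span = (start, start + len(dele))
        fully_inside = any(s <= span[0] and span[1] <= e for s, e in g.segments)
    else:
        # insertion point strictly inside one segment (both flanks coding)
        fully_inside = any(s < start < e for s, e in g.segments)
    if not fully_inside:
        logger.warning(
            "variant %s:%d spans a CDS boundary of %s; called frameshift by convention",
            v.contig_id, v.pos, g.gene_id,
        )
        return "frameshift"
    return "frameshift" if delta % 3 != 0 else "inframe_indel"


# ---------------------------------------------------------------------------
# Brute-force oracle: apply the edit, re-splice, retranslate, compare.
# ---------------------------------------------------------------------------

def apply_variant_oracle(
    annotation: GenomeAnnotation, v: Variant
) -> GenomeAnnotation:
    """Return a new annotation whose genome carries the edit.

    Gene-model coordinates are remapped across the edit so each gene's
    CDS can be re-extracted from the mutated genome.  Intended for tests
    and for generation-time verification of planted variants.
    """
    start, dele, ins = v.event
    contig = annotation.contigs.get(v.contig_id)
    if contig is None:
        raise VariantError(f"unknown contig {v.contig_id!r}")
    seq = contig.sequence
    if start + len(dele) > len(seq) or start < 0:
        raise VariantError(f"edit at {v.contig_id}:{v.pos} out of bounds")
    if seq[start : start + len(dele)] != dele:
        raise VariantError(f"ref mismatch at {v.contig_id}:{v.pos}")
    new_seq = seq[:start] + ins + seq[start + len(dele) :]
    delta = len(ins) - len(dele)

    def remap_start(x: int) -> int:
        if dele:  # deletion of [start, start+len(dele))
            if x <= start:
                return x
            return max(start, x - len(dele)) + len(ins)
        return x + delta if x >= start else x  # insertion before `start`

    def remap_end(x: int) -> int:
        if dele:
            if x <= start:
                return x
            return max(start, x - len(dele)) + len(ins)
        return x + delta if x > start else x

    new_contigs = [
        Contig(c.id, new_seq) if c.id == v.contig_id else c
        for c in annotation.contigs.values()
    ]
    new_genes = []
    for g in annotation.genes.values():
        if g.contig_id != v.contig_id or delta == 0:
            segs = g.segments
        else:
            segs = [(remap_start(s), remap_end(e)) for s, e in g.segments]
        new_genes.append(
            GeneModel(g.gene_id, g.contig_id, g.strand, list(segs), g.biotype)
        )
    # a frameshift edit legitimately breaks the frame of the hit gene, so
    # the length-divisibility warning is expected noise here
    glog = logging.getLogger("poxscreen.genome")
    prev = glog.level
    glog.setLevel(logging.ERROR)
    try:
        return GenomeAnnotation(new_contigs, new_genes)
    finally:
        glog.setLevel(prev)


def oracle_consequence(
    annotation: GenomeAnnotation, v: Variant, gene_id: str
) -> str:
    """Consequence derived purely by comparing wild-type vs mutant proteins."""
    wt_cds = spliced_cds(annotation, gene_id)
    wt_prot = translate(wt_cds)
    mutated = apply_variant_oracle(annotation, v)
    mut_cds = spliced_cds(mutated, gene_id)
    start, dele, ins = v.event
    delta = len(ins) - len(dele)
    if delta != 0:
        return "frameshift" if delta % 3 != 0 else "inframe_indel"
    mut_prot = translate(mut_cds)
    if mut_cds == wt_cds:
        return "none"
    if mut_prot == wt_prot:
        return "synonymous"
    if mut_prot and wt_prot and mut_prot[0] != "M" and wt_prot[0] == "M":
        return "start_loss"
    if len(mut_prot) < len(wt_prot) and mut_prot.endswith("*"):
        return "stop_gain"
    if wt_prot.endswith("*") and not mut_prot.endswith("*"):
        return "stop_loss"
    if len(mut_prot) > len(wt_prot):
        return "stop_loss"
    return "missense"


# ---------------------------------------------------------------------------
# Regulatory windows
# ---------------------------------------------------------------------------

def regulatory_flags(
    v: Variant,
    annotation: GenomeAnnotation,
    w: WindowConfig | None = None,
    exclude_cds_variants: bool = True,
) -> tuple[list[str], list[str]]:
    """Genes whose promoter / terminator window contains the variant.

    Distances are measured on the gene's coding orientation: the promoter
    window covers the ``upstream_bp`` bases strictly 5' of the first base
    of the start codon; the terminator window the ``downstream_bp`` bases
    strictly 3' of the last base of the stop codon.  By default a variant
    that falls inside any CDS is not window-flagged.
    """
    w = w or WindowConfig()
    if exclude_cds_variants and classify_region(v, annotation) == "CDS":
        return [], []
    start, end = v.affected_span
    qstart, qend = (start, end) if end > start else (start, start + 1)
    promoters: list[str] = []
    terminators: list[str] = []
    for g in annotation.genes_on(v.contig_id):
        ts = g.translation_start()
        te = g.stop_end()
        if g.strand == "+":
            prom = (ts - w.upstream_bp, ts)
            term = (te + 1, te + 1 + w.downstream_bp)
        else:
            prom = (ts + 1, ts + 1 + w.upstream_bp)
            term = (te - w.downstream_bp, te)
        if qstart < prom[1] and qend > prom[0]:
            promoters.append(g.gene_id)
        if qstart < term[1] and qend > term[0]:
            terminators.append(g.gene_id)
    return sorted(promoters), sorted(terminators)


def annotate_variant(
    v: Variant,
    annotation: GenomeAnnotation,
    w: WindowConfig | None = None,
    exclude_cds_variants: bool = True,
) -> AnnotatedVariant:
    region = classify_region(v, annotation)
    hits = coding_consequence(v, annotation) if region == "CDS" else []
    prom, term = regulatory_flags(v, annotation, w, exclude_cds_variants)
    return AnnotatedVariant(v, region, hits, prom, term)


def annotate_variants(
    variants: list[Variant],
    annotation: GenomeAnnotation,
    w: WindowConfig | None = None,
    exclude_cds_variants: bool = True,
) -> list[AnnotatedVariant]:
    return [annotate_variant(v, annotation, w, exclude_cds_variants) for v in variants]


@dataclass
class VariantSummary:
    snv_total: int
    snv_cds: int
    snv_intergenic: int
    snv_intron: int
    indel_total: int
    indel_deletions: int
    indel_insertions: int
    indels_in_cds: int
    nonsynonymous_snvs: int
    promoter_window_snvs: int
    terminator_window_snvs: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_variants(annotated: list[AnnotatedVariant]) -> VariantSummary:
    """Category counts in the style of a variant-distribution figure."""
    region_counts: Counter[str] = Counter()
    nonsyn = prom = term = 0
    indel_class: Counter[str] = Counter()
    indels_in_cds = 0
    n_snv = n_indel = 0
    for av in annotated:
        vc = av.variant.vclass
        if vc == "SNV":
            n_snv += 1
            region_counts[av.region] += 1
            if any(cons in NONSYN - {"frameshift"} for _, cons, _ in av.gene_hits):
                nonsyn += 1
            if av.promoter_of:
                prom += 1
            if av.terminator_of:
                term += 1
        else:
            n_indel += 1
            indel_class[vc] += 1
            if av.region == "CDS":
                indels_in_cds += 1
    return VariantSummary(
        snv_total=n_snv,
        snv_cds=region_counts["CDS"],
        snv_intergenic=region_counts["intergenic"],
        snv_intron=region_counts["intron"],
        indel_total=n_indel,
        indel_deletions=indel_class["deletion"],
        indel_insertions=indel_class["insertion"],
        indels_in_cds=indels_in_cds,
        nonsynonymous_snvs=nonsyn,
        promoter_window_snvs=prom,
        terminator_window_snvs=term,
    )


def write_vcf(path: str, contigs: list[Contig], variants: list[Variant]) -> None:
    """Write a minimal site-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poxscreen\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c.id},length={len(c)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        order = {c.id: i for i, c in enumerate(contigs)}
        for v in sorted(variants, key=lambda v: (order[v.contig_id], v.pos)):
            fh.write(f"{v.contig_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


def annotated_to_records(annotated: list[AnnotatedVariant]) -> list[dict]:
    """Tidy one-row-per-variant x gene-hit records for TSV/JSON export."""
    rows = []
    for av in annotated:
        base = dict(
            contig=av.variant.contig_id,
            pos=av.variant.pos,
            ref=av.variant.ref,
            alt=av.variant.alt,
            vclass=av.variant.vclass,
            region=av.region,
            promoter_of=",".join(av.promoter_of),
            terminator_of=",".join(av.terminator_of),
        )
        if av.gene_hits:
            for gid, cons, aa in av.gene_hits:
                rows.append({**base, "gene_id": gid, "consequence": cons, "aa_change": aa})
        else:
            rows.append({**base, "gene_id": "", "consequence": "none", "aa_change": ""})
    return rows
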