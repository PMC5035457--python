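"""Synthetic multi-omics scenarios with a machine-readable truth manifest.

Generates a self-contained fixture bundle emulating the structure of a
wild-type/mutant fungal strain comparison: a multi-contig genome with
strand-mixed multi-exon genes, planted variants of every consequence
class at the observed category mix (105 CDS / 146 intergenic / 23 intron
SNVs; 11 deletions and 1 insertion), negative-binomial read counts for
two strains x three replicates with planted log2 effects, a secretome
ratio table with planted up/down proteins, and a transcription-factor
list.  Planted candidate genes follow the three screening rules (5 with
variant-plus-expression evidence, 3 TFs with CDS variants, 3
differentially expressed TFs) so the end-to-end screen has an exact
expected answer.

Every planted variant is verified at generation time against the
mutate/re-splice/retranslate oracle; the manifest is therefore a hard
guarantee, not a statistical expectation.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import (
    Contig,
    GeneModel,
    GenomeAnnotation,
    gc_percent,
    reverse_complement,
    spliced_cds,
    write_fasta,
    write_gff3,
)
from .expression import CountMatrix
from .variants import (
    Variant,
    WindowConfig,
    classify_region,
    oracle_consequence,
    regulatory_flags,
    write_vcf,
)

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOPS
]
BASES = "ACGT"


class ScenarioError(ValueError):
    pass


@dataclass
class VariantPlan:
    """Planted variant counts per category.

    Defaults mirror the observed category mix of the strain comparison
    the generator emulates: 274 SNVs split 105 CDS / 146 intergenic /
    23 intron, and 12 InDels (11 deletions, 1 insertion, exactly one
    deletion inside a CDS causing a frameshift).
    """

    synonymous: int = 35
    missense: int = 66
    stop_gain: int = 4
    intron: int = 23
    intergenic: int = 83
    promoter: int = 53
    terminator: int = 10
    cds_frameshift_deletion: int = 1
    intergenic_deletion: int = 10
    intergenic_insertion: int = 1

    @property
    def n_snvs(self) -> int:
        return (
            self.synonymous + self.missense + self.stop_gain
            + self.intron + self.intergenic + self.promoter + self.terminator
        )

    @property
    def n_indels(self) -> int:
        return (
            self.cds_frameshift_deletion
            + self.intergenic_deletion
            + self.intergenic_insertion
        )


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic scenario (defaults = study shape)."""

    seed: int = 0
    n_contigs: int = 3
    n_genes: int = 120
    intron_max: int = 3
    minus_strand_frac: float = 0.5
    gap_range: tuple[int, int] = (3300, 4200)
    codon_range: tuple[int, int] = (100, 400)
    intron_len_range: tuple[int, int] = (60, 180)
    variant_plan: VariantPlan = field(default_factory=VariantPlan)
    replicates: int = 3
    depth_mean: float = 2000.0
    depth_sigma: float = 0.3
    dispersion: float = 0.02
    effect_log2fc: float = 2.5
    n_extra_de: int = 12
    secretome_n: int = 60
    secretome_up: int = 30
    secretome_down: int = 20
    secretome_signal_frac: float = 0.45
    n_rule_a: int = 5
    n_rule_b: int = 3
    n_rule_c: int = 3
    n_extra_tfs: int = 6
    window: WindowConfig = field(default_factory=WindowConfig)

    def validate(self) -> None:
        special = (
            self.n_rule_a + self.n_rule_b + self.n_rule_c
            + self.n_extra_tfs + self.n_extra_de
        )
        if special >= self.n_genes:
            raise ScenarioError("more special genes than genes in the scenario")
        if self.secretome_up + self.secretome_down > self.secretome_n:
            raise ScenarioError("secretome plan exceeds table size")
        if self.gap_range[0] < 2 * self.window.upstream_bp + 200:
            raise ScenarioError(
                "intergenic gaps must exceed twice the promoter window so "
                "window flags are unambiguous"
            )
        if self.secretome_n > self.n_genes:
            raise ScenarioError("secretome larger than the gene set")


def default_study_scenario(seed: int = 0) -> ScenarioConfig:
    """The default scenario: study-shaped category mix and candidate funnel."""
    return ScenarioConfig(seed=seed)


@dataclass
class ScenarioBundle:
    out_dir: str
    paths: dict[str, str]
    truth: dict
    annotation: GenomeAnnotation
    variants: list[Variant]
    counts: CountMatrix
    tf_genes: set[str]


def _stage_seed(seed: int, stage: int) -> int:
    """Derive a per-stage 31-bit seed from the scenario seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _codon_aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate(table=1))


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _build_gene(rng: np.random.Generator, cfg: ScenarioConfig):
    """Sense-orientation CDS plus intron layout for one gene."""
    n_codons = int(rng.integers(*cfg.codon_range))
    body = "".join(
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)
    )
    cds = "ATG" + body + STOPS[rng.integers(0, 3)]
    n_introns = int(rng.integers(0, cfg.intron_max + 1))
    cuts: list[int] = []
    if n_introns:
        for _ in range(50):
            cand = sorted(rng.choice(np.arange(20, len(cds) - 20), n_introns, replace=False))
            if all(b - a >= 20 for a, b in zip(cand, cand[1:])):
                cuts = [int(c) for c in cand]
                break
        else:
            cuts = []
    bounds = [0, *cuts, len(cds)]
    exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = [
        "GT" + _random_seq(rng, int(rng.integers(*cfg.intron_len_range)) - 4) + "AG"
        for _ in range(len(exons) - 1)
    ]
    return cds, exons, introns


def _assemble_genome(rng: np.random.Generator, cfg: ScenarioConfig):
    gene_ids = [f"SYN{i + 1:04d}" for i in range(cfg.n_genes)]
    per_contig = int(np.ceil(cfg.n_genes / cfg.n_contigs))
    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    book = {"intron_sizes": [], "exon_sizes": [], "span_sizes": [], "cds": {}}
    gi = 0
    for ci in range(cfg.n_contigs):
        cid = f"ctg{ci + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(per_contig):
            if gi >= cfg.n_genes:
                break
            gid = gene_ids[gi]
            gi += 1
            gap = _random_seq(rng, int(rng.integers(*cfg.gap_range)))
            parts.append(gap)
            pos += len(gap)
            cds, exons, introns = _build_gene(rng, cfg)
            strand = "-" if rng.random() < cfg.minus_strand_frac else "+"
            block_parts, rel_segments = [], []
            rel = 0
            for k, exon in enumerate(exons):
                rel_segments.append((rel, rel + len(exon)))
                block_parts.append(exon)
                rel += len(exon)
                if k < len(introns):
                    block_parts.append(introns[k])
                    rel += len(introns[k])
            block = "".join(block_parts)
            if strand == "-":
                block = reverse_complement(block)
                L = len(block)
                rel_segments = sorted((L - e, L - s) for s, e in rel_segments)
            segments = [(pos + s, pos + e) for s, e in rel_segments]
            parts.append(block)
            pos += len(block)
            genes.append(GeneModel(gid, cid, strand, segments))
            book["cds"][gid] = cds
            book["intron_sizes"].extend(len(iv) for iv in introns)
            book["exon_sizes"].extend(len(ex) for ex in exons)
            book["span_sizes"].append(len(block))
        tail = _random_seq(rng, int(rng.integers(*cfg.gap_range)))
        parts.append(tail)
        contigs.append(Contig(cid, "".join(parts)))
    annotation = GenomeAnnotation(contigs, genes)
    for g in genes:  # construction sanity: splicing must return the planted CDS
        assert spliced_cds(annotation, g.gene_id) == book["cds"][g.gene_id]
    return annotation, book


def _genome_bookkeeping(annotation: GenomeAnnotation, book: dict) -> dict:
    genome = "".join(c.sequence for c in annotation.contigs.values())
    coding = "".join(book["cds"].values())
    n = len(book["cds"])
    n_introns = len(book["intron_sizes"])
    return {
        "genome_size_bp": len(genome),
        "gc_genome_pct": gc_percent(genome),
        "gene_count": n,
        "gc_coding_pct": gc_percent(coding),
        "mean_gene_length_bp": float(np.mean(book["span_sizes"])),
        "mean_introns_per_gene": n_introns / n,
        "mean_intron_size_bp": float(np.mean(book["intron_sizes"])) if n_introns else float("nan"),
        "mean_exon_size_bp": float(np.mean(book["exon_sizes"])),
    }


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

class _Planter:
    def __init__(self, annotation: GenomeAnnotation, cfg: ScenarioConfig, rng):
        self.ann = annotation
        self.cfg = cfg
        self.rng = rng
        self.used: dict[str, set[int]] = {c: set() for c in annotation.contigs}
        self.used_codons: dict[str, set[int]] = {}
        self.records: list[dict] = []
        self.variants: list[Variant] = []
        self._tx_positions: dict[str, list[int]] = {}
        self._forbidden = self._forbidden_intervals()

    def _forbidden_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Per contig: gene spans padded by both regulatory windows."""
        w = self.cfg.window
        pad = max(w.upstream_bp, w.downstream_bp) + 10
        out: dict[str, list[tuple[int, int]]] = {c: [] for c in self.ann.contigs}
        for g in self.ann.genes.values():
            s, e = g.span
            out[g.contig_id].append((s - pad, e + pad))
        return out

    def _in_forbidden(self, contig: str, start: int, end: int) -> bool:
        return any(start < fe and end > fs for fs, fe in self._forbidden[contig])

    def _claim(self, contig: str, start: int, end: int) -> bool:
        span = set(range(start, max(end, start + 1)))
        if span & self.used[contig]:
            return False
        self.used[contig] |= span
        return True

    def _transcript_positions(self, g: GeneModel) -> list[int]:
        if g.gene_id not in self._tx_positions:
            if g.strand == "+":
                pos = [p for s, e in g.segments for p in range(s, e)]
            else:
                pos = [p for s, e in reversed(g.segments) for p in range(e - 1, s - 1, -1)]
            self._tx_positions[g.gene_id] = pos
        return self._tx_positions[g.gene_id]

    def _record(self, v: Variant, category: str, gene_id: str, consequence: str):
        region = classify_region(v, self.ann)
        prom, term = regulatory_flags(v, self.ann, self.cfg.window)
        self.variants.append(v)
        self.records.append(
            dict(
                contig=v.contig_id,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                category=category,
                region=region,
                gene_id=gene_id,
                consequence=consequence,
                promoter_of=prom,
                terminator_of=term,
            )
        )

    def plant_cds_snv(self, gene_id: str, intended: str) -> None:
        g = self.ann.genes[gene_id]
        cds = spliced_cds(self.ann, gene_id)
        tx = self._transcript_positions(g)
        used_codons = self.used_codons.setdefault(gene_id, set())
        n_codons = len(cds) // 3
        for _ in range(500):
            codon_i = int(self.rng.integers(1, n_codons - 1))
            if codon_i in used_codons:
                continue
            within = int(self.rng.integers(0, 3))
            cpos = codon_i * 3 + within
            old_codon = cds[codon_i * 3 : codon_i * 3 + 3]
            old_aa = _codon_aa(old_codon)
            for alt in self.rng.permutation(list(BASES)):
                if alt == cds[cpos]:
                    continue
                new_codon = old_codon[:within] + alt + old_codon[within + 1 :]
                new_aa = _codon_aa(new_codon)
                if intended == "synonymous" and not (new_aa == old_aa and old_aa != "*"):
                    continue
                if intended == "missense" and not (
                    new_aa != old_aa and "*" not in (new_aa, old_aa)
                ):
                    continue
                if intended == "stop_gain" and not (old_aa != "*" and new_aa == "*"):
                    continue
                p = tx[cpos]
                contig_seq = self.ann.contigs[g.contig_id].sequence
                ref_base = contig_seq[p]
                alt_base = alt if g.strand == "+" else alt.translate(
                    str.maketrans("ACGT", "TGCA")
                )
                v = Variant(g.contig_id, p + 1, ref_base, alt_base)
                if not self._claim(g.contig_id, p, p + 1):
                    break
                got = oracle_consequence(self.ann, v, gene_id)
                if got != intended:  # pragma: no cover - hard guarantee
                    raise ScenarioError(
                        f"planted {intended} at {g.contig_id}:{p + 1} but oracle says {got}"
                    )
                used_codons.add(codon_i)
                self._record(v, intended, gene_id, intended)
                return
        raise ScenarioError(f"could not plant {intended} SNV in {gene_id}")

    def plant_intron_snv(self, gene_id: str) -> None:
        g = self.ann.genes[gene_id]
        introns = g.intron_intervals
        if not introns:
            raise ScenarioError(f"gene {gene_id} has no introns")
        seq = self.ann.contigs[g.contig_id].sequence
        for _ in range(200):
            s, e = introns[int(self.rng.integers(0, len(introns)))]
            p = int(self.rng.integers(s + 3, e - 3))  # keep splice dinucleotides
            if not self._claim(g.contig_id, p, p + 1):
                continue
            ref = seq[p]
            alt = str(self.rng.choice([b for b in BASES if b != ref]))
            v = Variant(g.contig_id, p + 1, ref, alt)
            assert classify_region(v, self.ann) == "intron"
            self._record(v, "intron", gene_id, "")
            return
        raise ScenarioError(f"could not plant intron SNV in {gene_id}")

    def plant_window_snv(self, gene_id: str, which: str) -> None:
        g = self.ann.genes[gene_id]
        w = self.cfg.window
        seq = self.ann.contigs[g.contig_id].sequence
        for _ in range(200):
            if which == "promoter":
                offset = int(self.rng.integers(50, w.upstream_bp - 50))
                ts = g.translation_start()
                p = ts - offset if g.strand == "+" else ts + offset
            else:
                offset = int(self.rng.integers(10, w.downstream_bp - 10))
                te = g.stop_end()
                p = te + offset if g.strand == "+" else te - offset
            if p < 0 or p >= len(seq):
                continue
            if not self._claim(g.contig_id, p, p + 1):
                continue
            ref = seq[p]
            alt = str(self.rng.choice([b for b in BASES if b != ref]))
            v = Variant(g.contig_id, p + 1, ref, alt)
            prom, term = regulatory_flags(v, self.ann, w)
            expect = ([gene_id], []) if which == "promoter" else ([], [gene_id])
            if (prom, term) != expect or classify_region(v, self.ann) != "intergenic":
                raise ScenarioError(
                    f"window variant for {gene_id} at {g.contig_id}:{p + 1} is ambiguous"
                )
            self._record(v, which, gene_id, "")
            return
        raise ScenarioError(f"could not plant {which} SNV for {gene_id}")

    def _far_intergenic_pos(self, margin: int = 6) -> tuple[str, int]:
        contigs = sorted(self.ann.contigs)
        for _ in range(2000):
            cid = contigs[int(self.rng.integers(0, len(contigs)))]
            L = len(self.ann.contigs[cid])
            p = int(self.rng.integers(margin, L - margin))
            if self._in_forbidden(cid, p - margin, p + margin):
                continue
            return cid, p
        raise ScenarioError("no far-intergenic position found")

    def plant_intergenic_snv(self) -> None:
        cid, p = self._far_intergenic_pos()
        if not self._claim(cid, p, p + 1):
            return self.plant_intergenic_snv()
        seq = self.ann.contigs[cid].sequence
        ref = seq[p]
        alt = str(self.rng.choice([b for b in BASES if b != ref]))
        v = Variant(cid, p + 1, ref, alt)
        assert classify_region(v, self.ann) == "intergenic"
        prom, term = regulatory_flags(v, self.ann, self.cfg.window)
        assert not prom and not term
        self._record(v, "intergenic", "", "")

    def plant_intergenic_indel(self, kind: str) -> None:
        cid, p = self._far_intergenic_pos(margin=10)
        seq = self.ann.contigs[cid].sequence
        if kind == "deletion":
            L = int(self.rng.integers(1, 6))
            if not self._claim(cid, p - 1, p + L):
                return self.plant_intergenic_indel(kind)
            v = Variant(cid, p, seq[p - 1 : p + L], seq[p - 1])
        else:
            ins = _random_seq(self.rng, int(self.rng.integers(1, 5)))
            if not self._claim(cid, p - 1, p + 1):
                return self.plant_intergenic_indel(kind)
            v = Variant(cid, p, seq[p - 1], seq[p - 1] + ins)
        assert classify_region(v, self.ann) == "intergenic"
        self._record(v, f"intergenic_{kind}", "", "")

    def plant_cds_frameshift_deletion(self, gene_id: str) -> None:
        g = self.ann.genes[gene_id]
        seq = self.ann.contigs[g.contig_id].sequence
        for _ in range(200):
            s, e = g.segments[int(self.rng.integers(0, len(g.segments)))]
            L = int(self.rng.choice([1, 2]))
            if e - s < L + 10:
                continue
            p = int(self.rng.integers(s + 4, e - L - 4))
            if not self._claim(g.contig_id, p - 1, p + L):
                continue
            v = Variant(g.contig_id, p, seq[p - 1 : p + L], seq[p - 1])
            got = oracle_consequence(self.ann, v, gene_id)
            if got != "frameshift":  # pragma: no cover
                raise ScenarioError(f"planted frameshift but oracle says {got}")
            self._record(v, "cds_frameshift_deletion", gene_id, "frameshift")
            return
        raise ScenarioError(f"could not plant frameshift deletion in {gene_id}")


# ---------------------------------------------------------------------------
# counts / secretome
# ---------------------------------------------------------------------------

def negative_binomial_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + a*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def simulate_count_matrix(
    gene_ids: list[str],
    log2fc: dict[str, float],
    lengths: pd.Series | None,
    depth_mean: float,
    depth_sigma: float,
    dispersion: float,
    replicates: int,
    seed: int,
) -> CountMatrix:
    """Two-strain NB count matrix with planted per-gene log2 effects."""
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = pd.Series(
            rng.integers(300, 3000, len(gene_ids)).astype(float), index=gene_ids
        )
    base = rng.lognormal(
        np.log(depth_mean) - depth_sigma**2 / 2, depth_sigma, len(gene_ids)
    )
    samples = [f"WT_r{i + 1}" for i in range(replicates)] + [
        f"MUT_r{i + 1}" for i in range(replicates)
    ]
    data = np.zeros((len(gene_ids), 2 * replicates), dtype=int)
    for gi, gid in enumerate(gene_ids):
        # effects applied symmetrically around the base mean so that the
        # two libraries stay comparable in total mass
        fc = log2fc.get(gid, 0.0)
        mu1 = base[gi] * 2.0 ** (-fc / 2)
        mu2 = base[gi] * 2.0 ** (fc / 2)
        data[gi, :replicates] = negative_binomial_counts(rng, mu1, dispersion, replicates)
        data[gi, replicates:] = negative_binomial_counts(rng, mu2, dispersion, replicates)
    counts = pd.DataFrame(data, index=gene_ids, columns=samples)
    strain_of = {s: ("WT" if s.startswith("WT") else "MUT") for s in samples}
    return CountMatrix(counts, lengths.reindex(gene_ids), strain_of)


# ---------------------------------------------------------------------------
# scenario driver
# ---------------------------------------------------------------------------

def generate_scenario(cfg: ScenarioConfig, out_dir: str) -> ScenarioBundle:
    """Generate and write the full fixture bundle; returns paths and truth."""
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    rng_genome = np.random.default_rng(_stage_seed(cfg.seed, 0))
    rng_var = np.random.default_rng(_stage_seed(cfg.seed, 1))
    seed_counts = _stage_seed(cfg.seed, 2)
    rng_secr = np.random.default_rng(_stage_seed(cfg.seed, 3))

    annotation, book = _assemble_genome(rng_genome, cfg)
    gene_ids = sorted(annotation.genes)

    # --- gene roles -------------------------------------------------------
    perm = [gene_ids[i] for i in rng_var.permutation(len(gene_ids))]
    it = iter(perm)
    rule_a = [next(it) for _ in range(cfg.n_rule_a)]
    rule_b = [next(it) for _ in range(cfg.n_rule_b)]
    rule_c = [next(it) for _ in range(cfg.n_rule_c)]
    extra_tfs = [next(it) for _ in range(cfg.n_extra_tfs)]
    extra_de = [next(it) for _ in range(cfg.n_extra_de)]
    null_pool = list(it)
    tf_genes = sorted(rule_b + rule_c + extra_tfs)

    # --- variants ---------------------------------------------------------
    plan = cfg.variant_plan
    planter = _Planter(annotation, cfg, rng_var)

    # rule-A evidence: 2 missense, 2 promoter, 1 terminator (cycled for
    # non-default counts), drawn from the per-category budgets
    a_kinds = list(
        itertools.islice(
            itertools.cycle(["missense", "promoter", "promoter", "missense", "terminator"]),
            cfg.n_rule_a,
        )
    )
    budget = dict(
        synonymous=plan.synonymous,
        missense=plan.missense,
        stop_gain=plan.stop_gain,
        intron=plan.intron,
        intergenic=plan.intergenic,
        promoter=plan.promoter,
        terminator=plan.terminator,
    )
    for gid, kind in zip(rule_a, a_kinds):
        if budget.get(kind, 0) <= 0:
            kind = "missense"
        budget[kind] -= 1
        if kind == "missense":
            planter.plant_cds_snv(gid, "missense")
        else:
            planter.plant_window_snv(gid, kind)
    for gid in rule_b:
        budget["missense"] -= 1
        planter.plant_cds_snv(gid, "missense")
    if min(budget.values()) < 0:
        raise ScenarioError("variant plan too small for the candidate plan")

    cds_hosts = list(null_pool)  # genes allowed to carry random protein-altering variants
    syn_hosts = list(null_pool) + list(extra_tfs)
    intron_hosts = [g for g in null_pool if annotation.genes[g].n_introns > 0]
    window_hosts = list(null_pool)
    if not intron_hosts and budget["intron"]:
        raise ScenarioError("no intron-bearing genes available for intron SNVs")

    def pick(pool: list[str]) -> str:
        return pool[int(rng_var.integers(0, len(pool)))]

    for _ in range(budget["synonymous"]):
        planter.plant_cds_snv(pick(syn_hosts), "synonymous")
    for _ in range(budget["missense"]):
        planter.plant_cds_snv(pick(cds_hosts), "missense")
    for _ in range(budget["stop_gain"]):
        planter.plant_cds_snv(pick(cds_hosts), "stop_gain")
    for _ in range(budget["intron"]):
        planter.plant_intron_snv(pick(intron_hosts))
    for _ in range(budget["promoter"]):
        planter.plant_window_snv(pick(window_hosts), "promoter")
    for _ in range(budget["terminator"]):
        planter.plant_window_snv(pick(window_hosts), "terminator")
    for _ in range(budget["intergenic"]):
        planter.plant_intergenic_snv()
    for _ in range(plan.cds_frameshift_deletion):
        planter.plant_cds_frameshift_deletion(pick(cds_hosts))
    for _ in range(plan.intergenic_deletion):
        planter.plant_intergenic_indel("deletion")
    for _ in range(plan.intergenic_insertion):
        planter.plant_intergenic_indel("insertion")

    # --- expression -------------------------------------------------------
    fc = cfg.effect_log2fc
    log2fc: dict[str, float] = {}
    for i, gid in enumerate(rule_a):
        log2fc[gid] = fc if i % 5 < 3 else -fc
    for i, gid in enumerate(rule_c):
        log2fc[gid] = fc if i % 3 == 0 else -fc
    for i, gid in enumerate(extra_de):
        mag = float(rng_var.uniform(1.5, 4.0))
        log2fc[gid] = mag if i % 2 == 0 else -mag
    lengths = pd.Series(
        {gid: float(annotation.genes[gid].cds_length) for gid in gene_ids}
    )
    counts = simulate_count_matrix(
        gene_ids, log2fc, lengths, cfg.depth_mean, cfg.depth_sigma,
        cfg.dispersion, cfg.replicates, seed_counts,
    )

    # --- secretome --------------------------------------------------------
    n_neutral = cfg.secretome_n - cfg.secretome_up - cfg.secretome_down
    de_up = [g for g in extra_de if log2fc[g] > 0]
    de_down = [g for g in extra_de if log2fc[g] < 0]
    pool = list(null_pool)
    rng_secr.shuffle(pool)
    it2 = iter(pool)
    up_ids = de_up + [next(it2) for _ in range(cfg.secretome_up - len(de_up))]
    down_ids = de_down + [next(it2) for _ in range(cfg.secretome_down - len(de_down))]
    neutral_ids = [next(it2) for _ in range(n_neutral)]
    secr_rows = []
    for pid in up_ids:
        secr_rows.append((pid, float(rng_secr.uniform(2.2, 8.0)), "up"))
    for pid in down_ids:
        secr_rows.append((pid, float(rng_secr.uniform(0.12, 0.45)), "down"))
    for pid in neutral_ids:
        secr_rows.append((pid, float(rng_secr.uniform(0.85, 1.18)), "none"))
    secr_rows.sort()
    n_signal = int(round(cfg.secretome_signal_frac * cfg.secretome_n))
    signal_idx = set(rng_secr.choice(len(secr_rows), n_signal, replace=False).tolist())
    secretome = pd.DataFrame(
        [
            dict(
                protein_id=pid,
                ratio=round(ratio, 4),
                has_signal=i in signal_idx,
                tag="planted_" + direction,
            )
            for i, (pid, ratio, direction) in enumerate(secr_rows)
        ]
    ).set_index("protein_id")

    # --- truth manifest ---------------------------------------------------
    truth = {
        "seed": cfg.seed,
        "genome": _genome_bookkeeping(annotation, book),
        "variant_plan": dataclasses.asdict(plan),
        "variants": planter.records,
        "genes": {
            gid: {
                "log2fc": log2fc.get(gid, 0.0),
                "is_de": abs(log2fc.get(gid, 0.0)) >= 1.0,
                "tf": gid in set(tf_genes),
            }
            for gid in gene_ids
        },
        "secretome": {
            pid: {"direction": d, "has_signal": bool(i in signal_idx)}
            for i, (pid, _, d) in enumerate(secr_rows)
        },
        "candidates": {"A": sorted(rule_a), "B": sorted(rule_b), "C": sorted(rule_c)},
        "tf_genes": tf_genes,
    }

    # --- write the bundle -------------------------------------------------
    paths = {
        "fasta": os.path.join(out_dir, "genome.fasta"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "counts": os.path.join(out_dir, "counts.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "lengths": os.path.join(out_dir, "gene_lengths.tsv"),
        "secretome": os.path.join(out_dir, "secretome.tsv"),
        "tf_genes": os.path.join(out_dir, "tf_genes.txt"),
        "truth": os.path.join(out_dir, "truth.json"),
        "scenario": os.path.join(out_dir, "scenario.yaml"),
    }
    write_fasta(paths["fasta"], list(annotation.contigs.values()))
    write_gff3(paths["gff3"], annotation)
    write_vcf(paths["vcf"], list(annotation.contigs.values()), planter.variants)
    counts.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    pd.Series(counts.strain_of, name="strain").rename_axis("sample").to_csv(
        paths["samples"], sep="\t"
    )
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(paths["lengths"], sep="\t")
    secretome.to_csv(paths["secretome"], sep="\t")
    with open(paths["tf_genes"], "w") as fh:
        fh.write("\n".join(tf_genes) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["window"] = dataclasses.asdict(cfg.window)
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return ScenarioBundle(
        out_dir=out_dir,
        paths=paths,
        truth=truth,
        annotation=annotation,
        variants=planter.variants,
        counts=counts,
        tf_genes=set(tf_genes),
    )
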