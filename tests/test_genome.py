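"""Genome reading, splicing, translation and feature statistics."""

import math

import numpy as np
import pytest

from poxscreen.genome import (
    Contig,
    GeneModel,
    GenomeAnnotation,
    GenomeError,
    genome_stats,
    read_fasta,
    read_gff3,
    reverse_complement,
    spliced_cds,
    translate,
    write_fasta,
    write_gff3,
)


class TestReadFasta:
    def test_identity_and_case_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\nacGT\n>c2\nNNNA\n")
        contigs = read_fasta(str(p))
        assert [(c.id, c.sequence) for c in contigs] == [("c1", "ACGT"), ("c2", "NNNA")]

    @pytest.mark.parametrize(
        "content",
        [">c1\nACGT\n>c1\nTTTT\n", "", ">c1\nACXT\n", ">c1\nACGU\n"],
        ids=["duplicate-id", "empty", "non-iupac", "rna-u"],
    )
    def test_rejects_malformed(self, tmp_path, content):
        p = tmp_path / "bad.fasta"
        p.write_text(content)
        with pytest.raises(GenomeError):
            read_fasta(str(p))


class TestReadGff3:
    def _write(self, tmp_path, body):
        fa = tmp_path / "g.fasta"
        fa.write_text(">c1\n" + "ACGT" * 25 + "\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n" + body)
        return str(gff), read_fasta(str(fa))

    def test_two_segment_gene(self, tmp_path):
        body = (
            "c1\t.\tgene\t1\t28\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t28\t.\t+\t.\tID=m1;Parent=g1\n"
            "c1\t.\tCDS\t1\t9\t.\t+\t0\tID=m1.c1;Parent=m1\n"
            "c1\t.\tCDS\t20\t28\t.\t+\t0\tID=m1.c2;Parent=m1\n"
        )
        gff, contigs = self._write(tmp_path, body)
        ann = read_gff3(gff, contigs)
        g = ann.genes["g1"]
        assert g.segments == [(0, 9), (19, 28)]
        assert g.n_introns == 1

    def test_cds_beyond_contig_is_error(self, tmp_path):
        body = (
            "c1\t.\tgene\t1\t200\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t200\t.\t+\t.\tID=m1;Parent=g1\n"
            "c1\t.\tCDS\t1\t200\t.\t+\t0\tID=m1.c1;Parent=m1\n"
        )
        gff, contigs = self._write(tmp_path, body)
        with pytest.raises(GenomeError, match="outside contig bounds"):
            read_gff3(gff, contigs)

    def test_first_isoform_retained(self, tmp_path, caplog):
        body = (
            "c1\t.\tgene\t1\t28\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t28\t.\t+\t.\tID=m1;Parent=g1\n"
            "c1\t.\tCDS\t1\t9\t.\t+\t0\tID=m1.c;Parent=m1\n"
            "c1\t.\tmRNA\t1\t28\t.\t+\t.\tID=m2;Parent=g1\n"
            "c1\t.\tCDS\t1\t28\t.\t+\t0\tID=m2.c;Parent=m2\n"
        )
        gff, contigs = self._write(tmp_path, body)
        with caplog.at_level("WARNING", logger="poxscreen.genome"):
            ann = read_gff3(gff, contigs)
        assert ann.genes["g1"].segments == [(0, 9)]
        assert any("isoform" in r.message for r in caplog.records)


class TestSplicedCds:
    def test_plus_strand_concatenation(self, toy_annotation):
        assert spliced_cds(toy_annotation, "gplus") == "ATGAAATTTGGGCCCTAA"

    def test_minus_strand_reverse_complement(self, toy_annotation):
        assert spliced_cds(toy_annotation, "gminus") == "ATGGTTTGA"

    def test_three_exon_minus_strand_hand_spliced(self):
        # sense CDS ATG GTT CCC TGA split into 3 exons with 2 introns
        sense_exons = ["ATGG", "TTCC", "CTGA"]
        introns = ["GTCAG", "GTTAG"]
        block = sense_exons[0] + introns[0] + sense_exons[1] + introns[1] + sense_exons[2]
        seq = "AAAA" + reverse_complement(block) + "TTTT"
        L = len(block)
        rel = []
        pos = 0
        for ex, iv in zip(sense_exons, introns + [""]):
            rel.append((pos, pos + len(ex)))
            pos += len(ex) + len(iv)
        segments = sorted((4 + L - e, 4 + L - s) for s, e in rel)
        ann = GenomeAnnotation(
            [Contig("c", seq)], [GeneModel("g", "c", "-", segments)]
        )
        assert spliced_cds(ann, "g") == "ATGGTTCCCTGA"

    def test_unknown_gene_is_error(self, toy_annotation):
        with pytest.raises(GenomeError):
            spliced_cds(toy_annotation, "nope")

    def test_minus_equals_revcomp_of_plus_reading(self, scenario):
        ann = scenario.annotation
        for g in list(ann.genes.values())[:20]:
            plus = "".join(
                ann.contigs[g.contig_id].sequence[s:e] for s, e in g.segments
            )
            got = spliced_cds(ann, g.gene_id)
            assert got == (plus if g.strand == "+" else reverse_complement(plus))


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            ("ATGTGA", "M*"),
            ("ATGAAATAAAAA", "MK*"),
            ("ATGAAA", "MK"),
        ],
    )
    def test_basic(self, cds, expected):
        assert translate(cds) == expected

    def test_ambiguous_codon_is_x(self):
        assert translate("ATGANAAAA")[1] == "X"

    def test_too_short_is_error(self):
        with pytest.raises(GenomeError):
            translate("AT")

    def test_planted_genes_start_with_m(self, scenario):
        for gid in list(scenario.annotation.genes)[:30]:
            prot = translate(spliced_cds(scenario.annotation, gid))
            assert prot.startswith("M") and prot.endswith("*")


class TestGenomeStats:
    def test_contig_only_genome(self):
        ann = GenomeAnnotation([Contig("c1", "ATGC")], [])
        st = genome_stats(ann)
        assert st.genome_size_bp == 4
        assert st.gc_genome_pct == pytest.approx(50.0)
        assert st.gene_count == 0
        assert math.isnan(st.mean_gene_length_bp)

    def test_hand_counted_intron_exon_sizes(self):
        seq = "A" * 40
        ann = GenomeAnnotation(
            [Contig("c1", seq)], [GeneModel("g", "c1", "+", [(0, 9), (19, 28)])]
        )
        st = genome_stats(ann)
        assert st.gene_count == 1
        assert st.mean_introns_per_gene == 1.0
        assert st.mean_intron_size_bp == 10.0
        assert st.mean_exon_size_bp == 9.0
        assert st.mean_gene_length_bp == 28.0

    def test_gc_excludes_n(self):
        ann = GenomeAnnotation([Contig("c1", "GCNNAT")], [])
        assert genome_stats(ann).gc_genome_pct == pytest.approx(50.0)

    def test_matches_generator_bookkeeping(self, scenario):
        st = genome_stats(scenario.annotation)
        for key, expected in scenario.truth["genome"].items():
            assert getattr(st, key) == pytest.approx(expected), key

    def test_invariant_under_gene_and_contig_permutation(self, scenario):
        ann = scenario.annotation
        shuffled = GenomeAnnotation(
            list(reversed(list(ann.contigs.values()))),
            list(reversed(list(ann.genes.values()))),
        )
        assert genome_stats(shuffled).to_dict() == pytest.approx(
            genome_stats(ann).to_dict()
        )


class TestIntervalIndex:
    def test_matches_linear_scan(self, scenario):
        ann = scenario.annotation
        rng = np.random.default_rng(42)
        genes = list(ann.genes.values())
        for _ in range(1000):
            cid = list(ann.contigs)[rng.integers(0, len(ann.contigs))]
            p = int(rng.integers(0, len(ann.contigs[cid])))
            got_span = ann.genes_overlapping(cid, p, p + 1)
            want_span = {
                g.gene_id
                for g in genes
                if g.contig_id == cid and g.span[0] <= p < g.span[1]
            }
            assert got_span == want_span
            got_cds = ann.cds_overlapping(cid, p, p + 1)
            want_cds = {
                g.gene_id
                for g in genes
                if g.contig_id == cid and any(s <= p < e for s, e in g.segments)
            }
            assert got_cds == want_cds


class TestRoundTrip:
    def test_fasta_gff3_round_trip_preserves_models(self, scenario, tmp_path):
        ann = scenario.annotation
        fa = tmp_path / "g.fasta"
        gff = tmp_path / "g.gff3"
        write_fasta(str(fa), list(ann.contigs.values()))
        write_gff3(str(gff), ann)
        back = read_gff3(str(gff), read_fasta(str(fa)))
        assert set(back.genes) == set(ann.genes)
        for gid in list(ann.genes)[:15]:
            assert back.genes[gid].segments == ann.genes[gid].segments
            assert spliced_cds(back, gid) == spliced_cds(ann, gid)
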