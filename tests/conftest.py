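"""Shared fixtures: hand-built micro-genomes and one generated scenario."""

import logging

import pytest

from poxscreen.genome import Contig, GeneModel, GenomeAnnotation
from poxscreen.simulate import default_study_scenario, generate_scenario

logging.getLogger("poxscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """One default study-shaped scenario shared across the session."""
    out = tmp_path_factory.mktemp("scenario")
    return generate_scenario(default_study_scenario(seed=0), str(out))


def make_toy_annotation() -> GenomeAnnotation:
    """Two genes on one contig: a 2-exon plus-strand gene and a minus-strand gene.

    gplus: CDS segments [10,19) + [25,34), spliced = ATGAAATTTGGGCCCTAA
    gminus: single segment [60,69) on '-', sense CDS = ATGGTTTGA
    """
    exon1 = "ATGAAATTT"  # 9 bp
    intron = "GTAAAG"  # 6 bp, [19,25)
    exon2 = "GGGCCCTAA"  # 9 bp
    minus_sense = "ATGGTTTGA"
    seq = (
        "CCCCCCCCCC"  # [0,10)
        + exon1
        + intron
        + exon2  # ends at 34
        + "ACGTACGTACGTACGTACGTACGTAC"  # [34,60)
        + "TCAAACCAT"  # revcomp of ATGGTTTGA, [60,69)
        + "GGGGGGGGGGG"  # tail
    )
    contig = Contig("c1", seq)
    gplus = GeneModel("gplus", "c1", "+", [(10, 19), (25, 34)])
    gminus = GeneModel("gminus", "c1", "-", [(60, 69)])
    return GenomeAnnotation([contig], [gplus, gminus])


@pytest.fixture
def toy_annotation():
    return make_toy_annotation()
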