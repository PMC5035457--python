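#!/usr/bin/env python
"""Classify every mutant-vs-wild-type variant by region, consequence and
regulatory window, and tabulate the category distribution.

Writes results/variants_annotated.tsv (one row per variant x gene hit)
and results/variant_summary.json.
"""

import json

import pandas as pd

from poxscreen.genome import read_fasta, read_gff3
from poxscreen.variants import (
    annotate_variants,
    annotated_to_records,
    read_vcf,
    summarize_variants,
)

if __name__ == "__main__":
    contigs = read_fasta("scratch/scenario/genome.fasta")
    ann = read_gff3("scratch/scenario/genes.gff3", contigs)
    variants = read_vcf("scratch/scenario/variants.vcf", ann)
    annotated = annotate_variants(variants, ann)
    pd.DataFrame(annotated_to_records(annotated)).to_csv(
        "results/variants_annotated.tsv", sep="\t", index=False
    )
    s = summarize_variants(annotated)
    with open("results/variant_summary.json", "w") as fh:
        json.dump(s.to_dict(), fh, indent=1, sort_keys=True)
    print(f"{s.snv_total} SNVs: {s.snv_cds} in CDS, {s.snv_intergenic} intergenic, "
          f"{s.snv_intron} in introns")
    print(f"{s.nonsynonymous_snvs} non-synonymous SNVs; "
          f"{s.promoter_window_snvs} in promoter windows, "
          f"{s.terminator_window_snvs} in terminator windows")
    print(f"{s.indel_total} InDels ({s.indel_deletions} deletions, "
          f"{s.indel_insertions} insertions; {s.indels_in_cds} in CDS)")
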