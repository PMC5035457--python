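#!/usr/bin/env python
"""Summarize the scenario genome the way draft fungal genomes are reported.

Reads scratch/scenario/ back through the standard-format readers and
writes the feature table (size, GC, gene count, intron/exon geometry)
to results/genome_stats.json and .tsv.
"""

import json

import pandas as pd

from poxscreen.genome import genome_stats, read_fasta, read_gff3

if __name__ == "__main__":
    contigs = read_fasta("scratch/scenario/genome.fasta")
    ann = read_gff3("scratch/scenario/genes.gff3", contigs)
    stats = genome_stats(ann)
    with open("results/genome_stats.json", "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1, sort_keys=True)
    pd.Series(stats.to_dict(), name="value").rename_axis("feature").to_csv(
        "results/genome_stats.tsv", sep="\t"
    )
    print("genome feature summary (results/genome_stats.json):")
    for k, v in stats.to_dict().items():
        print(f"  {k}: {v:.2f}" if isinstance(v, float) else f"  {k}: {v}")
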