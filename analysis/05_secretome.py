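#!/usr/bin/env python
"""Differential secretion between the strains and agreement with the
transcript-level calls.

Writes results/secretome_summary.json and results/secretome_concordance.tsv.
"""

import json

import pandas as pd

from poxscreen.secretome import (
    SecretomeTable,
    differential_secretion,
    omics_concordance,
    signal_fraction,
)

if __name__ == "__main__":
    table = SecretomeTable.from_file("scratch/scenario/secretome.tsv")
    up, down = differential_secretion(table)
    frac = signal_fraction(table)
    de = pd.read_csv("results/de_results.tsv", sep="\t", index_col=0)
    conc = omics_concordance(up, down, de)
    conc.to_csv("results/secretome_concordance.tsv", sep="\t")
    with open("results/secretome_summary.json", "w") as fh:
        json.dump({"n_proteins": len(table.table), "fraction_lacking_signal": frac,
                   "up": sorted(up), "down": sorted(down)}, fh, indent=1, sort_keys=True)
    print(f"{len(table.table)} proteins quantified; {len(up)} up, {len(down)} down")
    print(f"{100 * frac:.0f}% lack a predicted secretion signal")
    print("concordance with transcripts:")
    print(conc["label"].value_counts().to_string())
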