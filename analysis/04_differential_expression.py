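#!/usr/bin/env python
"""Call differential expression between the two strains with the (M, D)
noise-cloud statistic at |M| >= 1 and probability >= 0.8.

Writes per-gene results to results/de_results.tsv and prints the DE
count with its split by direction.
"""

from poxscreen.expression import CountMatrix, DEConfig, de_call

SEED = 2016

if __name__ == "__main__":
    cm = CountMatrix.from_files(
        "scratch/scenario/counts.tsv",
        "scratch/scenario/samples.tsv",
        "scratch/scenario/gene_lengths.tsv",
    )
    res = de_call(cm, DEConfig(seed=SEED))
    res.rename_axis("gene_id").to_csv("results/de_results.tsv", sep="\t",
                                      float_format="%.6g")
    de = res[res["is_de"]]
    print(f"{len(de)} of {len(res)} genes differentially expressed "
          f"({(de['M'] > 0).sum()} up, {(de['M'] < 0).sum()} down in the mutant)")
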