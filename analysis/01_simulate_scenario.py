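#!/usr/bin/env python
"""Generate the synthetic wild-type/mutant scenario used by all later steps.

Writes a genome (FASTA), gene models (GFF3), planted variants (VCF),
two-strain count matrix, secretome ratio table, transcription-factor
list and the truth manifest under scratch/scenario/.
"""

from poxscreen.simulate import default_study_scenario, generate_scenario

SEED = 2016

if __name__ == "__main__":
    bundle = generate_scenario(default_study_scenario(SEED), "scratch/scenario")
    plan = bundle.truth["variant_plan"]
    n_snv = sum(plan[k] for k in ("synonymous", "missense", "stop_gain",
                                  "intron", "intergenic", "promoter", "terminator"))
    print(f"scenario written to {bundle.out_dir} (seed {SEED})")
    print(f"  genes: {len(bundle.annotation.genes)} on {len(bundle.annotation.contigs)} contigs")
    print(f"  planted variants: {n_snv} SNVs + "
          f"{plan['cds_frameshift_deletion'] + plan['intergenic_deletion'] + plan['intergenic_insertion']} InDels")
    print(f"  intended candidates: {sum(len(v) for v in bundle.truth['candidates'].values())} "
          f"(A/B/C = {[len(bundle.truth['candidates'][r]) for r in 'ABC']})")
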