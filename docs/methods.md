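# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GFF3 and VCF readers and
writers convert at the boundary (both formats are 1-based inclusive).
This confines off-by-one arithmetic to the I/O layer — splicing, codon
indexing and window arithmetic never adjust by one.

When a gene carries several mRNA isoforms the first in file order is
kept and a warning logged; the screen has no isoform-level semantics.

## Variant model and consequence calling

VCF records are validated against the reference (REF must match the
genome) and multi-allelic rows are split. Internally each variant is
normalized to a pure event by stripping the shared anchor prefix, giving
a substitution, a deleted reference span, or an insertion point. The
region partition (CDS > intron > intergenic precedence) is computed on
the event's reference span, so a deletion spanning an exon–intron
junction counts as CDS.

SNV consequences are called directly: the genome position is mapped to
its spliced-CDS index (strand-aware), the affected codon is substituted
and re-translated. Any change in codon 1 is start-loss (codon 1 is
ATG, so every substitution destroys it); otherwise equal amino acid is
synonymous, a new stop before the annotated one is stop-gain, loss of
the annotated stop is stop-loss, and the rest are missense with an
`S725N`-style annotation (reference residue, 1-based protein position,
alternate residue). In-CDS InDels are frameshift when the length change
is not a multiple of three, in-frame otherwise; an InDel only partially
inside the CDS is called frameshift by convention (logged). Genes whose
CDS length is not divisible by three are processed on the truncated
codon frame with a warning rather than rejected.

The independent check for all of this is `apply_variant_oracle`: apply
the edit to the genome, remap the gene model across the edit, re-splice,
re-translate, and derive the consequence purely by comparing wild-type
and mutant proteins. The direct caller and the oracle share no code
path beyond splicing/translation primitives. The synthetic generator
runs the oracle on every variant it plants, so manifest labels are hard
guarantees.

Regulatory windows are measured on each gene's coding orientation: the
promoter window covers the `upstream_bp` (default 1500) bases strictly
5′ of the first base of the start codon, the terminator window the
`downstream_bp` (default 200) bases strictly 3′ of the last base of the
stop codon; bounds are inclusive (a variant exactly 1500 bp upstream is
flagged, 1501 is not). A variant may flag several genes. By default a
variant lying in any CDS is not window-flagged (configurable), keeping
window flags orthogonal to the region partition.

## Differential expression

Counts are FPKM-normalized (`count × 10⁹ / (length × library size)`).
Per gene, with pseudocount k = 0.5 guarding zeros, M is the log2 ratio
and D the absolute difference of the two strain means of normalized
values; strain 1 is the strain appearing first in the sample columns.
The null (|M|, D) cloud pools every within-strain replicate pair over
all genes; a gene's probability is the fraction of null points it
dominates strictly in both coordinates, ties counting against the gene.
With unreplicated strains the null is instead built from multinomial
pseudo-replicates of each library (5 pseudo-replicates at 20 % of the
library size, seeded). A gene is called differentially expressed at
|M| ≥ 1 and probability ≥ 0.8; the variant-bearing-gene filter of rule A
uses |M| ≥ 1 alone ("altered more than twofold", boundary inclusive).
The published description of this procedure also mentions a "P ≤ 0.01"
threshold alongside the probability; that quantity is not an output of
the noise-cloud statistic, so only the |M| and probability thresholds
are exposed.

Because the null cloud is pooled across genes, genes at very different
expression levels share one D scale — a low-expression gene with a real
effect can be out-scored in D by replicate noise of highly expressed
genes. This is a property of the method, preserved deliberately; the
synthetic scenario keeps expression levels within about one decade
(lognormal sigma 0.3) so that planted effects clear the cloud.

## Candidate rules

Rule A: at least one variant with a protein-altering consequence
(missense, stop-gain, stop-loss, start-loss, frameshift) in the gene or
a promoter/terminator-window flag for it, AND |M| ≥ 1. Rule B: a listed
transcription factor with a protein-altering CDS variant. Rule C: a
listed transcription factor with a differential-expression call and no
qualifying CDS variant (such genes surface via rule B instead; a gene
can still carry several rule tags, e.g. A and C). The candidate list is
exactly the union of the three rules with per-gene provenance; the
manual homology-based shortlisting that follows such a screen in
practice is out of scope.

## Synthetic scenarios

The default scenario plants, on ~120 genes across 3 contigs: 274 SNVs
split 105 CDS (35 synonymous / 66 missense / 4 stop-gain), 23 intron and
146 intergenic (53 promoter-window, 10 terminator-window, 83 far), and
12 InDels (one 1–2 bp CDS deletion causing a frameshift, 10 intergenic
deletions, one intergenic insertion) — the category mix of the strain
comparison it emulates. Genes have ATG starts, in-frame stops, 0–3
introns and a roughly even strand mix. Intergenic gaps are ≥ 3.3 kb so
that no position can fall in two genes' windows, making window truth
unambiguous (the generator rejects configurations violating this).

Counts are negative-binomial with variance μ + αμ². The candidate plan
assigns log2 effects of ±2.5 to the five rule-A genes and three rule-C
genes, 0 to rule-B genes (their evidence is the CDS variant), and
±1.5–4 to twelve additional non-TF genes; effects are applied
symmetrically (μ·2^∓fc/2) so the two libraries keep comparable total
mass and FPKM normalization is not distorted by composition. Scenario
defaults use α = 0.02 and depth ≈ 2000 per gene — tightly replicated
biological triplicates — chosen so that null genes stay below half the
two-fold threshold and planted effects exceed it by 2.5×, the regime in
which exact recovery of the planted candidate set is the designed
behaviour. The DE power analyses use the harder α = 0.1 / depth 500
setting explicitly. Secretome tables plant 30 up, 20 down and 10
unchanged proteins on gene ids (so concordance is testable) with 55 %
lacking a secretion signal.

What the generator does not emulate: mapping and counting noise beyond
the negative binomial, positional sequencing biases, overlapping genes,
alternative isoforms, GC-content structure, or any linkage between a
planted variant and the expression effect of its gene — recovery results
therefore show the screen's logic is correct under its stated
assumptions, not that the thresholds are optimal for real data.

All randomness flows from one scenario seed through
`SeedSequence([seed, stage])` derivations (genome, variants, counts,
secretome), so bundles are byte-identical across runs and stages are
independently reproducible.

## Downstream assay arithmetic

Relative expression uses the comparative-Ct method with amplification
efficiency fixed at 2. Enzyme activity is product (µmol) per minute per
mL of enzyme, times the dilution factor; conversion from absorbance to
µmol is an upstream calibration and is accepted as input. The t test
is pooled-variance Student's (two-tailed) to match the n = 3 spreadsheet
practice it mirrors, with Welch available by flag; zero pooled variance
with equal means returns t = 0, p = 1, with unequal means p = 0 is
returned and flagged.

## Phylogeny

Distances: p = differing / compared sites with pairwise deletion (gaps
and ambiguous residues X/B/Z excluded per pair; complete deletion by
flag), Poisson-corrected d = −ln(1 − p); p ≥ 1 or zero comparable sites
is an error (saturated/uncomparable pair). Trees: Saitou–Nei neighbour
joining; ties in the Q criterion break toward the smallest index pair,
so degenerate inputs resolve deterministically (possibly differently
from other implementations); negative branch lengths are clamped to
zero with the deficit moved to the sister branch, preserving the pair's
path length. Output is unrooted (written with a trifurcating root).
Bootstrap resamples alignment columns with replacement; replicates with
a saturated pair are skipped and logged, and supports are percentages of
completed replicates, attached to internal nodes as labels.

## Problem sizes

Tests and the acceptance script run on the scales above: scenarios of
~120 genes / ~0.6 Mb genomes, 286 planted variants, 3 vs 3 replicates;
DE calibration on 220-gene simulations over 10–20 seeds; neighbour
joining on 50 random 4–10-taxon trees; bootstraps of 100–1000
replicates. These sizes give exact, fully checkable truth while keeping
the whole suite in the tens of seconds.
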