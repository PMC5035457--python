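"""FPKM normalization and noise-cloud differential expression.

Differential expression between the two strains is called with the
(M, D) statistic used by NOISeq-style methods: per gene, M is the log2
ratio and D the absolute difference of the strain-mean normalized
expression values.  A gene's empirical "probability" of being
differentially expressed is the fraction of an empirical null cloud of
(|M|, D) points that the gene's own signal pair dominates strictly in
both coordinates.

With replicated samples the null cloud is built from all within-strain
replicate pairs pooled over genes (no distributional assumption).  When
a strain has a single sample the null is simulated by multinomial
resampling of each library (seeded), mirroring the no-replicate fallback
of the original method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ExpressionError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with strain labels and lengths."""

    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series  # bp per gene
    strain_of: dict[str, str]  # sample -> strain label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ExpressionError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index[0]
            raise ExpressionError(f"gene {missing!r} has no length")
        if (self.lengths <= 0).any():
            raise ExpressionError("gene lengths must be positive")
        unknown = set(self.counts.columns) - set(self.strain_of)
        if unknown:
            raise ExpressionError(f"samples without strain label: {sorted(unknown)}")
        strains = list(dict.fromkeys(self.strain_of[s] for s in self.counts.columns))
        if len(strains) != 2:
            raise ExpressionError(f"expected exactly two strains, got {sorted(set(strains))}")
        self.strains = strains  # in order of first appearance; M = log2(strain2/strain1)

    def samples_of(self, strain: str) -> list[str]:
        return [s for s in self.counts.columns if self.strain_of[s] == strain]

    @classmethod
    def from_files(cls, counts_tsv: str, samples_tsv: str, lengths_tsv: str) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(samples_tsv, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts, lengths, samples.iloc[:, 0].to_dict())


@dataclass
class DEConfig:
    lfc_threshold: float = 1.0
    prob_threshold: float = 0.8
    pseudocount: float = 0.5
    null_size: int = 100_000
    n_pseudo_replicates: int = 5
    pseudo_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0 or self.prob_threshold < 0:
            raise ExpressionError("thresholds must be >= 0")
        if self.pseudocount <= 0:
            raise ExpressionError("pseudocount must be > 0")


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped reads, per sample."""
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals[totals == 0].index[0]
        raise ExpressionError(f"sample {bad!r} has zero total count")
    return counts.counts * 1e9 / np.outer(counts.lengths.values, totals.values)


def _replicate_null(norm: pd.DataFrame, groups: list[list[str]], k: float):
    """Pooled (|M|, D) cloud from all within-strain replicate pairs."""
    ms, ds = [], []
    for samples in groups:
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a = norm[samples[i]].values
                b = norm[samples[j]].values
                ms.append(np.abs(np.log2((a + k) / (b + k))))
                ds.append(np.abs(a - b))
    if not ms:
        return None
    return np.concatenate(ms), np.concatenate(ds)


def _simulated_null(counts: CountMatrix, cfg: DEConfig):
    """Null cloud from multinomial resampling of each library.

    Each sample is resampled into ``n_pseudo_replicates`` pseudo-libraries
    of ``pseudo_fraction`` of its depth; within-sample pseudo-replicate
    pairs then play the role of technical replicates.
    """
    rng = np.random.default_rng(cfg.seed)
    ms, ds = [], []
    lengths = counts.lengths.values
    for sample in counts.counts.columns:
        col = counts.counts[sample].values
        total = col.sum()
        probs = col / total
        size = max(1, int(round(cfg.pseudo_fraction * total)))
        pseudo = rng.multinomial(size, probs, size=cfg.n_pseudo_replicates).astype(float)
        pseudo_fpkm = pseudo * 1e9 / (lengths[None, :] * size)
        for i in range(cfg.n_pseudo_replicates):
            for j in range(i + 1, cfg.n_pseudo_replicates):
                a, b = pseudo_fpkm[i], pseudo_fpkm[j]
                ms.append(np.abs(np.log2((a + cfg.pseudocount) / (b + cfg.pseudocount))))
                ds.append(np.abs(a - b))
    return np.concatenate(ms), np.concatenate(ds)


def de_call(counts: CountMatrix, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Per-gene M, D, empirical probability and DE call.

    Returns a DataFrame indexed by gene with columns ``M`` (log2 ratio,
    strain2 over strain1 in sorted-label order), ``D`` (absolute
    difference of normalized means), ``prob`` and ``is_de``.  The
    probability is the strict-dominance fraction over the null cloud;
    ties count against the gene.
    """
    cfg = cfg or DEConfig()
    if counts.counts.shape[1] < 2:
        raise ExpressionError("need at least two samples")
    if (counts.counts.values == 0).all():
        zeros = np.zeros(counts.counts.shape[0])
        return pd.DataFrame(
            {"M": zeros, "D": zeros, "prob": zeros, "is_de": zeros.astype(bool)},
            index=counts.counts.index,
        )
    norm = fpkm(counts)
    k = cfg.pseudocount
    s1, s2 = counts.strains
    g1, g2 = counts.samples_of(s1), counts.samples_of(s2)
    m1 = norm[g1].mean(axis=1).values + k
    m2 = norm[g2].mean(axis=1).values + k
    M = np.log2(m2 / m1)
    D = np.abs(m2 - m1)

    if len(g1) >= 2 and len(g2) >= 2:
        null = _replicate_null(norm, [g1, g2], k)
    else:
        null = _simulated_null(counts, cfg)
    null_m, null_d = null
    if null_m.size > cfg.null_size:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(null_m.size, cfg.null_size, replace=False)
        null_m, null_d = null_m[idx], null_d[idx]

    if not np.isfinite(null_m).all():  # all-zero genes give 0/0 -> drop
        keep = np.isfinite(null_m)
        null_m, null_d = null_m[keep], null_d[keep]
    prob = np.zeros(len(M))
    if null_m.size:
        # strict dominance in both coordinates
        absM = np.abs(M)
        prob = (
            (absM[:, None] > null_m[None, :]) & (D[:, None] > null_d[None, :])
        ).mean(axis=1)
    is_de = (np.abs(M) >= cfg.lfc_threshold) & (prob >= cfg.prob_threshold)
    return pd.DataFrame(
        {"M": M, "D": D, "prob": prob, "is_de": is_de}, index=counts.counts.index
    )


def twofold_set(results: pd.DataFrame, lfc: float = 1.0) -> set[str]:
    """Genes altered at least two-fold (|M| >= lfc), probability not required."""
    return set(results.index[np.abs(results["M"]) >= lfc])
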