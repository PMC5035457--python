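"""Candidate-regulator screen: three evidence rules over the omics layers.

A gene is nominated when it satisfies at least one of:

* Rule A — it carries a variant with a protein-altering consequence, or
  a variant in its promoter/terminator window, AND its expression is
  altered at least two-fold (|M| >= 1, probability not required);
* Rule B — it is an annotated transcription factor with a
  protein-altering variant in its CDS;
* Rule C — it is an annotated transcription factor called differentially
  expressed (|M| and probability thresholds), without a qualifying CDS
  variant (genes with both kinds of evidence surface through Rule B, and
  through Rule A when the expression condition also holds).

The union with per-gene rule provenance is the candidate list; the final
manual homology-based shortlisting applied in practice downstream of
this screen is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import twofold_set
from .variants import NONSYN, AnnotatedVariant, WindowConfig

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    window: WindowConfig = field(default_factory=WindowConfig)
    rule_a_lfc: float = 1.0
    rule_c_lfc: float = 1.0
    rule_c_prob: float = 0.8
    tf_gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if min(self.rule_a_lfc, self.rule_c_lfc, self.rule_c_prob) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class CandidateGene:
    gene_id: str
    rules: set[str]
    evidence: list[tuple[str, str]]  # (rule, human-readable detail)


def evidence_table(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    """Per-gene variant evidence: protein-altering CDS hits and window flags."""
    rows = []
    for av in annotated:
        v = av.variant
        loc = f"{v.contig_id}:{v.pos}"
        for gid, cons, aa in av.gene_hits:
            rows.append(
                dict(gene_id=gid, kind="cds", consequence=cons, detail=f"{cons} {aa}".strip() + f" @{loc}")
            )
        for gid in av.promoter_of:
            rows.append(dict(gene_id=gid, kind="promoter", consequence="", detail=f"promoter variant @{loc}"))
        for gid in av.terminator_of:
            rows.append(dict(gene_id=gid, kind="terminator", consequence="", detail=f"terminator variant @{loc}"))
    return pd.DataFrame(rows, columns=["gene_id", "kind", "consequence", "detail"])


def _nonsyn_cds_genes(ev: pd.DataFrame) -> set[str]:
    mask = (ev["kind"] == "cds") & ev["consequence"].isin(NONSYN)
    return set(ev.loc[mask, "gene_id"])


def _window_genes(ev: pd.DataFrame) -> set[str]:
    return set(ev.loc[ev["kind"].isin(["promoter", "terminator"]), "gene_id"])


def rule_a(
    annotated: list[AnnotatedVariant], de: pd.DataFrame, cfg: ScreenConfig
) -> set[str]:
    """Variant-bearing genes whose expression is altered >= two-fold."""
    ev = evidence_table(annotated)
    with_variant = _nonsyn_cds_genes(ev) | _window_genes(ev)
    return with_variant & twofold_set(de, cfg.rule_a_lfc)


def rule_b(annotated: list[AnnotatedVariant], cfg: ScreenConfig) -> set[str]:
    """Transcription factors with a protein-altering CDS variant."""
    ev = evidence_table(annotated)
    return _nonsyn_cds_genes(ev) & cfg.tf_gene_ids


def rule_c(
    de: pd.DataFrame,
    cfg: ScreenConfig,
    annotated: list[AnnotatedVariant] | None = None,
    exclude_cds_variant: bool = True,
) -> set[str]:
    """Differentially expressed transcription factors (no CDS-variant evidence)."""
    called = set(
        de.index[
            (np.abs(de["M"]) >= cfg.rule_c_lfc) & (de["prob"] >= cfg.rule_c_prob)
        ]
    )
    out = called & cfg.tf_gene_ids
    if exclude_cds_variant and annotated is not None:
        out -= _nonsyn_cds_genes(evidence_table(annotated))
    return out


def screen_candidates(
    annotated: list[AnnotatedVariant],
    de: pd.DataFrame,
    cfg: ScreenConfig,
    known_genes: set[str] | None = None,
) -> tuple[list[CandidateGene], dict]:
    """Union of the three rules with per-gene provenance and a funnel report."""
    if known_genes is not None:
        orphans = set(de.index) - known_genes
        if orphans:
            logger.warning(
                "%d genes present in expression results but unknown to the "
                "annotation (e.g. %s); retained", len(orphans), sorted(orphans)[0],
            )
    a = rule_a(annotated, de, cfg)
    b = rule_b(annotated, cfg)
    c = rule_c(de, cfg, annotated)
    ev = evidence_table(annotated)
    candidates: list[CandidateGene] = []
    for gid in sorted(a | b | c):
        rules = set()
        evidence: list[tuple[str, str]] = []
        gene_ev = ev[ev["gene_id"] == gid]
        if gid in a:
            rules.add("A_variant_plus_expression")
            for d in gene_ev["detail"]:
                evidence.append(("A_variant_plus_expression", d))
            evidence.append(
                ("A_variant_plus_expression", f"M={de.loc[gid, 'M']:.3f}")
            )
        if gid in b:
            rules.add("B_tf_cds_variant")
            for d in gene_ev.loc[gene_ev["kind"] == "cds", "detail"]:
                evidence.append(("B_tf_cds_variant", d))
        if gid in c:
            rules.add("C_tf_differential")
            evidence.append(
                (
                    "C_tf_differential",
                    f"M={de.loc[gid, 'M']:.3f} prob={de.loc[gid, 'prob']:.3f}",
                )
            )
        candidates.append(CandidateGene(gid, rules, evidence))
    report = {
        "rule_A": len(a),
        "rule_B": len(b),
        "rule_C": len(c),
        "total": len(candidates),
        "rule_A_genes": sorted(a),
        "rule_B_genes": sorted(b),
        "rule_C_genes": sorted(c),
    }
    return candidates, report


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene_id=c.gene_id,
                rules=";".join(sorted(c.rules)),
                evidence="; ".join(f"[{r}] {d}" for r, d in c.evidence),
            )
            for c in candidates
        ],
        columns=["gene_id", "rules", "evidence"],
    )
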