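"""Differential secreted-protein analysis.

Operates on an already-quantified secretome table: one row per protein
with its mutant/wild-type abundance ratio, a predicted-secretion-signal
flag, and a free-text functional tag.  Protein ids share the gene-id
namespace so transcript/protein concordance is directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class SecretomeError(ValueError):
    pass


@dataclass
class SecretomeTable:
    table: pd.DataFrame  # index protein_id; columns ratio, has_signal, tag

    def __post_init__(self) -> None:
        required = {"ratio", "has_signal"}
        missing = required - set(self.table.columns)
        if missing:
            raise SecretomeError(f"missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise SecretomeError("duplicate protein ids")
        if (self.table["ratio"] <= 0).any():
            bad = self.table.index[self.table["ratio"] <= 0][0]
            raise SecretomeError(f"non-positive ratio for {bad!r}")

    @classmethod
    def from_file(cls, path: str) -> "SecretomeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["has_signal"] = df["has_signal"].astype(bool)
        return cls(df)


def differential_secretion(
    table: SecretomeTable, fold_threshold: float = 2.0
) -> tuple[set[str], set[str]]:
    """(up, down) protein sets at the fold threshold (boundaries inclusive)."""
    if fold_threshold <= 1:
        raise SecretomeError("fold threshold must be > 1")
    r = table.table["ratio"]
    up = set(r.index[r >= fold_threshold])
    down = set(r.index[r <= 1.0 / fold_threshold])
    return up, down


def signal_fraction(table: SecretomeTable) -> float:
    """Fraction of identified proteins lacking a predicted secretion signal."""
    if len(table.table) == 0:
        raise SecretomeError("empty secretome table")
    return float((~table.table["has_signal"].astype(bool)).mean())


def omics_concordance(
    up: set[str],
    down: set[str],
    de: pd.DataFrame,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Protein-level vs transcript-level direction agreement.

    Each differential protein is labelled ``concordant`` (same direction
    at both levels, transcript at |M| >= lfc), ``discordant`` (opposite
    direction), or ``protein_only``; DE genes without a differential
    protein are ``transcript_only``.
    """
    rows = []
    de_up = set(de.index[(de["M"] >= lfc)])
    de_down = set(de.index[(de["M"] <= -lfc)])
    for pid in sorted(up | down):
        p_dir = "up" if pid in up else "down"
        if pid in de_up:
            t_dir = "up"
        elif pid in de_down:
            t_dir = "down"
        else:
            t_dir = ""
        if not t_dir:
            label = "protein_only"
        elif t_dir == p_dir:
            label = "concordant"
        else:
            label = "discordant"
        rows.append(dict(id=pid, protein=p_dir, transcript=t_dir, label=label))
    for gid in sorted((de_up | de_down) - up - down):
        t_dir = "up" if gid in de_up else "down"
        rows.append(dict(id=gid, protein="", transcript=t_dir, label="transcript_only"))
    return pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=["protein", "transcript", "label"]
    )
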