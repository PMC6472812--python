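"""Candidate gene screening from differential-expression statistics.

Reference-gene (RG) candidates must look flat in every RNA-Seq contrast:
|log2FC| <= 1 (inclusive) and P > 0.05 (strict) across all contrasts.
Target-gene (TG) candidates must be clearly induced somewhere: log2FC > 2
and P < 0.05 (both strict) in at least one contrast.  With the default
bounds the two screens are disjoint by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DETable",
    "read_de_table",
    "screen_reference_candidates",
    "screen_target_candidates",
]


@dataclass
class DETable:
    """Differential-expression statistics: (gene, contrast, log2fc, pvalue)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"gene", "contrast", "log2fc", "pvalue"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if df.duplicated(subset=["gene", "contrast"]).any():
            dup = df[df.duplicated(subset=["gene", "contrast"])].iloc[0]
            raise ValueError(
                f"duplicate (gene, contrast) pair: ({dup['gene']}, {dup['contrast']})"
            )
        p = df["pvalue"].astype(float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("pvalue outside [0, 1]")
        self.records = df.assign(
            log2fc=df["log2fc"].astype(float), pvalue=p
        ).reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    @property
    def contrasts(self) -> list[str]:
        return sorted(self.records["contrast"].unique())


def read_de_table(path, sep: str | None = None) -> DETable:
    """Read a gene,contrast,log2fc,pvalue CSV/TSV."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return DETable(pd.read_csv(path, sep=sep))


def _complete_genes(de: DETable) -> list[str]:
    """Genes with a record for every contrast; warn about the rest."""
    n_contrasts = len(de.contrasts)
    counts = de.records.groupby("gene")["contrast"].nunique()
    incomplete = counts[counts < n_contrasts].index.tolist()
    if incomplete:
        warnings.warn(
            "genes missing one or more contrasts were excluded from "
            f"screening: {sorted(map(str, incomplete))}",
            stacklevel=3,
        )
    return [g for g in de.genes if g not in set(incomplete)]


def screen_reference_candidates(
    de: DETable, fc_bound: float = 1.0, p_floor: float = 0.05
) -> list[str]:
    """Genes flat in ALL contrasts: |log2fc| <= fc_bound and pvalue > p_floor.

    The fold-change bound is inclusive, the P threshold strict.  Genes
    missing a contrast are excluded with a warning, never silently kept.
    """
    keep = []
    records = de.records
    for gene in _complete_genes(de):
        sub = records[records["gene"] == gene]
        if (sub["log2fc"].abs() <= fc_bound).all() and (sub["pvalue"] > p_floor).all():
            keep.append(gene)
    return keep


def screen_target_candidates(
    de: DETable, fc_min: float = 2.0, p_ceiling: float = 0.05
) -> list[str]:
    """Genes up-regulated in >=1 contrast: log2fc > fc_min and pvalue < p_ceiling.

    Both inequalities are strict, and both must hold within the same
    contrast.
    """
    keep = []
    records = de.records
    for gene in _complete_genes(de):
        sub = records[records["gene"] == gene]
        hit = (sub["log2fc"] > fc_min) & (sub["pvalue"] < p_ceiling)
        if hit.any():
            keep.append(gene)
    return keep
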