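"""Bundled example data from a published-style salt-stress qPCR study.

A *Calotropis procera* salt-stress experiment screens ten candidate
reference genes and three salt-responsive target genes from leaf
RNA-Seq differential-expression statistics, then ranks the candidates
with geNorm, NormFinder and BestKeeper in three experiments (leaf at
100 mM NaCl; root at 50 and 200 mM NaCl, four collection times each).
These tables make the worked examples and congruence computations
runnable without any download.
"""

from __future__ import annotations

import pandas as pd

from refstab.screening import DETable

__all__ = [
    "example_de_table",
    "example_top4_rankings",
    "example_pairwise_variation",
    "EXPERIMENTS",
]

EXPERIMENTS = ("leaf_100", "root_50", "root_200")

_CONTRASTS = ("30min_vs_0h", "2h_vs_0h", "8h_vs_0h", "45d_vs_45d_control")

# gene -> ((log2fc, pvalue) per contrast, in _CONTRASTS order)
_DE_ROWS = {
    "MAPK2": ((-0.16, 0.82), (0.14, 0.85), (-0.42, 0.56), (-0.07, 0.93)),
    "CYP23": ((0.35, 0.67), (0.18, 0.83), (0.71, 0.36), (-0.18, 0.79)),
    "ACT104": ((-0.10, 0.88), (-0.17, 0.80), (0.19, 0.78), (-0.07, 0.91)),
    "TBB4": ((-0.95, 0.26), (0.36, 0.35), (-0.47, 0.55), (0.79, 0.24)),
    "UBQ11": ((0.44, 0.51), (1.00, 0.11), (0.77, 0.24), (-0.34, 0.60)),
    "ACT": ((-0.23, 0.76), (-0.41, 0.58), (0.40, 0.58), (0.45, 0.53)),
    "r40S": ((0.11, 0.87), (0.03, 0.97), (1.00, 0.50), (-0.12, 0.86)),
    "PPR": ((0.29, 0.70), (0.03, 0.98), (0.23, 0.79), (0.15, 0.82)),
    "UBP25": ((-0.48, 0.47), (-0.50, 0.45), (-1.00, 0.30), (-0.07, 0.92)),
    "FBOX": ((-0.27, 0.73), (0.28, 0.68), (0.13, 0.87), (-0.69, 0.30)),
    "ND1": ((2.69, 0.02), (0.77, 0.67), (-1.04, 0.73), (0.24, 0.88)),
    "CNBL4": ((0.63, 1.00), (1.22, 0.44), (2.75, 0.03), (-1.14, 0.35)),
    "NAC78": ((2.74, 0.12), (2.61, 0.01), (3.61, 0.01), (0.33, 0.71)),
}

#: Gene classes in the example study: ten reference candidates, three targets.
REFERENCE_GENES = (
    "MAPK2", "CYP23", "ACT104", "TBB4", "UBQ11",
    "ACT", "r40S", "PPR", "UBP25", "FBOX",
)
TARGET_GENES = ("ND1", "CNBL4", "NAC78")

# experiment -> algorithm -> top-4 ranking (best first), from the global
# (all collection times) analysis of the example study
_TOP4 = {
    "leaf_100": {
        "genorm": ["CYP23", "ACT", "PPR", "r40S"],
        "normfinder": ["ACT", "TBB4", "PPR", "r40S"],
        "bestkeeper": ["TBB4", "ACT104", "r40S", "ACT"],
    },
    "root_50": {
        "genorm": ["CYP23", "UBP25", "ACT104", "ACT"],
        "normfinder": ["CYP23", "UBP25", "ACT104", "UBQ11"],
        "bestkeeper": ["ACT104", "CYP23", "UBP25", "ACT"],
    },
    "root_200": {
        "genorm": ["CYP23", "UBP25", "ACT104", "ACT"],
        "normfinder": ["UBP25", "CYP23", "ACT104", "r40S"],
        "bestkeeper": ["ACT104", "ACT", "UBP25", "CYP23"],
    },
}

# experiment -> {n: V_{n/n+1}} printed alongside the geNorm rankings
_V_SERIES = {
    "leaf_100": {2: 0.14, 3: 0.16},
    "root_50": {2: 0.23, 3: 0.14},
    "root_200": {2: 0.20, 3: 0.14},
}


def example_de_table() -> DETable:
    """DE statistics of the 13 example genes over four contrasts."""
    rows = []
    for gene, cells in _DE_ROWS.items():
        for contrast, (fc, p) in zip(_CONTRASTS, cells):
            rows.append(
                {"gene": gene, "contrast": contrast, "log2fc": fc, "pvalue": p}
            )
    return DETable(pd.DataFrame(rows))


def example_top4_rankings(experiment: str) -> dict[str, list[str]]:
    """Top-4 stability rankings per algorithm for one experiment."""
    if experiment not in _TOP4:
        raise KeyError(f"unknown experiment {experiment!r}; use {EXPERIMENTS}")
    return {alg: list(genes) for alg, genes in _TOP4[experiment].items()}


def example_pairwise_variation(experiment: str) -> dict[int, float]:
    """geNorm V_{n/n+1} values for one experiment (n -> V)."""
    if experiment not in _V_SERIES:
        raise KeyError(f"unknown experiment {experiment!r}; use {EXPERIMENTS}")
    return dict(_V_SERIES[experiment])
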