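"""Shared result container for the stability algorithms."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StabilityResult"]


@dataclass
class StabilityResult:
    """One algorithm's per-gene stability metric and ordered ranking.

    ``ranking`` lists genes best-first and is always a permutation of
    the analysed genes minus ``excluded``.  ``metric`` maps every ranked
    gene to the algorithm's stability number (geNorm M, NormFinder
    stability value, BestKeeper Pearson r).  ``excluded`` maps genes
    removed by QC to a human-readable reason.  ``tied`` flags rankings
    the algorithm could not fully resolve (e.g. geNorm's final pair,
    or an all-identical dataset).
    """

    algorithm: str
    metric: dict[str, float]
    ranking: list[str]
    excluded: dict[str, str] = field(default_factory=dict)
    tied: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.ranking) != set(self.metric):
            raise ValueError("ranking must be a permutation of the scored genes")

    def top(self, k: int) -> list[str]:
        if len(self.ranking) < k:
            raise ValueError(
                f"ranking has {len(self.ranking)} genes, cannot take top {k}"
            )
        return self.ranking[:k]
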