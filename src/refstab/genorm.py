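"""geNorm expression-stability analysis.

For each candidate gene j the stability measure M_j is the arithmetic
mean, over all other genes k, of the standard deviation across samples
of the log2 expression ratio Q_j / Q_k.  Genes with constant ratios to
every other gene get M = 0; noisy or regulated genes inflate every
ratio they appear in and drift to high M.  Ranking proceeds by stepwise
exclusion: the max-M gene is removed and M recomputed on the remainder
until two genes are left, which cannot be ranked further and are
reported as a tied best pair.

The optimal number of reference genes comes from normalization factors:
NF_n(s) is the geometric mean of the top-n genes' quantities at sample
s, and the pairwise variation V_{n/n+1} is the standard deviation over
samples of log2(NF_n / NF_{n+1}).  The smallest n with V <= 0.15 is
taken as sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refstab.cq_data import QuantityMatrix
from refstab.stability import StabilityResult

__all__ = [
    "PairwiseVariationSeries",
    "m_values",
    "rank_stepwise",
    "pairwise_variation",
    "optimal_rg_count",
    "genorm_analysis",
    "V_CUTOFF",
]

#: Pairwise-variation cutoff below which adding another gene is unnecessary.
V_CUTOFF = 0.15

_TIE_TOL = 1e-12


@dataclass
class PairwiseVariationSeries:
    """V_{n/n+1} for n = 2..G-1 plus the per-n normalization factors."""

    v: list[tuple[int, float]]
    nf_cache: dict[int, pd.Series] = field(default_factory=dict)

    def as_dict(self) -> dict[int, float]:
        return dict(self.v)


def _log_ratio_sd(qj: np.ndarray, qk: np.ndarray) -> tuple[float, int]:
    """SD (ddof=1) of log2(qj/qk) over pairwise-complete samples."""
    ok = np.isfinite(qj) & np.isfinite(qk)
    n = int(ok.sum())
    if n < 2:
        return np.nan, n
    ratios = np.log2(qj[ok] / qk[ok])
    return float(np.std(ratios, ddof=1)), n


def m_values(q: QuantityMatrix) -> pd.Series:
    """Per-gene geNorm M on pairwise-complete samples.

    Raises ``ValueError`` with fewer than 3 genes; a gene with fewer
    than 2 complete samples against every partner gets M = NaN (the
    caller excludes it with a reason).
    """
    genes = q.gene_ids
    if len(genes) < 3:
        raise ValueError(f"geNorm needs >=3 genes, got {len(genes)}")
    vals = q.values.to_numpy(dtype=float)
    out = {}
    for j, gj in enumerate(genes):
        sds = []
        for k, _ in enumerate(genes):
            if k == j:
                continue
            sd, n = _log_ratio_sd(vals[j], vals[k])
            if n >= 2:
                sds.append(sd)
        out[gj] = float(np.mean(sds)) if sds else np.nan
    return pd.Series(out, name="M")


def rank_stepwise(q: QuantityMatrix) -> tuple[StabilityResult, list[str]]:
    """geNorm ranking by stepwise exclusion of the least stable gene.

    Returns the result plus the exclusion trajectory (first removed
    first).  The final two genes are tied at ranks 1-2 and ordered by
    their full-set M, then gene id; a dataset whose genes all have
    equal M at every step is flagged fully tied and ordered by gene id.
    """
    full_m = m_values(q)
    excluded = {g: "fewer than 2 pairwise-complete samples"
                for g in full_m.index[full_m.isna()]}
    remaining = [g for g in q.gene_ids if g not in excluded]
    if len(remaining) < 3:
        raise ValueError("fewer than 3 genes survive QC")

    trajectory: list[str] = []
    ranking_tail: list[str] = []
    fully_tied = True
    current = list(remaining)
    while len(current) > 2:
        m = m_values(q.subset_genes(current))
        spread = float(m.max() - m.min())
        if spread > _TIE_TOL:
            fully_tied = False
        # worst gene; deterministic tie-break on gene id
        worst = sorted(m.index[np.isclose(m, m.max(), atol=_TIE_TOL)])[-1] \
            if spread <= _TIE_TOL else m.idxmax()
        current.remove(worst)
        trajectory.append(worst)
        ranking_tail.insert(0, worst)

    final_pair = sorted(current, key=lambda g: (full_m[g], g))
    ranking = final_pair + ranking_tail
    metric = {g: float(full_m[g]) for g in ranking}
    result = StabilityResult(
        algorithm="genorm",
        metric=metric,
        ranking=ranking,
        excluded=excluded,
        tied=fully_tied,
        extras={"final_pair": final_pair},
    )
    return result, trajectory


def pairwise_variation(
    q: QuantityMatrix, ranking: list[str]
) -> PairwiseVariationSeries:
    """V_{n/n+1} series over successive normalization factors.

    NF_n(s) is the geometric mean of the top-n ranked genes' Q at
    sample s; samples with a missing value among the top-(n+1) genes
    are dropped from that V term.
    """
    if len(ranking) < 3:
        raise ValueError("pairwise variation needs >=3 ranked genes")
    vals = q.values.loc[ranking]
    nf_cache: dict[int, pd.Series] = {}
    for n in range(2, len(ranking) + 1):
        top = vals.iloc[:n]
        nf_cache[n] = np.exp(np.log(top).mean(axis=0))
    v = []
    for n in range(2, len(ranking)):
        ratio = np.log2(nf_cache[n] / nf_cache[n + 1]).dropna()
        v.append((n, float(np.std(ratio, ddof=1))))
    return PairwiseVariationSeries(v=v, nf_cache=nf_cache)


def optimal_rg_count(
    v_series: PairwiseVariationSeries | dict[int, float] | list[tuple[int, float]],
    cutoff: float = V_CUTOFF,
) -> tuple[int, bool]:
    """Smallest n >= 2 with V_{n/n+1} <= cutoff.

    Returns ``(n, satisfied)``; when no V meets the cutoff the total
    gene count (last n + 1) is returned with ``satisfied=False``.
    """
    if isinstance(v_series, PairwiseVariationSeries):
        items = v_series.v
    elif isinstance(v_series, dict):
        items = sorted(v_series.items())
    else:
        items = sorted(v_series)
    if not items:
        raise ValueError("empty pairwise-variation series")
    for n, v in items:
        if v <= cutoff:
            return n, True
    return items[-1][0] + 1, False


def genorm_analysis(q: QuantityMatrix) -> StabilityResult:
    """Full geNorm run: ranking + V series + optimal gene count."""
    result, trajectory = rank_stepwise(q)
    vs = pairwise_variation(q, result.ranking)
    n_opt, satisfied = optimal_rg_count(vs)
    result.extras.update(
        {
            "trajectory": trajectory,
            "v_series": vs.as_dict(),
            "optimal_n": n_opt,
            "v_cutoff_satisfied": satisfied,
        }
    )
    return result
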