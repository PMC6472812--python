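"""Cross-algorithm congruence and factorial time-subset sweeps.

Congruence between two stability rankings is the percent overlap of
their unordered top-k sets (k = 4 by default).  The subset sweep
enumerates every nonempty combination of collection times (15 for a
four-time experiment), re-runs each stability algorithm on the samples
of that combination — control samples travel with their matched time —
and summarises, per algorithm, the mean congruence of subset top-k
sets against the global (all-times) ranking, plus how frequently each
gene makes the top-k across a designated subset family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from refstab.bestkeeper import bestkeeper
from refstab.cq_data import CqDataset, relative_quantities
from refstab.genorm import genorm_analysis
from refstab.normfinder import design_from_dataset, normfinder_stability
from refstab.stability import StabilityResult

__all__ = [
    "CongruenceReport",
    "SubsetRun",
    "top_k_congruence",
    "enumerate_condition_subsets",
    "subset_stability_sweep",
    "run_algorithm",
    "ALGORITHMS",
]

ALGORITHMS = ("genorm", "normfinder", "bestkeeper")


@dataclass
class CongruenceReport:
    """Pairwise and per-algorithm congruence summaries."""

    pairs: pd.DataFrame  # algorithm_a, algorithm_b, k, overlap, percent
    mean_congruence: dict[str, float] = field(default_factory=dict)
    frequencies: pd.DataFrame | None = None  # gene x algorithm top-k counts


@dataclass
class SubsetRun:
    """Stability results of all algorithms on one time-subset."""

    subset: tuple[str, ...]
    results: dict[str, StabilityResult]
    skipped: dict[str, str] = field(default_factory=dict)


def top_k_congruence(rank_a: list[str], rank_b: list[str], k: int = 4) -> float:
    """Percent overlap of the unordered top-k sets of two rankings."""
    if len(rank_a) < k or len(rank_b) < k:
        raise ValueError(
            f"both rankings need >= {k} genes "
            f"(got {len(rank_a)} and {len(rank_b)})"
        )
    overlap = len(set(rank_a[:k]) & set(rank_b[:k]))
    return 100.0 * overlap / k


def enumerate_condition_subsets(times: list[str]) -> list[tuple[str, ...]]:
    """All nonempty subsets of collection times, deterministic order.

    Ordered by size descending, then lexicographically within a size;
    a four-time experiment yields 15 combinations.
    """
    uniq = sorted(set(times))
    if not uniq:
        raise ValueError("time list is empty")
    if len(uniq) > 10:
        raise ValueError("more than 10 distinct times is unsupported")
    out: list[tuple[str, ...]] = []
    for size in range(len(uniq), 0, -1):
        out.extend(sorted(combinations(uniq, size)))
    return out


def run_algorithm(
    ds: CqDataset,
    algorithm: str,
    *,
    default_efficiency: float | None = None,
    group_by: str = "condition",
) -> StabilityResult:
    """Run one stability algorithm end-to-end on a dataset."""
    if algorithm == "genorm":
        q = relative_quantities(ds, default_efficiency=default_efficiency)
        return genorm_analysis(q)
    if algorithm == "normfinder":
        q = relative_quantities(ds, default_efficiency=default_efficiency)
        return normfinder_stability(q, design_from_dataset(ds, group_by))
    if algorithm == "bestkeeper":
        _, result = bestkeeper(ds)
        return result
    raise ValueError(f"unknown algorithm {algorithm!r}")


def cross_algorithm_congruence(
    results: dict[str, StabilityResult], k: int = 4
) -> CongruenceReport:
    """Pairwise top-k congruence between every pair of algorithm results."""
    rows = []
    names = sorted(results)
    for a, b in combinations(names, 2):
        pct = top_k_congruence(results[a].ranking, results[b].ranking, k)
        rows.append(
            {
                "algorithm_a": a,
                "algorithm_b": b,
                "k": k,
                "overlap": int(round(pct * k / 100)),
                "percent": pct,
            }
        )
    return CongruenceReport(pairs=pd.DataFrame(rows))


def subset_stability_sweep(
    ds: CqDataset,
    algorithms: tuple[str, ...] = ALGORITHMS,
    k: int = 4,
    *,
    default_efficiency: float | None = None,
    group_by: str = "condition",
    frequency_family: list[tuple[str, ...]] | None = None,
) -> tuple[list[SubsetRun], CongruenceReport]:
    """Re-rank every time-subset and compare with the global ranking.

    A subset keeps every sample (control and treated alike) whose time
    label belongs to it.  Subsets on which an algorithm's preconditions
    fail are recorded as skipped, not fatal.  ``frequency_family``
    selects which subsets feed the per-gene top-k frequency table
    (default: all subsets).
    """
    times = sorted(set(ds.sample_meta["time"].astype(str)))
    subsets = enumerate_condition_subsets(times)
    global_results = {
        alg: run_algorithm(
            ds, alg, default_efficiency=default_efficiency, group_by=group_by
        )
        for alg in algorithms
    }

    runs: list[SubsetRun] = []
    for subset in subsets:
        keep = [
            s
            for s in ds.samples
            if str(ds.sample_meta.loc[s, "time"]) in subset
        ]
        sub_ds = ds.subset_samples(keep)
        results: dict[str, StabilityResult] = {}
        skipped: dict[str, str] = {}
        for alg in algorithms:
            try:
                results[alg] = run_algorithm(
                    sub_ds,
                    alg,
                    default_efficiency=default_efficiency,
                    group_by=group_by,
                )
            except ValueError as exc:
                skipped[alg] = str(exc)
        runs.append(SubsetRun(subset=subset, results=results, skipped=skipped))

    # mean congruence of each algorithm's subset top-k vs its global top-k
    mean_congruence: dict[str, float] = {}
    pair_rows = []
    for alg in algorithms:
        pcts = []
        for run in runs:
            if alg not in run.results:
                continue
            if len(run.results[alg].ranking) < k:
                continue
            pct = top_k_congruence(
                run.results[alg].ranking, global_results[alg].ranking, k
            )
            pcts.append(pct)
            pair_rows.append(
                {
                    "algorithm": alg,
                    "subset": "+".join(run.subset),
                    "k": k,
                    "percent": pct,
                }
            )
        mean_congruence[alg] = float(pd.Series(pcts).mean()) if pcts else float("nan")

    family = frequency_family if frequency_family is not None else subsets
    family_set = {tuple(f) for f in family}
    genes = ds.genes
    freq = pd.DataFrame(0, index=genes, columns=list(algorithms))
    for run in runs:
        if run.subset not in family_set:
            continue
        for alg in algorithms:
            if alg in run.results and len(run.results[alg].ranking) >= k:
                for g in run.results[alg].top(k):
                    freq.loc[g, alg] += 1

    report = CongruenceReport(
        pairs=pd.DataFrame(pair_rows),
        mean_congruence=mean_congruence,
        frequencies=freq,
    )
    return runs, report
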