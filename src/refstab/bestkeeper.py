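"""BestKeeper descriptive stability analysis on raw Cq values.

BestKeeper works directly on per-sample mean Cq.  Genes whose Cq
standard deviation exceeds a cutoff (default 1 cycle) are excluded;
the BestKeeper index is then the per-sample geometric mean Cq of the
retained genes, and each retained gene is scored by the Pearson
correlation r between its Cq vector and the index (two-sided p from the
t approximation with n-2 degrees of freedom).  Genes with higher r and
p < 0.05 are considered more stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from refstab.cq_data import CqDataset
from refstab.stability import StabilityResult

__all__ = ["BestKeeperReport", "bestkeeper"]


@dataclass
class BestKeeperReport:
    """Per-gene descriptive statistics, exclusions, and the index."""

    stats: pd.DataFrame  # per gene: n, geo_mean, mean, min, max, sd, mad, cv_pct, r, p
    excluded: dict[str, str] = field(default_factory=dict)
    index: pd.Series | None = None  # per-sample geometric mean Cq


def _gene_descriptives(row: pd.Series) -> dict:
    x = row.dropna().to_numpy(dtype=float)
    return {
        "n": int(x.size),
        "geo_mean": float(stats.gmean(x)),
        "mean": float(x.mean()),
        "min": float(x.min()),
        "max": float(x.max()),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
        # the original tool's dispersion: mean absolute deviation
        # around the geometric mean, in cycles
        "mad": float(np.mean(np.abs(x - stats.gmean(x)))),
        "cv_pct": float(np.std(x, ddof=1) / x.mean() * 100) if x.size > 1 else np.nan,
    }


def bestkeeper(
    ds: CqDataset,
    sd_cutoff: float = 1.0,
    *,
    use_mad: bool = False,
    p_threshold: float = 0.05,
) -> tuple[BestKeeperReport, StabilityResult]:
    """Run the BestKeeper procedure.

    ``use_mad`` switches the exclusion statistic from the classical
    sample SD (ddof=1) to the mean absolute deviation around the
    geometric mean.  Ranking: genes with p < ``p_threshold`` first, by
    descending r, then ascending SD, then gene id; zero-variance genes
    (r undefined) are flagged and placed last.
    """
    means = ds.mean_cq()
    genes = list(means.index)
    if len(genes) < 2:
        raise ValueError(f"BestKeeper needs >=2 genes, got {len(genes)}")
    if means.shape[1] < 3:
        raise ValueError(f"BestKeeper needs >=3 samples, got {means.shape[1]}")

    desc = pd.DataFrame({g: _gene_descriptives(means.loc[g]) for g in genes}).T
    stat_col = "mad" if use_mad else "sd"
    excluded = {
        g: f"{stat_col.upper()} {desc.loc[g, stat_col]:.3f} > {sd_cutoff}"
        for g in genes
        if desc.loc[g, stat_col] > sd_cutoff
    }
    retained = [g for g in genes if g not in excluded]
    if not retained:
        raise ValueError("no gene passes SD cutoff")

    log_cq = np.log(means.loc[retained])
    index = np.exp(log_cq.mean(axis=0))
    index.name = "bestkeeper_index"

    r_col, p_col, flagged = {}, {}, {}
    for g in retained:
        row = means.loc[g]
        ok = row.notna() & index.notna()
        x = row[ok].to_numpy(dtype=float)
        y = index[ok].to_numpy(dtype=float)
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            r_col[g], p_col[g] = np.nan, np.nan
            flagged[g] = "zero variance: correlation undefined"
            continue
        r, p = stats.pearsonr(x, y)
        r_col[g], p_col[g] = float(r), float(p)

    desc["r"] = pd.Series(r_col)
    desc["p"] = pd.Series(p_col)
    report = BestKeeperReport(
        stats=desc, excluded=excluded, index=index
    )

    def sort_key(g: str):
        r, p = r_col.get(g, np.nan), p_col.get(g, np.nan)
        undefined = g in flagged or not np.isfinite(r)
        significant = (not undefined) and p < p_threshold
        return (
            undefined,  # defined correlations first
            not significant,  # significant first
            -(r if np.isfinite(r) else -np.inf),
            desc.loc[g, "sd"],
            g,
        )

    ranking = sorted(retained, key=sort_key)
    metric = {g: (r_col[g] if np.isfinite(r_col.get(g, np.nan)) else np.nan)
              for g in ranking}
    result = StabilityResult(
        algorithm="bestkeeper",
        metric=metric,
        ranking=ranking,
        excluded=dict(excluded),
        extras={"flagged": flagged, "sd": desc["sd"].to_dict(),
                "p": desc["p"].to_dict()},
    )
    return report, result
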