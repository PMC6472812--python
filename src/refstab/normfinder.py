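"""NormFinder model-based stability analysis.

The model decomposes log-scale expression into a sample effect (overall
amount of template), a gene x group effect (systematic regulation of a
gene in an experimental group — the quantity a reference gene must not
have), and residual intra-group noise.  Working on natural-log relative
quantities:

1. x = ln Q, per gene and sample;
2. z = x minus the per-sample mean across genes (removes the sample
   effect);
3. per gene i and group g: group mean z_ig and residual variance s2_ig
   (ddof=1);
4. inter-group deviation d_ig = z_ig - mean_g(z_ig);
5. stability rho_i = mean over groups of |d_ig_hat| + sqrt(var_ig_hat / n_g),

with the variance bias-correction and shrinkage of d toward zero
described below; lower rho means more stable.  With a single group the
inter-group term vanishes and rho reduces to the SD of z across samples.

Because the z-transform forces a zero sum across genes, the naive
residual variance s2 and squared deviation d^2 are biased upward by a
share of the other genes' variation; the corrected variance is

    var_hat_ig = max(0, s2_ig - mean_i(s2_ig) / (G - 1))

and d is shrunk by t_g = sigma_d2 / (sigma_d2 + var_hat_ig / n_g),
where sigma_d2 = max(0, sum_i d_ig^2 / (G - 1) - mean_i(var_hat_ig / n_g))
estimates the true between-gene spread of group effects.  ``plain=True``
skips both corrections (d_hat = d, var_hat = s2) for oracle comparison;
on well-separated data the two modes rank identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from refstab.cq_data import CqDataset, QuantityMatrix
from refstab.stability import StabilityResult

__all__ = ["GroupDesign", "normfinder_stability", "design_from_dataset"]


@dataclass
class GroupDesign:
    """Partition of samples into experimental groups."""

    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("group design must cover at least one sample")

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def samples_in(self, label: str) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == label)


def design_from_dataset(ds: CqDataset, group_by: str = "condition") -> GroupDesign:
    """Build a design from a metadata column (``condition`` or ``time``)."""
    if group_by not in ds.sample_meta.columns:
        raise ValueError(f"no metadata column {group_by!r}")
    col = ds.sample_meta[group_by].astype(str)
    return GroupDesign({s: col[s] for s in ds.samples})


def normfinder_stability(
    q: QuantityMatrix,
    design: GroupDesign,
    *,
    plain: bool = False,
) -> StabilityResult:
    """Rank genes by the NormFinder stability value rho (lower = stabler)."""
    genes = q.gene_ids
    n_genes = len(genes)
    if n_genes < 3:
        raise ValueError(f"NormFinder needs >=3 genes, got {n_genes}")
    samples = [s for s in q.sample_ids if s in design.groups]
    if not samples:
        raise ValueError("group design covers none of the matrix samples")
    labels = sorted(set(design.groups[s] for s in samples))

    x = np.log(q.values[samples].to_numpy(dtype=float))
    z = x - np.nanmean(x, axis=0, keepdims=True)
    zdf = pd.DataFrame(z, index=genes, columns=samples)

    if len(labels) == 1:
        rho = zdf.std(axis=1, ddof=1)
        metric = {g: float(rho[g]) for g in genes}
        ranking = sorted(genes, key=lambda g: (metric[g], g))
        return StabilityResult(
            algorithm="normfinder", metric=metric, ranking=ranking,
            extras={"groups": labels, "mode": "intra-only"},
        )

    group_samples = {g: [s for s in samples if design.groups[s] == g]
                     for g in labels}
    for lab, ss in group_samples.items():
        if len(ss) < 2:
            raise ValueError(
                f"group {lab!r} has {len(ss)} sample(s); multi-group "
                "designs need >=2 per group"
            )

    n_g = np.array([len(group_samples[lab]) for lab in labels], dtype=float)
    zbar = np.column_stack(
        [zdf[group_samples[lab]].mean(axis=1).to_numpy() for lab in labels]
    )  # genes x groups
    s2 = np.column_stack(
        [zdf[group_samples[lab]].var(axis=1, ddof=1).to_numpy() for lab in labels]
    )
    d = zbar - zbar.mean(axis=1, keepdims=True)  # genes x groups

    if plain:
        var_hat = s2
        d_hat = d
    else:
        var_hat = np.maximum(0.0, s2 - s2.mean(axis=0, keepdims=True) / (n_genes - 1))
        sig_d2 = np.maximum(
            0.0,
            (d**2).sum(axis=0) / (n_genes - 1)
            - (var_hat / n_g[None, :]).mean(axis=0),
        )  # per group
        denom = sig_d2[None, :] + var_hat / n_g[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, sig_d2[None, :] / denom, 0.0)
        d_hat = d * t

    rho = (np.abs(d_hat) + np.sqrt(var_hat / n_g[None, :])).mean(axis=1)
    metric = {g: float(r) for g, r in zip(genes, rho)}
    ranking = sorted(genes, key=lambda g: (metric[g], g))
    return StabilityResult(
        algorithm="normfinder",
        metric=metric,
        ranking=ranking,
        extras={
            "groups": labels,
            "mode": "plain" if plain else "adjusted",
            "group_means": pd.DataFrame(zbar, index=genes, columns=labels),
            "group_variances": pd.DataFrame(s2, index=genes, columns=labels),
            "inter_group_deviation": pd.DataFrame(d, index=genes, columns=labels),
        },
    )
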