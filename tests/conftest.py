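"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each statistic with explicit loops and textbook
formulas, independent of the library's vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from refstab.cq_data import CqDataset, QuantityMatrix


# ---------------------------------------------------------------- oracles

def sd_sample(xs) -> float:
    """Textbook n-1 standard deviation."""
    n = len(xs)
    mean = sum(xs) / n
    return math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))


def m_values_oracle(values: np.ndarray) -> list[float]:
    """geNorm M by direct double loop over gene pairs (complete data)."""
    n_genes, n_samples = values.shape
    out = []
    for j in range(n_genes):
        sds = []
        for k in range(n_genes):
            if k == j:
                continue
            ratios = [
                math.log2(values[j, s] / values[k, s]) for s in range(n_samples)
            ]
            sds.append(sd_sample(ratios))
        out.append(sum(sds) / len(sds))
    return out


def pairwise_variation_oracle(values: np.ndarray) -> dict[int, float]:
    """V_{n/n+1} by direct formula; rows must be ranked best-first."""
    n_genes, n_samples = values.shape
    out = {}
    for n in range(2, n_genes):
        ratios = []
        for s in range(n_samples):
            nf_n = math.prod(values[i, s] for i in range(n)) ** (1 / n)
            nf_n1 = math.prod(values[i, s] for i in range(n + 1)) ** (1 / (n + 1))
            ratios.append(math.log2(nf_n / nf_n1))
        out[n] = sd_sample(ratios)
    return out


def pearson_oracle(x, y) -> float:
    """Pearson r by the direct summation formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def normfinder_steps_oracle(values: np.ndarray, groups: list[list[int]]):
    """Spreadsheet-style evaluation of the model's first stages.

    Returns (z, group means z_ig, residual variances s2_ig,
    inter-group deviations d_ig) computed with explicit loops on
    natural-log quantities.
    """
    n_genes, n_samples = values.shape
    x = [[math.log(values[i, s]) for s in range(n_samples)]
         for i in range(n_genes)]
    z = [[x[i][s] - sum(x[g][s] for g in range(n_genes)) / n_genes
          for s in range(n_samples)] for i in range(n_genes)]
    zbar = [[sum(z[i][s] for s in grp) / len(grp) for grp in groups]
            for i in range(n_genes)]
    s2 = []
    for i in range(n_genes):
        row = []
        for gi, grp in enumerate(groups):
            mean = zbar[i][gi]
            row.append(
                sum((z[i][s] - mean) ** 2 for s in grp) / (len(grp) - 1)
            )
        s2.append(row)
    d = [
        [zbar[i][gi] - sum(zbar[i]) / len(groups) for gi in range(len(groups))]
        for i in range(n_genes)
    ]
    return np.array(z), np.array(zbar), np.array(s2), np.array(d)


# ---------------------------------------------------------------- fixtures

def make_quantity_matrix(values, genes=None, samples=None) -> QuantityMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return QuantityMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_dataset(mean_cq: np.ndarray, genes, samples, *, conditions=None,
                 times=None, efficiencies=None, replicate_jitter=0.0,
                 seed=0) -> CqDataset:
    """Build a dataset whose per-sample means equal ``mean_cq`` exactly.

    Two replicates at mean +/- jitter keep the per-sample mean exact while
    satisfying the >=2-replicates invariant.
    """
    rows = []
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            for r, delta in ((1, +replicate_jitter), (2, -replicate_jitter)):
                rows.append(
                    {"sample": s, "gene": g, "replicate": r,
                     "cq": mean_cq[i][j] + delta}
                )
    meta = pd.DataFrame(
        {
            "experiment": "t",
            "condition": (conditions or ["control"] * len(samples)),
            "time": (times or ["0h"] * len(samples)),
            "tissue": "leaf",
        },
        index=pd.Index(samples, name="sample"),
    )
    return CqDataset(pd.DataFrame(rows), meta,
                     efficiencies or {g: 2.0 for g in genes})


@pytest.fixture
def benchmark_dataset():
    """One draw of the 10-gene benchmark layout."""
    from refstab.synthetic import generate_cq_dataset, benchmark_spec

    return generate_cq_dataset(benchmark_spec(), seed=7)
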