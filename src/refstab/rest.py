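"""Relative expression of target genes with a randomization test.

The expression ratio of a target gene t against a panel of reference
genes r1..rR between a control and a treated group is

    ratio = E_t ** (meanCq_control(t) - meanCq_treated(t)) / NF_ref,
    NF_ref = geometric mean over r of E_r ** (meanCq_control(r) - meanCq_treated(r)),

with E the per-gene amplification factor.  Significance comes from a
pairwise fixed-reallocation randomization test: the group labels of
whole replicates (each replicate carries its Cq for the target and all
references jointly, preserving between-gene correlation) are reshuffled
among the pooled replicates, keeping group sizes fixed, and the
two-sided p-value is the fraction of reallocations whose |log ratio|
reaches the observed one, with the (b+1)/(n+1) correction.

Resolution caveat: with n_c-vs-n_t replicates there are only
C(n_c+n_t, n_c) distinct reallocations, and the complete group swap
always reproduces |log ratio|, so the smallest attainable two-sided p
is 2/C(n_c+n_t, n_c) — 0.1 at 3v3.  Calibrated significance at the 5%
level therefore needs at least 4v4 replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "ExpressionResult",
    "relative_expression",
    "randomization_test",
    "exact_permutation_p",
    "analyze_expression",
]


@dataclass
class ExpressionResult:
    """REST-style outcome for one target gene."""

    target: str
    ratio: float
    p: float
    ci95: tuple[float, float]
    call: str  # 'up', 'down', or 'ns'
    n_control: int
    n_treated: int
    iterations: int
    seed: int | None


def _as_matrix(groups: dict[str, np.ndarray], genes: list[str]) -> np.ndarray:
    """Stack per-gene replicate vectors into a replicate x gene matrix."""
    cols = []
    n = None
    for g in genes:
        v = np.asarray(groups[g], dtype=float)
        if n is None:
            n = v.size
        elif v.size != n:
            raise ValueError(
                f"gene {g!r} has {v.size} replicates, expected {n} "
                "(fixed reallocation needs complete replicate vectors)"
            )
        cols.append(v)
    return np.column_stack(cols)


def _weights(target: str, refs: list[str], efficiencies: dict[str, float]) -> np.ndarray:
    for g in [target, *refs]:
        if g not in efficiencies:
            raise ValueError(f"missing amplification efficiency for gene {g!r}")
    w = np.empty(1 + len(refs))
    w[0] = np.log(efficiencies[target])
    for i, r in enumerate(refs, start=1):
        w[i] = -np.log(efficiencies[r]) / len(refs)
    return w


def relative_expression(
    target: str,
    refs: list[str],
    control: dict[str, np.ndarray],
    treated: dict[str, np.ndarray],
    efficiencies: dict[str, float],
) -> float:
    """Expression ratio of ``target`` normalized by the reference panel.

    ``control`` / ``treated`` map each gene (target and references) to
    its replicate Cq vector in that group.
    """
    if not refs:
        raise ValueError("at least one reference gene is required")
    for name, grp in (("control", control), ("treated", treated)):
        for g in [target, *refs]:
            if g not in grp:
                raise ValueError(f"missing {name} Cq data for gene {g!r}")
    genes = [target, *refs]
    w = _weights(target, refs, efficiencies)
    dcq = np.array(
        [
            np.mean(np.asarray(control[g], float))
            - np.mean(np.asarray(treated[g], float))
            for g in genes
        ]
    )
    return float(np.exp(w @ dcq))


def _stat_matrix(
    pooled: np.ndarray, ctrl_idx: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """log-ratio statistic for each row of control-index assignments."""
    n = pooled.shape[0]
    n_c = ctrl_idx.shape[1]
    mask = np.zeros((ctrl_idx.shape[0], n))
    rows = np.arange(ctrl_idx.shape[0])[:, None]
    mask[rows, ctrl_idx] = 1.0
    c_sums = mask @ pooled  # splits x genes
    t_sums = pooled.sum(axis=0)[None, :] - c_sums
    diffs = c_sums / n_c - t_sums / (n - n_c)
    return diffs @ w


def randomization_test(
    target: str,
    refs: list[str],
    control: dict[str, np.ndarray],
    treated: dict[str, np.ndarray],
    efficiencies: dict[str, float],
    iterations: int = 2000,
    seed: int | None = None,
) -> float:
    """Two-sided fixed-reallocation randomization p-value.

    Replicates (full gene vectors) are pooled and group labels randomly
    reassigned ``iterations`` times with group sizes preserved;
    p = (b + 1) / (iterations + 1) where b counts reallocations with
    |log ratio| >= the observed one.  Deterministic under a fixed seed.
    """
    if iterations < 100:
        raise ValueError("use at least 100 iterations")
    genes = [target, *refs]
    w = _weights(target, refs, efficiencies)
    c_mat = _as_matrix(control, genes)
    t_mat = _as_matrix(treated, genes)
    n_c, n_t = c_mat.shape[0], t_mat.shape[0]
    if n_c < 2 or n_t < 2:
        raise ValueError("each group needs >=2 replicates")
    pooled = np.vstack([c_mat, t_mat])
    if np.allclose(pooled.std(axis=0), 0.0):
        warnings.warn(
            "zero-variance replicate data: randomization test is "
            "uninformative, returning p = 1",
            stacklevel=2,
        )
        return 1.0
    obs = abs(w @ (c_mat.mean(axis=0) - t_mat.mean(axis=0)))

    rng = np.random.default_rng(seed)
    n = n_c + n_t
    perms = np.argsort(rng.random((iterations, n)), axis=1)[:, :n_c]
    stats = _stat_matrix(pooled, perms, w)
    b = int(np.sum(np.abs(stats) >= obs - 1e-12))
    return (b + 1) / (iterations + 1)


def exact_permutation_p(
    target: str,
    refs: list[str],
    control: dict[str, np.ndarray],
    treated: dict[str, np.ndarray],
    efficiencies: dict[str, float],
) -> float:
    """Exact two-sided permutation p over all group-size-preserving splits.

    Enumerable only for small designs (<= ~12 pooled replicates).
    """
    genes = [target, *refs]
    w = _weights(target, refs, efficiencies)
    c_mat = _as_matrix(control, genes)
    t_mat = _as_matrix(treated, genes)
    n_c = c_mat.shape[0]
    pooled = np.vstack([c_mat, t_mat])
    n = pooled.shape[0]
    if comb(n, n_c) > 5000:
        raise ValueError("too many splits to enumerate exactly")
    obs = abs(w @ (c_mat.mean(axis=0) - t_mat.mean(axis=0)))
    splits = np.array(list(combinations(range(n), n_c)))
    stats = _stat_matrix(pooled, splits, w)
    return float(np.mean(np.abs(stats) >= obs - 1e-12))


def analyze_expression(
    target: str,
    refs: list[str],
    control: dict[str, np.ndarray],
    treated: dict[str, np.ndarray],
    efficiencies: dict[str, float],
    iterations: int = 2000,
    bootstrap: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ExpressionResult:
    """Full REST-style evaluation: ratio, randomization p, bootstrap CI, call."""
    ratio = relative_expression(target, refs, control, treated, efficiencies)
    p = randomization_test(
        target, refs, control, treated, efficiencies,
        iterations=iterations, seed=seed,
    )
    genes = [target, *refs]
    w = _weights(target, refs, efficiencies)
    c_mat = _as_matrix(control, genes)
    t_mat = _as_matrix(treated, genes)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    boots = np.empty(bootstrap)
    for i in range(bootstrap):
        ci = rng.integers(0, c_mat.shape[0], c_mat.shape[0])
        ti = rng.integers(0, t_mat.shape[0], t_mat.shape[0])
        boots[i] = w @ (c_mat[ci].mean(axis=0) - t_mat[ti].mean(axis=0))
    lo, hi = np.exp(np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    if p < alpha and ratio > 1:
        call = "up"
    elif p < alpha and ratio < 1:
        call = "down"
    else:
        call = "ns"
    return ExpressionResult(
        target=target,
        ratio=ratio,
        p=p,
        ci95=(float(lo), float(hi)),
        call=call,
        n_control=c_mat.shape[0],
        n_treated=t_mat.shape[0],
        iterations=iterations,
        seed=seed,
    )
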