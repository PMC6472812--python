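"""geNorm M-values, stepwise ranking, and pairwise variation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from refstab.cq_data import QuantityMatrix, relative_quantities
from refstab.genorm import (
    genorm_analysis,
    m_values,
    optimal_rg_count,
    pairwise_variation,
    rank_stepwise,
)
from refstab.synthetic import GeneSpec, CqSimSpec, generate_cq_dataset

from conftest import m_values_oracle, make_quantity_matrix, pairwise_variation_oracle


def q_from_cq(cq_rows, e=2.0):
    cq = np.asarray(cq_rows, dtype=float)
    vals = e ** (cq.min(axis=1, keepdims=True) - cq)
    return make_quantity_matrix(vals)


class TestMValues:
    def test_constant_ratio_genes_have_zero_m(self):
        base = np.array([1.0, 0.5, 0.125, 0.25])
        q = make_quantity_matrix([base, 0.5 * base, 0.25 * base])
        m = m_values(q)
        assert np.allclose(m, 0.0, atol=1e-14)

    def test_matches_direct_summation_on_hand_instance(self):
        vals = np.array([
            [1.0, 0.5, 0.25, 0.8],
            [0.9, 0.7, 0.35, 1.0],
            [1.0, 0.2, 0.5, 0.3],
        ])
        m = m_values(make_quantity_matrix(vals))
        oracle = m_values_oracle(vals)
        assert np.allclose(m.to_numpy(), oracle, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(3, 6), st.integers(2, 8)),
            elements=st.floats(0.01, 1.0, allow_nan=False),
        )
    )
    def test_matches_oracle_on_random_instances(self, vals):
        m = m_values(make_quantity_matrix(vals))
        assert np.allclose(m.to_numpy(), m_values_oracle(vals), atol=1e-12)

    def test_invariant_to_rescaling_a_gene_column(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.05, 1.0, (5, 6))
        m0 = m_values(make_quantity_matrix(vals))
        vals2 = vals.copy()
        vals2[2] *= 7.3
        m1 = m_values(make_quantity_matrix(vals2))
        assert np.allclose(m0, m1, atol=1e-12)

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            m_values(make_quantity_matrix([[1.0, 0.5], [0.5, 1.0]]))

    def test_added_noise_increases_m(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cq = np.tile(np.array([20.0, 21.0, 22.0, 20.5, 21.5, 23.0]), (5, 1))
            clean_m = m_values(q_from_cq(cq)).iloc[0]
            noisy = cq.copy()
            noisy[0] += rng.normal(0, 0.5, 6)
            noisy_m = m_values(q_from_cq(noisy)).iloc[0]
            hits += noisy_m > clean_m
        assert hits >= int(0.95 * n_seeds)


class TestRankStepwise:
    def test_zero_shift_genes_take_top_ranks(self):
        from refstab.synthetic import benchmark_spec

        spec = benchmark_spec()
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            ds, truth = generate_cq_dataset(spec, seed)
            result, _ = rank_stepwise(relative_quantities(ds))
            if set(result.ranking[:3]) == set(truth.stable_genes()):
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_identical_genes_fall_back_to_gene_id_order(self):
        base = np.array([1.0, 0.5, 0.25, 0.7])
        q = make_quantity_matrix(
            [base, base * 0.9, base * 0.8, base * 0.6],
            genes=["d", "b", "c", "a"],
        )
        result, _ = rank_stepwise(q)
        assert result.tied
        assert result.ranking == sorted(result.ranking)

    def test_removing_worst_gene_reproduces_remaining_trajectory(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.05, 1.0, (6, 8))
        q = make_quantity_matrix(vals)
        _, trajectory = rank_stepwise(q)
        q2 = make_quantity_matrix(
            np.delete(vals, list(q.gene_ids).index(trajectory[0]), axis=0),
            genes=[g for g in q.gene_ids if g != trajectory[0]],
        )
        _, trajectory2 = rank_stepwise(q2)
        assert trajectory2 == trajectory[1:]

    def test_mean_m_non_increasing_along_exclusion(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.05, 1.0, (7, 10))
        q = make_quantity_matrix(vals)
        result, trajectory = rank_stepwise(q)
        remaining = list(q.gene_ids)
        means = [m_values(q.subset_genes(remaining)).mean()]
        for worst in trajectory:
            remaining.remove(worst)
            if len(remaining) >= 3:
                means.append(m_values(q.subset_genes(remaining)).mean())
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))


class TestPairwiseVariation:
    def test_identical_genes_have_zero_v(self):
        base = np.array([1.0, 0.5, 0.25, 0.7])
        q = make_quantity_matrix([base, base * 0.5, base * 0.9, base * 0.3])
        vs = pairwise_variation(q, list(q.gene_ids))
        assert all(v == pytest.approx(0.0, abs=1e-12) for _, v in vs.v)

    def test_matches_direct_formula_on_hand_instance(self):
        vals = np.array([
            [1.0, 0.5, 0.25, 0.8],
            [0.9, 0.7, 0.35, 1.0],
            [1.0, 0.2, 0.5, 0.3],
            [0.6, 0.9, 0.15, 0.45],
        ])
        q = make_quantity_matrix(vals)
        vs = pairwise_variation(q, list(q.gene_ids))
        oracle = pairwise_variation_oracle(vals)
        for n, v in vs.v:
            assert v == pytest.approx(oracle[n], abs=1e-12)

    def test_n_beyond_gene_count_errors(self):
        q = make_quantity_matrix(np.full((2, 4), 0.5))
        with pytest.raises(ValueError):
            pairwise_variation(q, list(q.gene_ids))


class TestOptimalCount:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ({2: 0.14, 3: 0.16}, 2),  # leaf-style series
            ({2: 0.23, 3: 0.14}, 3),  # root-style series
            ({2: 0.0, 3: 0.0}, 2),
        ],
    )
    def test_printed_style_series(self, series, expected):
        n, satisfied = optimal_rg_count(series)
        assert n == expected and satisfied

    def test_no_n_satisfying_cutoff_flags_it(self):
        n, satisfied = optimal_rg_count({2: 0.4, 3: 0.3, 4: 0.2})
        assert n == 5 and not satisfied

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            optimal_rg_count({})


def test_well_behaved_panel_stays_below_m_limit():
    """A candidate panel without strongly regulated members keeps every M
    under the conventional 1.5 screening limit (the benchmark's 2-4 cycle
    injected responders exceed it by design)."""
    from refstab.synthetic import benchmark_spec

    spec = benchmark_spec(shifts=(0.0, 0.0, 0.0, 0.5, 1.0, 1.5))
    for seed in range(5):
        ds, _ = generate_cq_dataset(spec, seed)
        result = genorm_analysis(relative_quantities(ds))
        assert max(result.metric.values()) < 1.5
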