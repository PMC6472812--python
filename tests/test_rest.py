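"""REST-style expression ratios and the fixed-reallocation randomization test."""

import numpy as np
import pytest

from refstab.rest import (
    analyze_expression,
    exact_permutation_p,
    randomization_test,
    relative_expression,
)

EFF = {"T": 2.0, "R1": 2.0, "R2": 1.9}


def groups_from(cq: dict[str, list[float]]):
    return {g: np.asarray(v, dtype=float) for g, v in cq.items()}


class TestRatio:
    def test_identical_groups_ratio_one(self):
        c = groups_from({"T": [20, 20, 20], "R1": [22, 22, 22], "R2": [24, 24, 24]})
        assert relative_expression("T", ["R1", "R2"], c, c, EFF) == pytest.approx(1.0)

    def test_two_cycle_target_shift_quadruples(self):
        c = groups_from({"T": [20, 20], "R1": [22, 22]})
        t = groups_from({"T": [18, 18], "R1": [22, 22]})
        assert relative_expression("T", ["R1"], c, t, EFF) == pytest.approx(4.0)

    def test_reference_shift_halves(self):
        c = groups_from({"T": [20, 20], "R1": [22, 22]})
        t = groups_from({"T": [20, 20], "R1": [21, 21]})
        assert relative_expression("T", ["R1"], c, t, EFF) == pytest.approx(0.5)

    def test_single_ref_symmetry_product_is_one(self):
        rng = np.random.default_rng(0)
        c = groups_from({"T": rng.normal(20, 0.3, 3), "R1": rng.normal(22, 0.3, 3)})
        t = groups_from({"T": rng.normal(19, 0.3, 3), "R1": rng.normal(22, 0.3, 3)})
        eff = {"T": 2.0, "R1": 2.0}
        fwd = relative_expression("T", ["R1"], c, t, eff)
        rev = relative_expression("R1", ["T"], c, t, eff)
        assert fwd * rev == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_named_in_error(self):
        c = groups_from({"T": [20, 20]})
        with pytest.raises(ValueError, match="R1"):
            relative_expression("T", ["R1"], c, c, EFF)


class TestRandomization:
    def test_identical_groups_give_p_one(self):
        c = groups_from({"T": [20, 20, 20], "R1": [22, 22, 22]})
        with pytest.warns(UserWarning, match="zero-variance"):
            p = randomization_test("T", ["R1"], c, c, EFF, seed=1)
        assert p == 1.0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        c = groups_from({"T": rng.normal(20, 0.2, 4), "R1": rng.normal(22, 0.2, 4)})
        t = groups_from({"T": rng.normal(19, 0.2, 4), "R1": rng.normal(22, 0.2, 4)})
        p1 = randomization_test("T", ["R1"], c, t, EFF, seed=42)
        p2 = randomization_test("T", ["R1"], c, t, EFF, seed=42)
        assert p1 == p2

    def test_three_vs_three_cannot_beat_p_of_point_one(self):
        """With 3v3 replicates only C(6,3)=20 reallocations exist and the
        full swap mirrors |log ratio|, so the exact two-sided p is >= 0.1."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c = groups_from(
                {"T": rng.normal(20, 0.2, 3), "R1": rng.normal(22, 0.2, 3)}
            )
            t = groups_from(
                {"T": rng.normal(16, 0.2, 3), "R1": rng.normal(22, 0.2, 3)}
            )
            assert exact_permutation_p("T", ["R1"], c, t, EFF) >= 0.1 - 1e-12

    def test_sampled_p_tracks_exact_enumeration(self):
        rng = np.random.default_rng(7)
        c = groups_from({"T": rng.normal(20, 0.3, 5), "R1": rng.normal(22, 0.3, 5)})
        t = groups_from({"T": rng.normal(19.3, 0.3, 5), "R1": rng.normal(22, 0.3, 5)})
        exact = exact_permutation_p("T", ["R1"], c, t, EFF)
        sampled = randomization_test(
            "T", ["R1"], c, t, EFF, iterations=20_000, seed=3
        )
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_label_swap_inverts_ratio_but_keeps_p(self):
        rng = np.random.default_rng(11)
        c = groups_from({"T": rng.normal(20, 0.2, 4), "R1": rng.normal(22, 0.2, 4)})
        t = groups_from({"T": rng.normal(19, 0.2, 4), "R1": rng.normal(22, 0.2, 4)})
        r_fwd = relative_expression("T", ["R1"], c, t, EFF)
        r_rev = relative_expression("T", ["R1"], t, c, EFF)
        assert r_fwd * r_rev == pytest.approx(1.0, abs=1e-12)
        p_fwd = exact_permutation_p("T", ["R1"], c, t, EFF)
        p_rev = exact_permutation_p("T", ["R1"], t, c, EFF)
        assert p_fwd == pytest.approx(p_rev, abs=1e-12)

    def test_type_one_error_calibrated_at_six_vs_six(self):
        rejections = 0
        n_datasets = 300
        for s in range(n_datasets):
            rng = np.random.default_rng(20_000 + s)
            genes = ["T", "R1", "R2"]
            c = {g: rng.normal(20, 0.2, 6) for g in genes}
            t = {g: rng.normal(20, 0.2, 6) for g in genes}
            p = randomization_test(
                "T", ["R1", "R2"], c, t, EFF, iterations=1000, seed=s
            )
            rejections += p < 0.05
        assert 0.02 <= rejections / n_datasets <= 0.08

    def test_power_against_fourfold_change_at_six_vs_six(self):
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(40_000 + s)
            genes = ["T", "R1", "R2"]
            c = {g: rng.normal(20, 0.2, 6) for g in genes}
            t = {
                g: rng.normal(20, 0.2, 6) - (2.0 if g == "T" else 0.0)
                for g in genes
            }
            p = randomization_test(
                "T", ["R1", "R2"], c, t, EFF, iterations=1000, seed=s
            )
            hits += p < 0.05
        assert hits >= int(0.95 * n_seeds)


class TestAnalyzeExpression:
    def test_calls_follow_ratio_and_p(self):
        rng = np.random.default_rng(9)
        genes = ["T", "R1", "R2"]
        c = {g: rng.normal(20, 0.2, 6) for g in genes}
        t_up = {g: rng.normal(20, 0.2, 6) - (2.0 if g == "T" else 0.0)
                for g in genes}
        res = analyze_expression("T", ["R1", "R2"], c, t_up, EFF, seed=1)
        assert res.ratio > 1 and res.call == "up"
        assert res.ci95[0] <= res.ratio <= res.ci95[1]

        t_null = {g: rng.normal(20, 0.2, 6) for g in genes}
        res2 = analyze_expression("T", ["R1", "R2"], c, t_null, EFF, seed=1)
        assert res2.call == "ns" or res2.p < 0.05  # ns unless a rare false hit
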