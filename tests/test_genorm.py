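"""geNorm statistics against hand calculations and a direct-formula oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from conftest import as_dict_of_lists, random_quantities
from erenorm import (
    CqDesign,
    TargetSpec,
    classify_stability,
    generate_cq_dataset,
    cq_to_relative_quantity,
    m_values,
    normalization_factors,
    pairwise_variation,
    rank_targets,
    v_curve,
)
from erenorm.genorm import GeNormError


def _q(**cols):
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))])


class TestPairwiseVariation:
    def test_identical_profiles_have_zero_variation(self):
        q = _q(a=[1.0, 2.0, 3.0, 4.0], b=[1.0, 2.0, 3.0, 4.0])
        assert pairwise_variation(q, "a", "b") == 0.0

    def test_constant_ratio_has_zero_variation(self):
        q = _q(a=[1.0, 2.0, 3.0], b=[2.0, 4.0, 6.0])
        assert pairwise_variation(q, "a", "b") == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_log_ratio_profile(self):
        # log2 ratios {0, 0, 2, 2}: variance 4/3, SD 1.1547
        q = _q(a=[1.0, 1.0, 4.0, 4.0], b=[1.0, 1.0, 1.0, 1.0])
        assert pairwise_variation(q, "a", "b") == pytest.approx(np.sqrt(4 / 3), abs=1e-10)

    def test_symmetry(self, q_fixture):
        assert pairwise_variation(q_fixture, "t1", "t2") == pytest.approx(
            pairwise_variation(q_fixture, "t2", "t1"), abs=1e-12
        )

    def test_too_few_samples_raises(self):
        with pytest.raises(GeNormError, match="3 samples"):
            pairwise_variation(_q(a=[1.0, 2.0], b=[1.0, 1.0]), "a", "b")


class TestMValues:
    def test_three_gene_construction_with_one_divergent_profile(self):
        q = _q(
            a=[1.0, 1.0, 1.0, 1.0],
            b=[1.0, 1.0, 1.0, 1.0],
            c=[1.0, 1.0, 4.0, 4.0],
        )
        m = m_values(q)
        v = np.sqrt(4 / 3)
        assert m["a"] == pytest.approx((0 + v) / 2, abs=1e-10)
        assert m["c"] == pytest.approx(v, abs=1e-10)

    def test_all_proportional_targets_have_zero_m(self):
        base = np.array([1.0, 3.0, 0.5, 2.0])
        q = _q(a=base, b=2 * base, c=0.25 * base)
        assert np.allclose(m_values(q).to_numpy(), 0.0, atol=1e-12)

    def test_matches_direct_formula_oracle(self, q_fixture):
        m = m_values(q_fixture)
        expected = oracle.m_values(as_dict_of_lists(q_fixture))
        for t in q_fixture.columns:
            assert m[t] == pytest.approx(expected[t], abs=1e-10)


class TestRanking:
    def test_designed_unstable_target_is_excluded_first(self):
        targets = [
            TargetSpec("a", 2.0, 20.0, biological_sd=0.05),
            TargetSpec("b", 2.0, 22.0, biological_sd=0.05),
            TargetSpec("c", 2.0, 24.0, biological_sd=1.5),
        ]
        design = CqDesign(targets=targets, groups=["g"], n_samples=8, seed=5)
        cq, _ = generate_cq_dataset(design)
        ranking = rank_targets(cq_to_relative_quantity(cq, 2.0))
        assert ranking.exclusion_order[0] == "c"
        assert set(ranking.ordered_targets[:2]) == {"a", "b"}

    def test_column_permutation_leaves_ranking_unchanged(self, q_fixture):
        r1 = rank_targets(q_fixture)
        r2 = rank_targets(q_fixture[list(reversed(q_fixture.columns))])
        assert r1.ordered_targets[2:] == r2.ordered_targets[2:]
        assert set(r1.ordered_targets[:2]) == set(r2.ordered_targets[:2])

    def test_matches_stepwise_oracle(self, q_fixture):
        ranking = rank_targets(q_fixture)
        expected_order, expected_exclusion = oracle.stepwise_ranking(
            as_dict_of_lists(q_fixture), list(q_fixture.columns)
        )
        assert ranking.exclusion_order == expected_exclusion
        assert ranking.ordered_targets == expected_order

    def test_top_pair_shares_rank_one(self, q_fixture):
        ranks = rank_targets(q_fixture).ranks
        assert ranks.iloc[0] == 1 and ranks.iloc[1] == 1 and ranks.iloc[2] == 3


class TestNormalizationFactors:
    def test_equal_targets_give_their_common_value(self):
        q = _q(a=[1.0, 0.5, 2.0], b=[1.0, 0.5, 2.0])
        nf = normalization_factors(q, ["a", "b"], 2)
        assert np.allclose(nf.to_numpy(), [1.0, 0.5, 2.0])

    def test_geometric_mean_of_one_and_four_is_two(self):
        q = _q(a=[1.0, 1.0, 1.0], b=[4.0, 1.0, 1.0])
        assert normalization_factors(q, ["a", "b"], 2).iloc[0] == pytest.approx(2.0)

    def test_matches_product_root_oracle(self, q_fixture):
        ordered = rank_targets(q_fixture).ordered_targets
        nf = normalization_factors(q_fixture, ordered, 3)
        d = as_dict_of_lists(q_fixture)
        for s in range(len(q_fixture)):
            assert nf.iloc[s] == pytest.approx(
                oracle.normalization_factor(d, ordered, 3, s), abs=1e-10
            )

    def test_out_of_range_n_raises(self, q_fixture):
        with pytest.raises(GeNormError):
            normalization_factors(q_fixture, list(q_fixture.columns), 1)


class TestVCurve:
    def test_identical_targets_give_zero_curve_and_two_references(self):
        base = [1.0, 2.0, 0.5, 1.5]
        q = _q(a=base, b=base, c=base, d=base)
        vc = v_curve(q, list(q.columns))
        assert np.allclose(vc.v.to_numpy(), 0.0)
        assert vc.optimal_n == 2
        assert vc.cutoff_reached

    def test_two_stable_references_suffice_for_designed_data(self):
        # V2/3 ~ sigma_third/3, so moderately unstable companions (0.3)
        # keep the designed answer at two references
        targets = [TargetSpec(f"stab{i}", 2.0, 20.0, biological_sd=0.05) for i in range(2)] + [
            TargetSpec(f"wob{i}", 2.0, 22.0, biological_sd=0.3) for i in range(3)
        ]
        design = CqDesign(targets=targets, groups=["g"], n_samples=10,
                          sample_content_sd=0.5, seed=9)
        cq, _ = generate_cq_dataset(design)
        q = cq_to_relative_quantity(cq, 2.0)
        ranking = rank_targets(q)
        vc = v_curve(q, ranking)
        assert set(ranking.ordered_targets[:2]) == {"stab0", "stab1"}
        assert vc.v.loc[2] < 0.15
        assert vc.optimal_n == 2

    def test_matches_direct_formula_oracle(self, q_fixture):
        ranking = rank_targets(q_fixture)
        vc = v_curve(q_fixture, ranking)
        expected = oracle.v_curve(as_dict_of_lists(q_fixture), ranking.ordered_targets)
        for n, v in expected.items():
            assert vc.v.loc[n] == pytest.approx(v, abs=1e-10)


class TestClassification:
    @pytest.mark.parametrize(
        "m, category", [(0.19, "very-high"), (0.49, "high"), (1.5, "low"), (0.2, "high"), (0.5, "low")]
    )
    def test_thresholds(self, m, category):
        assert classify_stability(m) == category

    def test_negative_m_raises(self):
        with pytest.raises(GeNormError):
            classify_stability(-0.1)


class TestScalingInvariance:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_arbitrary_positive_scalings_preserve_stability_outputs(self, seed):
        q = random_quantities(seed=seed)
        rng = np.random.default_rng(seed + 1)
        scaled = q.mul(rng.uniform(0.1, 10, size=len(q)), axis=0)
        scaled = scaled.mul(rng.uniform(0.1, 10, size=q.shape[1]), axis=1)
        m1, m2 = m_values(q), m_values(scaled)
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-9)
        assert rank_targets(q).ordered_targets == rank_targets(scaled).ordered_targets

    def test_power_of_two_scalings_are_bit_exact(self, q_fixture):
        rng = np.random.default_rng(0)
        row = np.exp2(rng.integers(-6, 7, size=len(q_fixture)).astype(float))
        col = np.exp2(rng.integers(-6, 7, size=q_fixture.shape[1]).astype(float))
        scaled = q_fixture.mul(row, axis=0).mul(col, axis=1)
        assert m_values(q_fixture).equals(m_values(scaled))
        vc1 = v_curve(q_fixture, list(q_fixture.columns))
        vc2 = v_curve(scaled, list(scaled.columns))
        assert vc1.v.equals(vc2.v)
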