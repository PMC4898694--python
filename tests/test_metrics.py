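import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from matesim.couples_data import SynthConfig, synth_couples
from matesim.metrics import (
    bootstrap_summary,
    euclidean_distance,
    fulfillment_records,
    mate_value,
    mean_absolute_distance,
    model_fulfillment_summary,
    mv_fulfillment_correlation,
    relative_fulfillment,
    rescale_dimensions,
)


class TestEuclideanDistance:
    def test_hand_values(self):
        assert euclidean_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert euclidean_distance([0, 0], [3, 4]) == 5.0
        assert euclidean_distance(np.zeros(23), np.ones(23)) == pytest.approx(
            np.sqrt(23)
        )

    def test_errors_name_offending_dimensions(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match=r"\[1\]"):
            euclidean_distance([1.0, np.nan], [1.0, 2.0])

    @given(
        a=arrays(float, (8,), elements=st.floats(-10, 10)),
        b=arrays(float, (8,), elements=st.floats(-10, 10)),
        c=arrays(float, (8,), elements=st.floats(-10, 10)),
    )
    def test_metric_axioms(self, a, b, c):
        dab = euclidean_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(euclidean_distance(b, a))
        assert dab <= euclidean_distance(a, c) + euclidean_distance(c, b) + 1e-9


class TestRescale:
    def test_identity_and_known_value(self):
        assert rescale_dimensions(3.7, 23, 23) == 3.7
        assert rescale_dimensions(10.0, 40, 23) == pytest.approx(7.583, abs=0.001)

    @given(
        d=st.floats(0, 100),
        ks=st.tuples(st.integers(1, 100), st.integers(1, 100)),
    )
    def test_involution(self, d, ks):
        a, b = ks
        assert rescale_dimensions(rescale_dimensions(d, a, b), b, a) == pytest.approx(
            d, rel=1e-12, abs=1e-12
        )


class TestRelativeFulfillment:
    def test_share_of_further_alternatives(self):
        ideal = [0.0, 0.0]
        partner = [1.0, 0.0]  # distance 1
        alts = [[2.0, 0.0], [3.0, 0.0], [0.5, 0.0]]
        assert relative_fulfillment(ideal, partner, alts) == pytest.approx(200 / 3)

    def test_nearest_partner_scores_100(self):
        assert relative_fulfillment([0, 0], [1, 0], [[5, 0], [0, 2]]) == 100.0

    def test_equidistant_alternative_not_counted_as_further(self):
        ideal = [0.0]
        partner = [2.0]
        alts = [[2.0], [-2.0], [3.0], [1.0]]  # two ties, one further, one closer
        assert relative_fulfillment(ideal, partner, alts) == 25.0


class TestMateValue:
    def test_zero_distance_is_sample_maximum(self, rng):
        ideals = rng.uniform(1, 7, (20, 5))
        center = ideals.mean(axis=0)
        best = mate_value(center, ideals)
        other = mate_value(center + 1.0, ideals)
        assert best == 0.0 and best > other

    def test_transforms_agree_on_ranking(self, rng):
        ideals = rng.uniform(1, 7, (10, 4))
        selfs = rng.uniform(1, 7, (15, 4))
        neg = [mate_value(s, ideals, "negate") for s in selfs]
        rec = [mate_value(s, ideals, "reciprocal") for s in selfs]
        assert np.array_equal(np.argsort(neg), np.argsort(rec))


def _toy_table():
    """Two couples in 2 dimensions with distances checkable by hand."""
    rows = [
        # couple A: female ideal (1,1), partner male at (1,1) -> distance 0
        dict(couple_id="A", participant_id="f1", sex="female",
             ideal_1=1.0, ideal_2=1.0, partner_1=1.0, partner_2=1.0,
             self_1=2.0, self_2=2.0),
        dict(couple_id="A", participant_id="m1", sex="male",
             ideal_1=2.0, ideal_2=2.0, partner_1=5.0, partner_2=6.0,
             self_1=1.0, self_2=1.0),
        # couple B: female ideal (4,4), partner male at (7,7)
        dict(couple_id="B", participant_id="f2", sex="female",
             ideal_1=4.0, ideal_2=4.0, partner_1=7.0, partner_2=7.0,
             self_1=5.0, self_2=6.0),
        dict(couple_id="B", participant_id="m2", sex="male",
             ideal_1=7.0, ideal_2=7.0, partner_1=6.0, partner_2=6.0,
             self_1=7.0, self_2=7.0),
    ]
    return pd.DataFrame(rows)


class TestFulfillmentRecords:
    def test_absolute_distances_by_hand(self):
        recs = fulfillment_records(_toy_table()).set_index("participant_id")
        assert recs.loc["f1", "absolute_distance"] == 0.0
        assert recs.loc["f2", "absolute_distance"] == pytest.approx(np.sqrt(18))
        assert recs.loc["m1", "absolute_distance"] == pytest.approx(5.0)

    def test_relative_percentiles_by_enumeration(self):
        recs = fulfillment_records(_toy_table()).set_index("participant_id")
        # f1's alternatives: male described at (7,7); own partner at (1,1)
        assert recs.loc["f1", "relative_percentile"] == 100.0
        # f2: own partner (7,7) at sqrt(18); alternative (1,1) at sqrt(18) tie
        assert recs.loc["f2", "relative_percentile"] == 0.0

    def test_mate_value_uses_opposite_sex_mean_ideal(self):
        recs = fulfillment_records(_toy_table()).set_index("participant_id")
        # mean male ideal = (4.5, 4.5); f1 self = (2,2)
        assert recs.loc["f1", "mate_value"] == pytest.approx(-np.sqrt(12.5))

    def test_rescaling_applies_to_absolute_only(self):
        plain = fulfillment_records(_toy_table())
        scaled = fulfillment_records(_toy_table(), rescale_to=8)
        np.testing.assert_allclose(
            scaled["absolute_distance"], plain["absolute_distance"] * 2.0
        )
        np.testing.assert_allclose(
            scaled["relative_percentile"], plain["relative_percentile"]
        )

    def test_random_pairing_null_is_fifty_percent(self, rng):
        # after shuffling partner descriptions within sex, the own partner is
        # exchangeable with every alternative: mean percentile sits at 50
        cfg = SynthConfig(n_couples=150, k_dims=6, match_noise_sd=1.0, seed=11)
        table = synth_couples(cfg)
        partner_cols = [c for c in table.columns if c.startswith("partner_")]
        for s in ("female", "male"):
            rows = table.index[table.sex == s].to_numpy()
            table.loc[rows, partner_cols] = (
                table.loc[rng.permutation(rows), partner_cols].to_numpy()
            )
        recs = fulfillment_records(table)
        assert abs(recs["relative_percentile"].mean() - 50.0) < 3.5


class TestCorrelation:
    def test_perfect_linear_dependence(self):
        recs = pd.DataFrame(
            {"mate_value": [-1.0, -2.0, -3.0, -4.0],
             "absolute_distance": [1.0, 2.0, 3.0, 4.0]}
        )
        assert mv_fulfillment_correlation(recs) == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        recs = pd.DataFrame(
            {"mate_value": rng.normal(size=4000),
             "absolute_distance": rng.normal(size=4000)}
        )
        assert abs(mv_fulfillment_correlation(recs)) < 0.05

    def test_zero_variance_flagged(self):
        recs = pd.DataFrame(
            {"mate_value": [1.0, 1.0, 1.0], "absolute_distance": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            mv_fulfillment_correlation(recs)


class TestBootstrap:
    def test_constant_statistic_zero_width(self, rng):
        table = _toy_table()
        point, ci = bootstrap_summary(table, lambda t: 3.25, 200, rng)
        assert point == 3.25 and ci == (3.25, 3.25)

    def test_seeded_bootstrap_reproducible(self):
        table = synth_couples(SynthConfig(n_couples=20, k_dims=3, seed=2))
        a = bootstrap_summary(table, mean_absolute_distance, 100,
                              np.random.default_rng(5))
        b = bootstrap_summary(table, mean_absolute_distance, 100,
                              np.random.default_rng(5))
        assert a == b

    def test_zero_replicates_gives_point_only(self, rng):
        point, ci = bootstrap_summary(_toy_table(), mean_absolute_distance, 0, rng)
        assert ci is None and point > 0

    def test_ci_width_shrinks_with_sample_size(self):
        # CLT rate: quadrupling the couples should roughly halve the CI
        widths = []
        for n in (50, 200):
            table = synth_couples(SynthConfig(n_couples=n, k_dims=4, seed=8))
            _, ci = bootstrap_summary(
                table, mean_absolute_distance, 400, np.random.default_rng(1)
            )
            widths.append(ci[1] - ci[0])
        assert 1.4 < widths[0] / widths[1] < 2.9


class TestModelSummary:
    def test_identical_runs_zero_width_ci(self):
        table = synth_couples(SynthConfig(n_couples=30, k_dims=4, seed=3))
        mean, ci, vals = model_fulfillment_summary([table, table], "absolute")
        assert ci[0] == pytest.approx(ci[1]) == pytest.approx(mean)
        assert len(vals) == 2

    def test_empty_runs_are_excluded(self):
        table = synth_couples(SynthConfig(n_couples=30, k_dims=4, seed=3))
        empty = table.iloc[:0]
        mean, _, vals = model_fulfillment_summary(
            [table, empty, table], "relative"
        )
        assert len(vals) == 2
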