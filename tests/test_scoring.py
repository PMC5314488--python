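"""Aesthetics index scoring, auditor combination and neighbourhood ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urbanaudit.instrument import WeightVector
from urbanaudit.scoring import (
    ObservationMatrix,
    ScoreRangeWarning,
    aesthetics_score,
    combine_auditors,
    neighbourhood_mean,
    rank_neighbourhoods,
    read_observations_csv,
    score_locations,
    write_observations_csv,
)


def make_obs(values, items, neighbourhoods=None, auditor="a1"):
    data = pd.DataFrame(values, columns=list(items))
    data.index = [f"loc{i}" for i in range(len(data))]
    nb = neighbourhoods or ["nbh"] * len(data)
    meta = pd.DataFrame(
        {"neighbourhood_id": nb, "auditor_id": auditor, "date": "2020-01-01"},
        index=data.index,
    )
    return ObservationMatrix(data, meta)


UNIFORM = WeightVector(tuple("abcde"), np.full(5, 0.2))


class TestAestheticsScore:
    def test_constant_response_gives_that_constant_in_both_modes(self):
        x = np.full(5, 3.0)
        for mode in ("literal", "renormalized"):
            assert aesthetics_score(x, UNIFORM, mode=mode) == pytest.approx(3.0)

    def test_maximal_response_with_normalized_weights_gives_five(
        self, printed_mean_weights
    ):
        w = printed_mean_weights
        wn = WeightVector(w.item_ids, w.weights / w.weights.sum())
        assert aesthetics_score(np.full(10, 5.0), wn) == pytest.approx(5.0)

    def test_printed_weights_na_furniture_overflows_literal_mode(
        self, printed_mean_weights
    ):
        """The worked overflow case: x=5 on 8 applicable items, the two
        outdoor-furniture items (weights 0.034 and 0.042) not applicable.
        Literal mode gives (10/8)*5*0.922 = 5.7625 and warns; the
        renormalized mode stays at the 5.0 ceiling."""
        ids = list(printed_mean_weights.item_ids)
        x = np.full(10, 5.0)
        x[ids.index("furniture_presence")] = np.nan
        x[ids.index("furniture_quality")] = np.nan
        with pytest.warns(ScoreRangeWarning):
            s = aesthetics_score(x, printed_mean_weights, mode="literal")
        assert s == pytest.approx(5.7625, abs=1e-12)
        s2 = aesthetics_score(x, printed_mean_weights, mode="renormalized")
        assert s2 == pytest.approx(5.0, abs=1e-12)

    def test_all_not_applicable_rejected(self):
        with pytest.raises(ValueError, match="NOT_APPLICABLE"):
            aesthetics_score(np.full(5, np.nan), UNIFORM)

    @given(
        st.lists(
            st.one_of(st.sampled_from([1.0, 2.0, 3.0, 4.0, 5.0]), st.just(np.nan)),
            min_size=5,
            max_size=5,
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_renormalized_score_is_convex_combination(self, vals):
        x = np.array(vals)
        if not np.isfinite(x).any():
            return
        s = aesthetics_score(x, UNIFORM, mode="renormalized")
        finite = x[np.isfinite(x)]
        assert finite.min() - 1e-12 <= s <= finite.max() + 1e-12

    def test_modes_agree_when_all_applicable(self, rng):
        w = rng.dirichlet(np.ones(5))
        wv = WeightVector(tuple("abcde"), w)
        x = rng.integers(1, 6, size=5).astype(float)
        lit = aesthetics_score(x, wv, mode="literal")
        ren = aesthetics_score(x, wv, mode="renormalized")
        assert lit == pytest.approx(ren, abs=1e-12)


class TestCombineAuditors:
    def test_identical_auditors_pass_through(self):
        a = make_obs([[1, 2, 3, 4, 5]], "abcde")
        b = make_obs([[1, 2, 3, 4, 5]], "abcde", auditor="a2")
        out = combine_auditors([a, b])
        np.testing.assert_array_equal(out.data.to_numpy(), a.data.to_numpy())

    def test_mean_of_two_and_four_is_three(self):
        a = make_obs([[2, 2, 2, 2, 2]], "abcde")
        b = make_obs([[4, 4, 4, 4, 4]], "abcde", auditor="a2")
        out = combine_auditors([a, b])
        assert (out.data.to_numpy() == 3.0).all()

    def test_item_applicable_for_one_auditor_keeps_that_value(self):
        a = make_obs([[4, 3, 3, 3, 3]], "abcde")
        b = make_obs([[np.nan, 3, 3, 3, 3]], "abcde", auditor="a2")
        out = combine_auditors([a, b])
        assert out.data.iloc[0, 0] == pytest.approx(4.0)
        # item is NA only if all auditors marked it so
        assert out.data.notna().iloc[0].all()

    def test_disjoint_location_sets_rejected(self):
        a = make_obs([[1, 2, 3, 4, 5]], "abcde")
        b = make_obs([[1, 2, 3, 4, 5], [1, 1, 1, 1, 1]], "abcde")
        with pytest.raises(ValueError, match="identical location sets"):
            combine_auditors([a, b])

    def test_per_auditor_policy_returns_inputs(self):
        a = make_obs([[1, 2, 3, 4, 5]], "abcde")
        b = make_obs([[2, 2, 3, 4, 4]], "abcde", auditor="a2")
        out = combine_auditors([a, b], policy="per_auditor")
        assert out == [a, b]


class TestNeighbourhoodMean:
    def test_two_scores_average(self):
        s = pd.Series([2.0, 4.0], index=["l1", "l2"])
        nb = pd.Series(["n", "n"], index=s.index)
        ss = neighbourhood_mean(s, nb)
        assert ss.neighbourhood_scores["n"] == pytest.approx(3.0)
        assert ss.n["n"] == 2

    def test_single_location_is_identity(self):
        s = pd.Series([3.7], index=["l1"])
        ss = neighbourhood_mean(s, pd.Series(["n"], index=s.index))
        assert ss.neighbourhood_scores["n"] == pytest.approx(3.7)

    def test_matches_brute_force_sum(self, rng):
        s = pd.Series(rng.uniform(1, 5, 5), index=[f"l{i}" for i in range(5)])
        nb = pd.Series(["n"] * 5, index=s.index)
        ss = neighbourhood_mean(s, nb)
        brute = sum(s.tolist()) / 5
        assert ss.neighbourhood_scores["n"] == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_location_order(self, rng):
        s = pd.Series(rng.uniform(1, 5, 6), index=[f"l{i}" for i in range(6)])
        nb = pd.Series(["a", "b"] * 3, index=s.index)
        ss1 = neighbourhood_mean(s, nb)
        perm = rng.permutation(6)
        ss2 = neighbourhood_mean(s.iloc[perm], nb.iloc[perm])
        pd.testing.assert_series_equal(
            ss1.neighbourhood_scores.sort_index(), ss2.neighbourhood_scores.sort_index()
        )


class TestRanking:
    def test_season_one_extremes(self, season_scores):
        """Lowest-ranked is Carlington (2.92), highest New Barrhaven (4.29)."""
        s = season_scores.set_index("neighbourhood_id")["qs_2011"]
        ss = neighbourhood_mean(s, pd.Series(s.index, index=s.index))
        ranked = rank_neighbourhoods(ss)
        assert ranked.iloc[0]["neighbourhood_id"] == "Carlington"
        assert ranked.iloc[0]["q_s"] == pytest.approx(2.92)
        assert ranked.iloc[-1]["neighbourhood_id"] == "New Barrhaven-Stonebridge"
        assert ranked.iloc[-1]["q_s"] == pytest.approx(4.29)

    def test_all_equal_scores_flag_ties_and_keep_id_order(self):
        s = pd.Series([3.0, 3.0, 3.0], index=["l1", "l2", "l3"])
        nb = pd.Series(["c", "a", "b"], index=s.index)
        ranked = rank_neighbourhoods(neighbourhood_mean(s, nb))
        assert list(ranked["neighbourhood_id"]) == ["a", "b", "c"]
        assert ranked["tied"].all()

    def test_matches_sort_oracle_on_distinct_values(self):
        s = pd.Series([4.1, 2.2, 3.3], index=["l1", "l2", "l3"])
        nb = pd.Series(["x", "y", "z"], index=s.index)
        ranked = rank_neighbourhoods(neighbourhood_mean(s, nb))
        oracle = sorted(zip([4.1, 2.2, 3.3], ["x", "y", "z"]))
        assert list(ranked["neighbourhood_id"]) == [n for _, n in oracle]


class TestValidationAndIO:
    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            make_obs([[0, 2, 3, 4, 5]], "abcde")

    def test_fully_na_row_rejected(self):
        with pytest.raises(ValueError, match="every item"):
            make_obs([[np.nan] * 5], "abcde")

    def test_long_csv_roundtrip(self, tmp_path):
        obs = make_obs([[1, np.nan, 3, 4, 5], [2, 2, 2, 2, 2]], "abcde")
        write_observations_csv(tmp_path / "obs.csv", obs)
        back = read_observations_csv(tmp_path / "obs.csv", item_ids="abcde")
        pd.testing.assert_frame_equal(back.data, obs.data, check_names=False)

    def test_score_locations_requires_matching_items(self):
        obs = make_obs([[1, 2, 3, 4, 5]], "abcde")
        wrong = WeightVector(tuple("abcdf"), np.full(5, 0.2))
        with pytest.raises(ValueError, match="match"):
            score_locations(obs, wrong)
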