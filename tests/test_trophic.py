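"""Isotope trophic-level scoring: binning formula, bounds, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oribatrait as ot
from oribatrait.trophic import (
    SCORE_MAX,
    TROPHIC_SPACING,
    IsotopeTable,
    assign_trophic_levels,
    combine_species_scores,
    normalize_baseline,
    species_habitat_means,
)


def _table(rows):
    return IsotopeTable(pd.DataFrame(rows))


def _row(sp, hab, d13c, d15n, b13=0.0, b15=0.0):
    return {
        "species": sp,
        "habitat": hab,
        "d13C": d13c,
        "d15N": d15n,
        "baseline_d13C": b13,
        "baseline_d15N": b15,
    }


class TestNormalize:
    def test_subtracts_baseline(self):
        t = _table([_row("a", "h", -25.0, 8.4, b13=-26.0, b15=5.0)])
        norm = normalize_baseline(t)
        assert norm.data["d15N"].iloc[0] == pytest.approx(3.4)
        assert norm.data["d13C"].iloc[0] == pytest.approx(1.0)

    def test_zero_baseline_is_identity(self):
        t = _table([_row("a", "h", -25.0, 4.0)])
        norm = normalize_baseline(t)
        assert norm.data["d15N"].iloc[0] == 4.0

    def test_double_normalization_guarded(self):
        t = normalize_baseline(_table([_row("a", "h", -25.0, 4.0)]))
        with pytest.raises(ValueError, match="already"):
            normalize_baseline(t)

    def test_missing_baseline_names_habitat(self):
        t = _table([_row("a", "bog", -25.0, 4.0, b15=np.nan)])
        with pytest.raises(ValueError, match="bog"):
            normalize_baseline(t)


class TestSpeciesHabitatMeans:
    def test_single_record_is_itself(self):
        t = normalize_baseline(_table([_row("a", "h", -25.0, 4.0)]))
        m = species_habitat_means(t)
        assert m["d15N"].iloc[0] == 4.0 and m["n"].iloc[0] == 1

    def test_two_records_average(self):
        t = normalize_baseline(
            _table([_row("a", "h", -25.0, 2.0), _row("a", "h", -25.0, 4.0)])
        )
        assert species_habitat_means(t)["d15N"].iloc[0] == pytest.approx(3.0)

    def test_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(0)
        rows = [
            _row(f"s{rng.integers(5)}", f"h{rng.integers(3)}",
                 rng.normal(), rng.normal())
            for _ in range(60)
        ]
        t = normalize_baseline(_table(rows))
        got = species_habitat_means(t).set_index(["species", "habitat"])["d15N"]
        # brute-force oracle: plain accumulation loop
        acc: dict = {}
        for r in t.data.itertuples():
            acc.setdefault((r.species, r.habitat), []).append(r.d15N)
        for key, vals in acc.items():
            assert got[key] == pytest.approx(sum(vals) / len(vals))

    def test_requires_normalized(self):
        with pytest.raises(ValueError, match="normalize"):
            species_habitat_means(_table([_row("a", "h", -25.0, 4.0)]))


class TestAssignTrophicLevels:
    def test_single_species_anchored_at_zero(self):
        out = assign_trophic_levels(pd.Series({"a": 12.3}))
        assert out["score"].iloc[0] == 0.0 and out["group"].iloc[0] == 0

    def test_binning_formula_worked_values(self):
        # direct evaluation of g = min(3, floor(d/3.4)),
        # r = min(0.99, (d - 3.4 g)/3.4)
        y = pd.Series({"a": 0.0, "b": 1.0, "c": 3.5, "d": 7.0, "e": 10.5})
        out = assign_trophic_levels(y)
        expected = {
            "a": 0.0,
            "b": 1.0 / 3.4,
            "c": 1 + 0.1 / 3.4,
            "d": 2 + 0.2 / 3.4,
            "e": 3 + 0.3 / 3.4,
        }
        for sp, val in expected.items():
            assert out.loc[sp, "score"] == pytest.approx(val, abs=1e-9)

    def test_far_beyond_fourth_group_caps_at_score_max(self):
        out = assign_trophic_levels(pd.Series({"lo": 0.0, "hi": 20.0}))
        assert out.loc["hi", "score"] == SCORE_MAX
        assert out.loc["hi", "group"] == 3

    def test_exact_group_width_moves_one_level(self):
        out = assign_trophic_levels(pd.Series({"a": 0.0, "b": TROPHIC_SPACING}))
        assert out.loc["b", "group"] == 1
        assert out.loc["b", "score"] == pytest.approx(1.0)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            assign_trophic_levels(pd.Series(dtype=float))

    def test_rank_decimal_preserves_order(self):
        y = pd.Series({"a": 0.0, "b": 0.5, "c": 1.0, "d": 4.0})
        out = assign_trophic_levels(y, decimal="rank")
        ordered = out.sort_values("d15N")["score"].to_numpy()
        assert np.all(np.diff(ordered) >= 0)
        assert out["score"].between(0, SCORE_MAX).all()

    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity_hold_for_any_community(self, values):
        y = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
        out = assign_trophic_levels(y)
        assert out["score"].between(0.0, SCORE_MAX).all()
        ordered = out.sort_values("d15N")["score"].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)
        # ties score equally
        dup = out.groupby("d15N")["score"].nunique()
        assert (dup == 1).all()

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_invariance(self, shift):
        y = pd.Series({"a": 0.0, "b": 2.2, "c": 7.9})
        base = assign_trophic_levels(y)["score"]
        moved = assign_trophic_levels(y + shift)["score"]
        np.testing.assert_allclose(moved, base, atol=1e-9)


class TestCombineScores:
    def test_single_habitat_unchanged(self):
        df = pd.DataFrame(
            {"species": ["a"], "habitat": ["h"], "score": [1.7], "group": [1]}
        )
        out = combine_species_scores(df)
        assert out["score"].iloc[0] == 1.7 and out["group"].iloc[0] == 1

    def test_mean_across_habitats_and_disagreement_flag(self):
        df = pd.DataFrame(
            {
                "species": ["a", "a", "b", "b"],
                "habitat": ["h1", "h2", "h1", "h2"],
                "score": [1.2, 2.2, 0.4, 0.6],
                "group": [1, 2, 0, 0],
            }
        )
        out = combine_species_scores(df).set_index("species")
        assert out.loc["a", "score"] == pytest.approx(1.7)
        assert bool(out.loc["a", "group_disagreement"])
        assert not bool(out.loc["b", "group_disagreement"])
        assert out.loc["b", "score"] == pytest.approx(0.5)

    def test_group_names_attached(self):
        df = pd.DataFrame(
            {"species": ["a"], "habitat": ["h"], "score": [3.2], "group": [3]}
        )
        assert (
            combine_species_scores(df)["group_name"].iloc[0] == "predator/scavenger"
        )


class TestFullScoring:
    def test_noiseless_multi_habitat_recovery(self):
        # every habitat contains the anchor species at true level 0, so the
        # continuous score reproduces the true level exactly
        from oribatrait.synthetic_data import CommunitySpec, simulate_isotope_communities

        tls = {"anchor": 0.0, "p1": 1.25, "p2": 2.5, "pred": 3.75}
        spec = CommunitySpec(
            tls,
            {f"h{i}": (-25.0 + i, float(i)) for i in range(4)},
            {f"h{i}": list(tls) for i in range(4)},
            noise_sd=0.0,
        )
        table = simulate_isotope_communities(spec, seed=0)
        scores = ot.score_isotope_table(table).set_index("species")
        for sp, tl in tls.items():
            assert scores.loc[sp, "score"] == pytest.approx(tl, abs=0.01)
        assert (scores["n_habitats"] == 4).all()
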