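"""Generators: determinism, Yule waiting-time theory, BM covariance structure."""

import numpy as np
import pandas as pd
import pytest

import oribatrait as ot
from oribatrait.synthetic_data import (
    CommunitySpec,
    default_community_spec,
    simulate_isotope_communities,
)
from oribatrait.trophic import TROPHIC_SPACING


class TestYule:
    def test_two_tips_is_a_cherry(self):
        t = ot.simulate_yule(2, seed=0)
        assert t.n_tips == 2 and t.children.shape == (1, 2)

    def test_same_seed_same_newick(self):
        a = ot.simulate_yule(30, root_age=100.0, seed=42).to_newick()
        b = ot.simulate_yule(30, root_age=100.0, seed=42).to_newick()
        assert a == b

    def test_different_seed_differs(self):
        a = ot.simulate_yule(30, root_age=100.0, seed=1).to_newick()
        b = ot.simulate_yule(30, root_age=100.0, seed=2).to_newick()
        assert a != b

    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError):
            ot.simulate_yule(1, seed=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_invariants_hold_for_all_seeds(self, seed):
        t = ot.simulate_yule(40, root_age=400.0, seed=seed)
        assert t.is_ultrametric()
        assert t.root_age == pytest.approx(400.0)
        assert np.all(t.blen[: t.n_tips] > 0)

    def test_root_age_matches_pure_birth_theory(self):
        # Under a pure-birth process at rate b, the time from 2 lineages to
        # n (plus the exponential tail at rate b*n) has mean
        # (1/b) * sum_{k=2..n} 1/k and matching variance of the sum of
        # independent exponentials; check the unscaled root age to 3 SE.
        b, n, reps = 0.7, 8, 2000
        expected = sum(1.0 / k for k in range(2, n + 1)) / b
        var = sum(1.0 / k**2 for k in range(2, n + 1)) / b**2
        ages = [
            ot.simulate_yule(n, birth_rate=b, seed=s).root_age for s in range(reps)
        ]
        se = np.sqrt(var / reps)
        assert abs(np.mean(ages) - expected) < 3 * se


class TestBrownianMotion:
    def test_determinism(self, yule100):
        a = ot.simulate_bm(yule100, 1.0, seed=3)
        b = ot.simulate_bm(yule100, 1.0, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_vanishing_rate_collapses_to_root_state(self, yule100):
        x = ot.simulate_bm(yule100, 1e-12, root_state=5.0, seed=1)
        np.testing.assert_allclose(x.to_numpy(), 5.0, atol=1e-3)

    def test_rejects_nonpositive_rate(self, yule100):
        with pytest.raises(ValueError):
            ot.simulate_bm(yule100, 0.0, seed=1)

    def test_tip_covariance_matches_sigma2_vcv(self):
        # 5000 replicates on a fixed 5-tip tree: sample covariance of tip
        # vectors converges to sigma2 * C (BM theory)
        tree = ot.simulate_yule(5, root_age=1.0, seed=17)
        sigma2 = 1.0
        X = np.stack(
            [ot.simulate_bm(tree, sigma2, seed=s).to_numpy() for s in range(5000)]
        )
        S = np.cov(X.T)
        C = tree.vcv()
        # per-entry Monte-Carlo SE ~ sqrt((Cii Cjj + Cij^2)/N) <= 0.02
        assert np.max(np.abs(S - sigma2 * C)) < 0.08

    def test_mean_converges_to_root_state(self, yule100):
        means = [
            ot.simulate_bm(yule100, 1.0, root_state=2.5, seed=s).mean()
            for s in range(300)
        ]
        # replicate means are i.i.d. across seeds; 4-SE band
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 2.5) < 4 * se


class TestLambdaModel:
    def test_lambda_zero_tips_are_uncorrelated(self):
        tree = ot.simulate_yule(6, root_age=1.0, seed=4)
        X = np.stack(
            [ot.simulate_lambda(tree, 0.0, 1.0, seed=s).to_numpy() for s in range(4000)]
        )
        S = np.cov(X.T)
        off = S[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.08
        np.testing.assert_allclose(np.diag(S), 1.0, atol=0.12)

    def test_lambda_one_matches_bm_marginal(self):
        # same marginal law as BM at every tip: KS test on one tip over
        # 2000 replicates
        from scipy import stats

        tree = ot.simulate_yule(6, root_age=1.0, seed=4)
        a = np.array(
            [ot.simulate_lambda(tree, 1.0, 1.0, seed=s).iloc[0] for s in range(2000)]
        )
        b = np.array(
            [ot.simulate_bm(tree, 1.0, seed=10_000 + s).iloc[0] for s in range(2000)]
        )
        assert stats.ks_2samp(a, b).pvalue > 0.001


class TestCladeShift:
    def test_zero_offset_identical_to_bm(self, yule100):
        node = yule100.n_tips + 10
        a = ot.simulate_clade_shift(yule100, node, 0.0, 1.0, seed=9)
        b = ot.simulate_bm(yule100, 1.0, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_offset_at_root_shifts_every_tip(self, yule100):
        a = ot.simulate_clade_shift(yule100, yule100.root, 3.0, 1.0, seed=9)
        b = ot.simulate_bm(yule100, 1.0, root_state=3.0, seed=9)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_unknown_node(self, yule100):
        with pytest.raises(KeyError):
            ot.simulate_clade_shift(yule100, 10_000, 1.0, 1.0, seed=0)


class TestIsotopeCommunities:
    def _noiseless_spec(self):
        tls = {"a": 0.0, "b": 0.5, "c": 1.2, "d": 2.7, "e": 3.9}
        habs = {"h1": (-26.0, 2.0), "h2": (-24.0, -1.0)}
        members = {"h1": list(tls), "h2": list(tls)}
        return CommunitySpec(tls, habs, members, noise_sd=0.0)

    def test_determinism(self):
        spec = default_community_spec(seed=5)
        a = simulate_isotope_communities(spec, seed=6).data
        b = simulate_isotope_communities(spec, seed=6).data
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_recovery_of_integer_levels(self):
        spec = self._noiseless_spec()
        table = simulate_isotope_communities(spec, seed=0)
        scores = ot.score_isotope_table(table)
        got = scores.set_index("species")["group"].to_dict()
        assert got == {sp: int(tl) for sp, tl in spec.true_tl.items()}

    def test_d15n_encodes_trophic_spacing(self):
        spec = self._noiseless_spec()
        df = simulate_isotope_communities(spec, seed=0).data
        sub = df[df.habitat == "h1"].set_index("species")
        lift = sub["d15N"] - sub["baseline_d15N"]
        for sp, tl in spec.true_tl.items():
            assert lift[sp] == pytest.approx(TROPHIC_SPACING * tl)

    def test_study_scale_default(self):
        spec = default_community_spec(seed=1)
        table = simulate_isotope_communities(spec, seed=2)
        assert len(table.species) == 70
        assert len(table.habitats) == 4

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            CommunitySpec({}, {}, {})

    def test_true_levels_bounded(self):
        with pytest.raises(ValueError):
            CommunitySpec({"a": 4.5}, {"h": (0.0, 0.0)}, {"h": ["a"]})
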