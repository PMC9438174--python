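import numpy as np
import pytest

import mircascade as mc
from mircascade.interactions import InteractionPair

from conftest import make_profile


def pearson_bruteforce(x, y):
    """Definitional oracle: covariance over the product of standard deviations,
    p from the t-transform t = r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestPearsonWithP:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = mc.pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = mc.pearson_with_p(x, x)
        assert r == pytest.approx(1.0)

    def test_known_vectors(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r, p = mc.pearson_with_p(x, y)
        r_oracle, p_oracle = pearson_bruteforce(x, y)
        assert r == pytest.approx(0.822, abs=1e-3)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_definitional_oracle_on_random_pairs(self):
        rng = np.random.default_rng(101)
        for _ in range(100):
            n = rng.integers(3, 30)
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            r, p = mc.pearson_with_p(x, y)
            r_o, p_o = pearson_bruteforce(x, y)
            assert r == pytest.approx(r_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            mc.pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            mc.pearson_with_p([1.0, 2.0], [2.0, 1.0])


class TestClassifyProfile:
    def test_gene_up_mirna_down_is_profile1(self, days7):
        gene = make_profile("g", days7, 5 + 0.2 * days7)
        mirna = make_profile("m", days7, 8 - 0.1 * days7)
        assert mc.classify_profile(gene, mirna) == "profile1"

    def test_gene_down_mirna_up_is_profile2(self, days7):
        gene = make_profile("g", days7, 8 - 0.2 * days7)
        mirna = make_profile("m", days7, 5 + 0.3 * days7)
        assert mc.classify_profile(gene, mirna) == "profile2"

    def test_both_up_is_none(self, days7):
        gene = make_profile("g", days7, 5 + 0.2 * days7)
        mirna = make_profile("m", days7, 5 + 0.1 * days7)
        assert mc.classify_profile(gene, mirna) == "none"

    def test_noiseless_planted_profile1_always_classified(self, days7):
        # latent saturating curve, mirrored pair, no noise
        t = (days7 - days7[0]) / (days7[-1] - days7[0])
        f = 3 * (1 - np.exp(-3 * t))
        for base_g in (6.0, 9.0, 11.0):
            gene = make_profile("g", days7, base_g + f)
            mirna = make_profile("m", days7, 10.0 - f)
            assert mc.classify_profile(gene, mirna) == "profile1"


class TestScorePairs:
    def _profiles(self, days, spec):
        """spec: {tid: values}"""
        return {tid: make_profile(tid, days, vals) for tid, vals in spec.items()}

    def test_perfect_mirror_tops_ranking(self, days7):
        t = np.linspace(0, 1, 7)
        f = 3 * (1 - np.exp(-3 * t))
        rng = np.random.default_rng(2)
        gp = self._profiles(days7, {"g1": 8 + f, "g2": 8 + rng.standard_normal(7)})
        mp = self._profiles(days7, {"m1": 10 - f, "m2": 8 + rng.standard_normal(7)})
        pairs = [InteractionPair("m1", "g1", "high"), InteractionPair("m2", "g2", "high")]
        scores = mc.score_pairs(pairs, gp, mp)
        assert scores[0].gene_id == "g1"
        assert scores[0].pearson_r == pytest.approx(-1.0)
        assert scores[0].validated and scores[0].high_stringency
        assert scores[0].profile == "profile1"

    def test_moderate_negative_below_cut_not_high_stringency(self, days7):
        # analytic sample correlation exactly -0.5 -> excluded by the strict rule
        gp = self._profiles(days7[:3], {"g": [1.0, 2.0, 3.0]})
        mp = self._profiles(days7[:3], {"m": [5.0, 6.0, 4.0]})
        (score,) = mc.score_pairs(
            [InteractionPair("m", "g", "high")], gp, mp
        )
        assert score.pearson_r == pytest.approx(-0.5, abs=1e-12)
        assert score.validated  # sign rule still holds
        assert not score.high_stringency

    def test_invariant_to_per_transcript_constant_shift(self, days7):
        rng = np.random.default_rng(4)
        gvals = rng.standard_normal(7)
        mvals = rng.standard_normal(7)
        pairs = [InteractionPair("m", "g", "high")]
        base = mc.score_pairs(
            pairs, self._profiles(days7, {"g": gvals}), self._profiles(days7, {"m": mvals})
        )
        shifted = mc.score_pairs(
            pairs,
            self._profiles(days7, {"g": gvals + 5.5}),
            self._profiles(days7, {"m": mvals - 2.25}),
        )
        assert base[0].pearson_r == pytest.approx(shifted[0].pearson_r, abs=1e-12)

    def test_tie_break_is_lexicographic(self, days7):
        vals = np.linspace(0, 1, 7)
        gp = self._profiles(days7, {"gB": 1 + vals, "gA": 1 + vals})
        mp = self._profiles(days7, {"m1": 5 - vals, "m2": 5 - vals})
        pairs = [InteractionPair("m2", "gB", "high"), InteractionPair("m1", "gA", "high")]
        scores = mc.score_pairs(pairs, gp, mp)
        assert [(s.gene_id, s.mirna_id) for s in scores] == [("gA", "m1"), ("gB", "m2")]

    def test_mismatched_day_grids_name_the_pair(self, days7):
        gp = self._profiles(days7, {"g": np.arange(7.0)})
        mp = {"m": make_profile("m", [100.0, 101.0, 102.0], [1.0, 2.0, 3.0])}
        with pytest.raises(ValueError, match=r"\(m, g\)"):
            mc.score_pairs([InteractionPair("m", "g", "high")], gp, mp)

    def test_strong_negatives_occupy_top_ranks(self, days7):
        # 10 pairs with fixed latent day-curves of known correlation
        # {-0.9 x4, -0.3 x3, +0.6 x3}; sigma=0.1 noise resampled per run.
        rng = np.random.default_rng(77)
        u = rng.standard_normal(7)
        v = rng.standard_normal(7)
        u = (u - u.mean()) / u.std()
        v = v - v.mean() - u * (u * (v - v.mean())).sum() / (u**2).sum()
        v = v / v.std()
        rhos = [-0.9] * 4 + [-0.3] * 3 + [0.6] * 3
        strong = {f"g{i}" for i in range(4)}
        wins = 0
        n_runs = 500
        sim_rng = np.random.default_rng(20220902)
        for _ in range(n_runs):
            gp, mp, pairs = {}, {}, []
            for i, rho in enumerate(rhos):
                x = u + sim_rng.normal(0, 0.1, 7)
                y = rho * u + np.sqrt(1 - rho**2) * v + sim_rng.normal(0, 0.1, 7)
                gp[f"g{i}"] = make_profile(f"g{i}", days7, 8 + x)
                mp[f"m{i}"] = make_profile(f"m{i}", days7, 8 + y)
                pairs.append(InteractionPair(f"m{i}", f"g{i}", "high"))
            scores = mc.score_pairs(pairs, gp, mp)
            if {s.gene_id for s in scores[:4]} == strong:
                wins += 1
        assert wins / n_runs >= 0.95

    def test_bh_adjustment_is_monotone(self, days7):
        rng = np.random.default_rng(13)
        gp, mp, pairs = {}, {}, []
        for i in range(8):
            gp[f"g{i}"] = make_profile(f"g{i}", days7, rng.standard_normal(7))
            mp[f"m{i}"] = make_profile(f"m{i}", days7, rng.standard_normal(7))
            pairs.append(InteractionPair(f"m{i}", f"g{i}", "high"))
        scores = mc.score_pairs(pairs, gp, mp)
        assert all(s.p_adj >= s.p_value - 1e-15 for s in scores)


def test_kendall_alternative_statistic():
    tau, p = mc.ifc.kendall_with_p([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert tau == pytest.approx(-1.0)
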