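"""Within-subject inference against independent references."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg as sla
from scipy import stats as sst

from perturbfatigue import stats as pstats
from _oracles import anova_oracle_f


def random_cube(rng, n, shape):
    return rng.standard_normal((n, *shape))


class TestRmAnova:
    def test_zero_effect_when_all_levels_identical(self, rng):
        base = rng.standard_normal(8)[:, None, None]
        cube = np.broadcast_to(base, (8, 4, 2)).copy()
        for eff in pstats.rm_anova(cube):
            assert eff.F == pytest.approx(0.0, abs=1e-20)

    def test_subject_shift_invariance(self, rng):
        cube = random_cube(rng, 6, (3, 2))
        shifted = cube.copy()
        shifted[2] += 7.5
        f0 = [e.F for e in pstats.rm_anova(cube)]
        f1 = [e.F for e in pstats.rm_anova(shifted)]
        assert f0 == pytest.approx(f1, rel=1e-10)

    @pytest.mark.parametrize("shape", [(4,), (4, 2), (3, 2, 2)])
    def test_matches_projection_oracle(self, rng, shape):
        cube = random_cube(rng, 6, shape)
        ours = {e.name: e.F for e in pstats.rm_anova(cube)}
        theirs = anova_oracle_f(cube)
        assert ours.keys() == theirs.keys()
        for name in ours:
            assert ours[name] == pytest.approx(theirs[name], rel=1e-10)

    def test_matches_statsmodels_anovarm_two_way(self, rng):
        from statsmodels.stats.anova import AnovaRM

        cube = random_cube(rng, 10, (4, 2))
        rows = [
            (s, a, b, cube[s, a, b])
            for s in range(10) for a in range(4) for b in range(2)
        ]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "y"])
        ref = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        ours = {e.name: e for e in pstats.rm_anova(cube)}
        mapping = {"A": "f1", "B": "f2", "A:B": "f1:f2"}
        for ref_name, our_name in mapping.items():
            assert ours[our_name].F == pytest.approx(ref.loc[ref_name, "F Value"], rel=1e-8)
            assert ours[our_name].p_uncorrected == pytest.approx(
                ref.loc[ref_name, "Pr > F"], rel=1e-8, abs=1e-12
            )

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            pstats.rm_anova(np.ones((1, 3)))


def _cube_with_contrast_scores(M, l):
    """Build (n, l) data whose Helmert contrast scores equal M exactly."""
    C = sla.helmert(l, full=False)
    return M @ C


class TestEpsilonAndMauchly:
    def test_two_levels_epsilon_one_and_mauchly_vacuous(self, rng):
        cube = random_cube(rng, 8, (2,))
        assert pstats.gg_epsilon(cube, "f1") == 1.0
        assert pstats.mauchly(cube, "f1") == (1.0, 1.0)

    def test_spherical_scores_give_epsilon_one(self):
        n, l = 9, 4
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((n, l - 1)))
        M = q * np.sqrt(n - 1)  # sample covariance exactly I after centering? ensure mean 0
        M = M - M.mean(axis=0)
        # re-orthonormalise the centred scores
        q2, _ = np.linalg.qr(M)
        M = q2 * np.sqrt(n - 1)
        cube = _cube_with_contrast_scores(M, l)
        eps = pstats.gg_epsilon(cube, "f1")
        W, p = pstats.mauchly(cube, "f1")
        assert eps == pytest.approx(1.0, abs=1e-6)
        assert W == pytest.approx(1.0, abs=1e-6)
        assert p > 0.5

    def test_rank_one_covariance_hits_lower_bound(self):
        n, l = 12, 4
        v = np.linspace(-1, 1, n)
        w = np.array([1.0, 2.0, -1.0])
        M = np.outer(v, w)
        cube = _cube_with_contrast_scores(M, l)
        assert pstats.gg_epsilon(cube, "f1") == pytest.approx(1.0 / (l - 1), abs=1e-12)

    def test_mauchly_matches_direct_formula(self, rng):
        n, l = 12, 4
        cube = random_cube(rng, n, (l,))
        W, p = pstats.mauchly(cube, "f1")
        C = sla.helmert(l, full=False)
        scores = cube @ C.T
        S = np.cov(scores, rowvar=False)
        k = l - 1
        W_ref = np.linalg.det(S) / (np.trace(S) / k) ** k
        d = 1 - (2 * k * k + k + 2) / (6 * k * (n - 1))
        chi2 = -(n - 1) * d * np.log(W_ref)
        p_ref = sst.chi2.sf(chi2, k * (k + 1) // 2 - 1)
        assert W == pytest.approx(W_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_singular_covariance_skips_mauchly(self, rng):
        cube = random_cube(rng, 3, (4,))  # n - 1 < df
        W, p = pstats.mauchly(cube, "f1")
        assert np.isnan(W) and np.isnan(p)
        eff = next(e for e in pstats.rm_anova(cube) if e.name == "f1")
        assert eff.sphericity_applied  # GG applied unconditionally


class TestAdjustments:
    def test_bonferroni_examples(self):
        assert pstats.bonferroni([0.01, 0.03]) == pytest.approx([0.02, 0.06])
        assert pstats.bonferroni([0.9], n_tests=5) == [1.0]
        assert pstats.bonferroni([0.4]) == [0.4]

    def test_bhy_single_p_unchanged(self):
        adj, rej = pstats.bhy_fdr([0.03])
        assert adj == pytest.approx([0.03])
        assert rej == [True]

    def test_bhy_hand_example(self):
        # m=2, c(2)=1.5: adjusted [0.01*2*1.5/1, 0.04*2*1.5/2] -> [0.03, 0.06]
        adj, _ = pstats.bhy_fdr([0.01, 0.04])
        assert adj == pytest.approx([0.03, 0.06])

    def test_bhy_all_ones_rejects_nothing(self):
        _, rej = pstats.bhy_fdr([1.0] * 5)
        assert not any(rej)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_bhy_rejects_subset_of_bh(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, rej_bhy = pstats.bhy_fdr(pvals, q=0.05)
        rej_bh = multipletests(pvals, alpha=0.05, method="fdr_bh")[0]
        assert all(not y or b for y, b in zip(rej_bhy, rej_bh))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_bhy_adjusted_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj, _ = pstats.bhy_fdr(pvals)
        ref = multipletests(pvals, method="fdr_by")[1]
        assert adj == pytest.approx(list(ref), rel=1e-10, abs=1e-12)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pstats.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(0.0, abs=1e-30)

    def test_antisymmetric_under_negation(self, rng):
        x, y = rng.standard_normal((2, 20))
        assert pstats.pearson(x, -y).r == pytest.approx(-pstats.pearson(x, y).r)

    def test_matches_scipy(self, rng):
        x, y = rng.standard_normal((2, 15))
        res = pstats.pearson(x, y)
        ref = sst.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pstats.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_correlation_near_zero(self, rng):
        x = rng.standard_normal(4000)
        y = rng.permutation(x)
        assert abs(pstats.pearson(x, y).r) < 0.05


class TestCube:
    def test_casewise_deletion(self):
        rows = []
        for s in range(5):
            for q in range(1, 5):
                if s == 3 and q == 2:
                    continue  # incomplete subject
                rows.append((f"S{s}", q, float(s + q)))
        df = pd.DataFrame(rows, columns=["subject", "quarter", "value"])
        cube = pstats.WithinDesignCube.from_long(df, "subject", ["quarter"], "value")
        assert cube.values.shape == (4, 4)
        assert "S3" not in cube.subjects
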