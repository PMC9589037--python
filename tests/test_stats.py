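"""Box-cox, repeated-measures ANOVA, sphericity, family correction, post-hoc."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from taskconn import parcellation as pc
from taskconn import stats as st


@pytest.fixture(scope="module")
def tiny_pair():
    schema = pc.ParcellationSchema(
        roi_ids=(1, 2, 3, 4), network_of={1: "A", 2: "A", 3: "B", 4: "B"})
    pairs = pc.enumerate_pairs(schema, ["A", "B"])
    return next(p for p in pairs
                if (p.target_network, p.source_network) == ("A", "B"))


def table_from_cells(pair, cells, n_conn=None):
    """PairConditionTable whose connections all equal the given cell values."""
    n_conn = n_conn or pair.n_connections
    n, a, b = cells.shape
    values = np.repeat(cells[:, None, :, :], n_conn, axis=1)
    return st.PairConditionTable(pair=pair, values=values, transformed=values,
                                 participants=[f"p{i}" for i in range(n)])


class TestBoxCox:
    def test_lognormal_sample_fits_log_transform(self):
        v = np.exp(np.random.default_rng(0).standard_normal(10_000))
        fit, _ = st.boxcox_fit(v)
        assert abs(fit.lmbda) < 0.15
        assert fit.shift == 0.0

    def test_normal_positive_sample_fits_identity(self):
        v = np.random.default_rng(1).normal(10.0, 2.0, 10_000)
        fit, _ = st.boxcox_fit(v[v > 0])
        assert abs(fit.lmbda - 1.0) < 0.2

    def test_agrees_with_scipy_mle(self, rng):
        v = rng.gamma(2.0, 3.0, 5_000)
        fit, _ = st.boxcox_fit(v)
        _, lam_scipy = sps.boxcox(v)
        assert fit.lmbda == pytest.approx(lam_scipy, abs=1e-3)

    def test_unit_lambda_is_affine(self):
        v = np.array([1.0, 2.0, 5.0])
        out = st.boxcox_transform(v, st.BoxCoxResult(1.0, 0.0, 0.0))
        np.testing.assert_allclose(out, v - 1.0)

    def test_negative_values_get_positive_shift(self, rng):
        v = rng.normal(-1.0, 0.5, 500)
        fit, out = st.boxcox_fit(v)
        assert fit.shift > 0
        assert np.all(v + fit.shift > 0)
        assert np.all(np.diff(out[np.argsort(v)]) >= 0)  # monotone

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            st.boxcox_fit(np.ones(10))


class TestTwoWayRMANOVA:
    def test_matches_naive_sum_of_squares(self, rng):
        # independent decomposition computed with explicit loops
        y = rng.standard_normal((4, 3, 2))
        n, a, b = y.shape
        grand = y.mean()
        ss_ab = 0.0
        for f in range(a):
            for s in range(b):
                ss_ab += n * (y[:, f, s].mean() - y[:, f, :].mean()
                              - y[:, :, s].mean() + grand) ** 2
        ss_err = 0.0
        for i in range(n):
            for f in range(a):
                for s in range(b):
                    ss_err += (y[i, f, s]
                               - y[:, f, s].mean() - y[i, f, :].mean()
                               - y[i, :, s].mean() + y[:, f, :].mean()
                               + y[:, :, s].mean() + y[i].mean() - grand) ** 2
        f_expected = (ss_ab / ((a - 1) * (b - 1))) / (
            ss_err / ((a - 1) * (b - 1) * (n - 1)))
        f_stat, df1, df2, _ = st.two_way_rm_anova(y)
        assert f_stat == pytest.approx(f_expected, rel=1e-10)
        assert (df1, df2) == (2.0, 6.0)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.standard_normal((10, 8, 2))
        f_stat, df1, df2, _ = st.two_way_rm_anova(y)
        rows = [{"s": i, "f": f, "g": g, "y": y[i, f, g]}
                for i in range(10) for f in range(8) for g in range(2)]
        aov = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["f", "g"],
                          subject="s", detailed=True)
        inter = aov[aov["Source"].str.contains("\\*")].iloc[0]
        assert f_stat == pytest.approx(float(inter["F"]), rel=1e-10)
        assert (df1, df2) == (float(inter["ddof1"]), float(inter["ddof2"]))

    def test_needs_two_participants(self, rng):
        with pytest.raises(ValueError):
            st.two_way_rm_anova(rng.standard_normal((1, 8, 2)))


class TestRMANOVAPair:
    def test_location_invariance(self, tiny_pair, rng):
        cells = rng.standard_normal((8, 8, 2))
        r1 = st.rm_anova_pair(table_from_cells(tiny_pair, cells))
        r2 = st.rm_anova_pair(table_from_cells(tiny_pair, cells + 100.0))
        assert r1.F_interaction == pytest.approx(r2.F_interaction, rel=1e-9)

    def test_interaction_degrees_of_freedom(self, tiny_pair, rng):
        res = st.rm_anova_pair(table_from_cells(
            tiny_pair, rng.standard_normal((12, 8, 2))))
        assert (res.df_num, res.df_den) == (7.0, 77.0)
        assert 1 / 7 <= res.epsilon <= 1.0
        assert 0.0 <= res.p_uncorrected <= 1.0

    def test_planted_interaction_detected(self, tiny_pair, rng):
        cells = rng.standard_normal((15, 8, 2)) * 0.3
        cells[:, 2:4, 0] += 2.0  # strong word effect at frames 3-4
        res = st.rm_anova_pair(table_from_cells(tiny_pair, cells))
        assert res.p_uncorrected < 0.001
        assert np.argmin(res.posthoc) in (2, 3)

    def test_aggregation_modes_agree_on_f(self, tiny_pair, rng):
        table = table_from_cells(tiny_pair, rng.standard_normal((6, 8, 2)))
        f1 = st.rm_anova_pair(table, mode="lmm_then_anova").F_interaction
        f2 = st.rm_anova_pair(table, mode="participant_mean").F_interaction
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_needs_two_participants(self, tiny_pair, rng):
        with pytest.raises(ValueError):
            st.rm_anova_pair(table_from_cells(tiny_pair,
                                              rng.standard_normal((1, 8, 2))))


class TestSphericity:
    def test_compound_symmetry_gives_epsilon_near_one(self, rng):
        y = rng.standard_normal((200, 8)) + rng.standard_normal((200, 1))
        _, eps = st.mauchly_epsilon(y)
        assert eps > 0.9

    def test_rank_one_covariance_hits_lower_bound(self, rng):
        shared = rng.standard_normal((40, 1))
        y = shared * np.linspace(1, 3, 6) + 1e-4 * rng.standard_normal((40, 6))
        _, eps = st.mauchly_epsilon(y)
        assert eps < 1 / 5 + 0.05

    def test_epsilon_one_leaves_p_unchanged(self):
        f_stat, d1, d2 = 2.5, 7, 98
        assert sps.f.sf(f_stat, 1.0 * d1, 1.0 * d2) == sps.f.sf(f_stat, d1, d2)

    def test_matches_pingouin_epsilon(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.standard_normal((15, 5)) @ np.diag([1, 2, 0.5, 1, 3])
        _, eps = st.mauchly_epsilon(y)
        df = pd.DataFrame({"y": y.ravel(),
                           "c": np.tile(np.arange(5), 15),
                           "s": np.repeat(np.arange(15), 5)})
        eps_pg = pg.epsilon(df, dv="y", within="c", subject="s", correction="gg")
        assert eps == pytest.approx(float(eps_pg), abs=1e-10)

    def test_singular_covariance_warns_lower_bound(self, rng):
        y = rng.standard_normal((4, 8))  # fewer subjects than contrasts
        with pytest.warns(RuntimeWarning):
            _, eps = st.mauchly_epsilon(y)
        assert eps == pytest.approx(1 / 7)

    def test_huynh_feldt_at_least_gg(self):
        assert st.huynh_feldt(0.6, 15, 7) >= 0.6
        assert st.huynh_feldt(1.0, 15, 7) == 1.0


class TestFamilyCorrection:
    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(st.correct_family(np.ones(36)), 1.0)

    def test_family_of_one_unchanged(self):
        np.testing.assert_allclose(st.correct_family([0.01]), [0.01])

    def test_bonferroni_example(self):
        out = st.correct_family([0.001] + [0.5] * 35, method="bonferroni")
        assert out[0] == pytest.approx(0.036)

    def test_holm_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=36)
        ours = st.correct_family(p, method="holm")
        theirs = sm.multipletests(p, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_tukey_is_monotone_and_bounded(self, rng):
        p = np.sort(rng.uniform(0.0005, 0.9, 36))
        out = st.correct_family(p, method="tukey", df=98)
        assert np.all(np.diff(out) >= -1e-12)
        assert np.all(out >= p - 1e-12)
        assert np.all((out >= 0) & (out <= 1))

    def test_unknown_method_lists_options(self):
        with pytest.raises(ValueError, match="tukey"):
            st.correct_family([0.5], method="fdr_by_magic")

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            st.correct_family([0.5, 1.2])


class TestPosthoc:
    def test_identical_conditions_give_unit_pvalues(self, tiny_pair):
        cells = np.zeros((6, 8, 2))
        cells[:, :, :] = np.arange(6)[:, None, None]
        np.testing.assert_allclose(
            st.posthoc_frames(table_from_cells(tiny_pair, cells)), 1.0)

    def test_label_swap_symmetric(self, tiny_pair, rng):
        cells = rng.standard_normal((10, 8, 2))
        p1 = st.posthoc_frames(table_from_cells(tiny_pair, cells))
        p2 = st.posthoc_frames(table_from_cells(tiny_pair, cells[:, :, ::-1]))
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestMarginalMeans:
    def test_constant_input(self, tiny_pair):
        table = table_from_cells(tiny_pair, np.full((5, 8, 2), 3.5))
        mm = st.marginal_means(table)
        assert len(mm) == 16
        np.testing.assert_allclose(mm["mean"], 3.5)
        np.testing.assert_allclose(mm["dispersion"], 0.0)

    def test_sem_is_std_over_sqrt_n(self, tiny_pair, rng):
        table = table_from_cells(tiny_pair, rng.standard_normal((5, 8, 2)))
        mm_std = st.marginal_means(table, dispersion="std")
        mm_sem = st.marginal_means(table, dispersion="sem")
        n = table.values.shape[0] * table.values.shape[1]
        np.testing.assert_allclose(mm_sem["dispersion"],
                                   mm_std["dispersion"] / np.sqrt(n))

    def test_dispersion_factor_is_1_15(self, tiny_pair, rng):
        table = table_from_cells(tiny_pair, rng.standard_normal((5, 8, 2)))
        mm = st.marginal_means(table)
        vals = table.values[:, :, 0, 0].ravel()
        assert mm.iloc[0]["dispersion"] == pytest.approx(1.15 * vals.std(ddof=1))
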