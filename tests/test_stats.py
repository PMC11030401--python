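import itertools

import numpy as np
import pandas as pd
import pytest

from eventshift._dip import dip_statistic
from eventshift.layout import make_session_layout
from eventshift.stats import (
    bayes_anova_bf01,
    between_subject_variance,
    dip_test,
    dunn_pairwise,
    kruskal_wallis,
    paired_t,
    rm_anova,
    sample_non_boundaries,
    shapiro_gate,
    spearman,
)


class TestShapiroGate:
    def test_normal_sample(self, rng):
        rep = shapiro_gate(rng.standard_normal(100))
        assert rep["p"] > 0.001

    def test_exponential_sample(self, rng):
        rep = shapiro_gate(rng.exponential(size=100))
        assert rep["verdict"] == "non-normal"

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            shapiro_gate(np.array([1.0, 2.0]))


class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1..9 -> rank sums 6, 15, 24 -> H = 7.2
        rep = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6]),
                              np.array([7, 8, 9])])
        assert rep["statistic"] == pytest.approx(7.2)
        assert rep["eta2"] == pytest.approx((7.2 - 2) / 6)

    def test_within_group_order_invariance(self, rng):
        g = [rng.standard_normal(7) for _ in range(3)]
        h1 = kruskal_wallis(g)["statistic"]
        h2 = kruskal_wallis([np.flip(x) for x in g])["statistic"]
        assert h1 == pytest.approx(h2)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.ones(3), np.ones(3)])

    def test_matches_scipy_with_ties(self, rng):
        from scipy import stats as sps
        g = [rng.integers(0, 5, size=8).astype(float) for _ in range(3)]
        rep = kruskal_wallis(g)
        h, p = sps.kruskal(*g)
        assert rep["statistic"] == pytest.approx(h, abs=1e-12)
        assert rep["p"] == pytest.approx(p, abs=1e-12)


class TestDunn:
    def test_hand_computed_z(self):
        groups = [np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])]
        reps = dunn_pairwise(groups, ["w", "m", "s"])
        ws = next(r for r in reps if r["pair"] == ("w", "s"))
        assert ws["statistic"] == pytest.approx(-6 / np.sqrt(5))

    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        reps = dunn_pairwise([g, g])
        assert reps[0]["statistic"] == pytest.approx(0.0)
        assert reps[0]["p_corrected"] == 1.0

    def test_corrected_p_capped(self, rng):
        reps = dunn_pairwise([rng.standard_normal(4) for _ in range(4)])
        assert all(r["p_corrected"] <= 1.0 for r in reps)

    def test_matches_brute_force_ranks(self, rng):
        # independent re-derivation from pooled average ranks, n <= 12
        groups = [rng.integers(0, 6, size=4).astype(float) for _ in range(3)]
        pooled = np.concatenate(groups)
        order = pooled.argsort(kind="stable")
        ranks = np.empty(pooled.size)
        sv = pooled[order]
        i = 0
        while i < pooled.size:
            j = i
            while j + 1 < pooled.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        mr = [ranks[k * 4 : (k + 1) * 4].mean() for k in range(3)]
        n = pooled.size
        _, t = np.unique(pooled, return_counts=True)
        var = n * (n + 1) / 12 - np.sum(t**3 - t) / (12 * (n - 1))
        expected_z01 = (mr[0] - mr[1]) / np.sqrt(var * (1 / 4 + 1 / 4))
        reps = dunn_pairwise(groups)
        z01 = next(r for r in reps if r["pair"] == ("group0", "group1"))
        assert z01["statistic"] == pytest.approx(expected_z01, abs=1e-12)


class TestSpearman:
    def test_monotone(self):
        rep = spearman(np.arange(10.0), np.arange(10.0) ** 3)
        assert rep["rho"] == pytest.approx(1.0)

    def test_reversed(self):
        rep = spearman(np.arange(10.0), -np.arange(10.0))
        assert rep["rho"] == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))

    def test_ties_match_rank_formula(self, rng):
        x = rng.integers(0, 4, size=12).astype(float)
        y = rng.integers(0, 4, size=12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            pytest.skip("degenerate draw")
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)["rho"] == pytest.approx(expected, abs=1e-12)


class TestBetweenSubjectVariance:
    @staticmethod
    def _table(values):
        rows = []
        for s, vals in enumerate(values):
            for b, v in enumerate(vals):
                rows.append({"boundary_id": b, "level": "1", "subject": s,
                             "cbc": v})
        return pd.DataFrame(rows)

    def test_identical_subjects_zero(self):
        t = self._table([[0.3, -0.2], [0.3, -0.2]])
        out = between_subject_variance(t)
        np.testing.assert_allclose(out["variance"], 0.0)

    def test_two_subjects_half_squared_diff(self):
        t = self._table([[0.5], [0.1]])
        out = between_subject_variance(t)
        assert out["variance"].iloc[0] == pytest.approx((0.5 - 0.1) ** 2 / 2)

    def test_single_defined_subject_nan(self):
        t = self._table([[0.5], [np.nan]])
        assert np.isnan(between_subject_variance(t)["variance"].iloc[0])

    def test_matches_brute_force(self, rng):
        vals = rng.standard_normal((5, 4))
        t = self._table(vals)
        out = between_subject_variance(t).set_index("boundary_id")["variance"]
        for b in range(4):
            assert out[b] == pytest.approx(np.var(vals[:, b], ddof=1), abs=1e-12)


# Reference BF10 values computed with R BayesFactor::anovaBF
# (rscaleFixed = 0.5) on the fixtures generated below (seed 7).
_REFERENCE_BF10 = [0.777463953209, 4.85883922244e12, 178.527141336,
                   19.4906362864]


def _bf_fixtures():
    rng = np.random.default_rng(7)
    cases = []
    cases.append((rng.normal(size=120), np.repeat([0, 1, 2], 40)))
    y = rng.normal(size=120) + np.repeat([0.0, 1.0, 2.0], 40)
    cases.append((y, np.repeat([0, 1, 2], 40)))
    y = np.concatenate([rng.normal(size=20), rng.normal(0.8, 1, size=35),
                        rng.normal(0.3, 1, size=15)])
    cases.append((y, np.repeat([0, 1, 2], [20, 35, 15])))
    y = np.concatenate([rng.normal(size=25), rng.normal(0.6, 1, size=25)])
    cases.append((y, np.repeat([0, 1], 25)))
    return cases


class TestBayesAnova:
    @pytest.mark.parametrize("case", range(4))
    def test_matches_reference_implementation(self, case):
        y, g = _bf_fixtures()[case]
        rep = bayes_anova_bf01(y, g)
        assert rep["bf10"] == pytest.approx(_REFERENCE_BF10[case], rel=1e-5)

    def test_bf01_bf10_product(self):
        y, g = _bf_fixtures()[0]
        rep = bayes_anova_bf01(y, g)
        assert rep["bf01"] * rep["bf10"] == pytest.approx(1.0)

    def test_strong_separation_rejects_null(self, rng):
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40),
                            rng.normal(6, 1, 40)])
        g = np.repeat([0, 1, 2], 40)
        assert bayes_anova_bf01(y, g)["bf01"] < 0.1

    def test_posterior_summaries_present(self):
        y, g = _bf_fixtures()[0]
        rep = bayes_anova_bf01(y, g)
        assert len(rep["group_summaries"]) == 3
        s = rep["group_summaries"][0]
        assert s["ci95"][0] < s["posterior_mean"] < s["ci95"][1]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            bayes_anova_bf01(np.arange(10.0), np.zeros(10))


# Reference dip values computed with R diptest::dip on the samples
# generated by _dip_fixtures() below (seed 42).
_REFERENCE_DIPS = [
    0.125, 0.15077400594179452, 0.2374293334237995, 0.125,
    0.125, 0.2290175391893879, 0.1, 0.1,
    0.19242471917408124, 0.13017977258016203, 0.1, 0.19386528537084627,
    0.1544386500151941, 0.08333333333333333, 0.22808894422586246, 0.1096572073028904,
    0.12511170912660313, 0.23491524869996602, 0.10514602095763861, 0.1033492010334327,
    0.1903862451077933, 0.14312336314572668, 0.07142857142857142, 0.19832196598257185,
    0.10188505536335915, 0.10186949931703207, 0.2198997775451173, 0.14894530620639762,
    0.11095427013343509, 0.20572699658689605, 0.09429007775246993, 0.12244393607289712,
    0.2026899335420464, 0.10635557893141415, 0.07793750697165854, 0.1914391257668031,
    0.08337682077151769, 0.06186437299628952, 0.20859901545491563, 0.10682691568333488,
    0.08156906194794325, 0.18964257299075638, 0.11995612067598838, 0.048479969921959416,
    0.18504065358912197, 0.06718811158137726, 0.06766379727249663, 0.19221980307986555,
    0.03629657691157689, 0.05076448654709511, 0.1834803908566042, 0.04462460795292932,
    0.043907922191301706, 0.18804305864703846, 0.0356061520014951, 0.02057314281997936,
    0.17937243454909846, 0.03005857594151343, 0.01923114509159103, 0.1736396982614958,
    0.027708671636889122, 0.01959192672567269, 0.17802876338235787, 0.028599975850810696,
    0.017669727276395052, 0.17642099682926327, 0.125, 0.05,
    0.125,
]


def _dip_fixtures():
    rng = np.random.default_rng(42)
    samples = []
    for n in [4, 5, 6, 7, 8, 10, 15, 20, 50, 100, 200]:
        for k in range(6):
            kind = k % 3
            if kind == 0:
                s = rng.uniform(size=n)
            elif kind == 1:
                s = rng.normal(size=n)
            else:
                s = np.concatenate([rng.normal(-3, 0.4, size=n // 2),
                                    rng.normal(3, 0.4, size=n - n // 2)])
            samples.append(s)
    samples.append(np.arange(4) / 3.0)
    samples.append(np.arange(10) / 9.0)
    samples.append(np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0]))
    return samples


class TestDipStatistic:
    def test_matches_reference_implementation(self):
        for s, expected in zip(_dip_fixtures(), _REFERENCE_DIPS):
            assert dip_statistic(s) == pytest.approx(expected, abs=1e-13)

    def test_equally_spaced_minimum(self):
        # published closed-form minimum for n points: 1 / (2n)
        assert dip_statistic(np.arange(4) / 3.0) == pytest.approx(0.125)
        assert dip_statistic(np.arange(10.0)) == pytest.approx(0.05)

    def test_tiny_samples_return_minimum(self):
        assert dip_statistic(np.array([1.0, 2.0, 3.0])) == pytest.approx(1 / 6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic(np.array([]))

    def test_strong_bimodality_approaches_quarter(self, rng):
        x = np.concatenate([rng.normal(-5, 0.01, 500), rng.normal(5, 0.01, 500)])
        assert dip_statistic(x) > 0.2


class TestDipTest:
    def test_unimodal_not_rejected(self, rng):
        hits = sum(
            dip_test(rng.standard_normal(200), n_boot=500, seed=1)["p"] > 0.05
            for _ in range(20)
        )
        assert hits >= 18

    def test_bimodal_rejected(self, rng):
        x = np.concatenate([rng.normal(-5, 0.1, 100), rng.normal(5, 0.1, 100)])
        assert dip_test(x, n_boot=2000, seed=1)["p"] < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            dip_test(np.array([1.0, 2.0, 3.0]))

    def test_deterministic(self, rng):
        x = rng.standard_normal(50)
        assert dip_test(x, seed=3) == dip_test(x, seed=3)


class TestRmAnova:
    def test_constant_rows_give_zero_f(self):
        table = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 3))
        rep = rm_anova(table)
        assert rep["statistic"] == pytest.approx(0.0)

    def test_matches_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        table = rng.standard_normal((6, 3)) + np.array([0.0, 0.3, 0.8])
        rep = rm_anova(table)
        long = pd.DataFrame(
            {
                "y": table.ravel(),
                "subject": np.repeat(np.arange(6), 3),
                "cond": np.tile(np.arange(3), 6),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          detailed=True, effsize="ng2")
        assert rep["statistic"] == pytest.approx(ref["F"][0], abs=1e-8)
        assert rep["p"] == pytest.approx(ref["p_unc"][0], abs=1e-8)
        assert rep["eta2_g"] == pytest.approx(ref["ng2"][0], abs=1e-8)

    def test_subject_offset_invariance(self, rng):
        table = rng.standard_normal((5, 3))
        shifted = table.copy()
        shifted[2] += 7.5
        assert rm_anova(table)["statistic"] == pytest.approx(
            rm_anova(shifted)["statistic"], abs=1e-9
        )

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            rm_anova(table)


class TestPairedT:
    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.arange(5.0), np.arange(5.0))

    def test_constant_positive_shift(self, rng):
        a = rng.standard_normal(10)
        b = a - 1.0 + 1e-6 * rng.standard_normal(10)
        rep = paired_t(a, b)
        assert rep["statistic"] > 100

    def test_hand_computed_fixture(self):
        a = np.array([3.0, 5.0, 4.0, 6.0, 7.0])
        b = np.array([1.0, 4.0, 4.0, 3.0, 5.0])
        d = a - b  # mean 1.6, sd 1.1402
        expected_t = 1.6 / (np.std(d, ddof=1) / np.sqrt(5))
        rep = paired_t(a, b, n_comparisons=3)
        assert rep["statistic"] == pytest.approx(expected_t, abs=1e-12)
        assert rep["df"] == 4
        assert rep["p_corrected"] == pytest.approx(min(1.0, rep["p"] * 3))


class TestNonBoundarySampler:
    def test_default_counts(self):
        layout = make_session_layout(
            [180.0] * 10, title_duration=4.0, tr=1.5,
            runs=[range(5), range(5, 10)],
        )
        pts = sample_non_boundaries(layout, seed=0)
        assert len(pts) == 44
        assert pts.groupby("run").size().tolist() == [22, 22]

    def test_pairwise_gaps(self, two_run_layout):
        pts = sample_non_boundaries(two_run_layout, per_run=10, seed=1)
        t = np.sort(pts["time_s"].to_numpy())
        assert np.diff(t).min() >= 6.0 - 1e-9

    def test_avoids_titles_and_tails(self, two_run_layout):
        pts = sample_non_boundaries(two_run_layout, per_run=10, seed=2)
        for t in pts["time_s"]:
            assert not two_run_layout.in_title(t)
        for run in range(2):
            end = (two_run_layout.run_starts[run]
                   + two_run_layout.run_durations[run])
            sel = pts[pts["run"] == run]["time_s"]
            assert (sel < end - 10.0).all()

    def test_avoids_boundaries(self, two_run_layout):
        boundaries = pd.DataFrame(
            {"time_s": [50.0, 100.0, 400.0], "excluded": [False, False, False]}
        )
        pts = sample_non_boundaries(two_run_layout, boundaries, per_run=8,
                                    seed=3)
        for t in pts["time_s"]:
            assert np.abs(boundaries["time_s"] - t).min() >= 6.0

    def test_unsatisfiable_raises(self, two_run_layout):
        with pytest.raises(RuntimeError):
            sample_non_boundaries(two_run_layout, per_run=200, seed=0,
                                  max_tries=500)

    def test_deterministic(self, two_run_layout):
        a = sample_non_boundaries(two_run_layout, per_run=5, seed=9)
        b = sample_non_boundaries(two_run_layout, per_run=5, seed=9)
        pd.testing.assert_frame_equal(a, b)
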