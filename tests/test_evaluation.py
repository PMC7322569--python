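"""ROC/AUC + DeLong, quintile ORs, trend/ANOVA/GLM, power calculator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grspipe import evaluation as ev
from grspipe.errors import ComputationError, ConfigError


def exhaustive_auc(scores, labels):
    """Oracle: enumerate every case-control pair; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    cases = s[y == 1]
    controls = s[y == 0]
    wins = sum(1.0 if c > d else (0.5 if c == d else 0.0)
               for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


def permutation_delong_p(scores_a, scores_b, labels, n_perm, seed):
    """Permutation oracle for the paired AUC difference (swap a/b per sample)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    obs = abs(exhaustive_auc(a, y) - exhaustive_auc(b, y))
    n = len(y)
    swap = rng.random((n_perm, n)) < 0.5
    pa = np.where(swap, b, a)
    pb = np.where(swap, a, b)
    case = y == 1
    n1, n0 = case.sum(), (~case).sum()

    def auc_rows(mat):
        ranks = stats.rankdata(mat, axis=1)
        return (ranks[:, case].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)

    diffs = np.abs(auc_rows(pa) - auc_rows(pb))
    return (1 + np.sum(diffs >= obs - 1e-12)) / (n_perm + 1)


class TestRocAuc:
    def test_enumerated_four_pair_example(self):
        res = ev.roc_auc([2, 3, 1, 2.5], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = rng.binomial(1, 0.4, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)      # induce ties
            assert ev.roc_auc(s, y).auc == pytest.approx(
                exhaustive_auc(s, y), abs=1e-12)

    def test_perfect_separation_gives_point_ci(self):
        res = ev.roc_auc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert res.auc == 1.0 and res.var == 0.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_shuffled_labels_near_half(self, rng):
        s = rng.normal(size=2000)
        y = rng.permutation(np.r_[np.ones(1000), np.zeros(1000)])
        assert ev.roc_auc(s, y).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ComputationError):
            ev.roc_auc([1, 2, 3], [1, 1, 1])

    def test_curve_is_monotone_from_origin_to_corner(self, rng):
        s = rng.normal(size=100)
        y = rng.binomial(1, 0.3, 100)
        curve = ev.roc_auc(s, y).curve
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]
        assert (np.diff(curve["fpr"]) >= 0).all()
        assert (np.diff(curve["tpr"]) >= 0).all()


class TestDeLongPaired:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.normal(size=50)
        y = rng.binomial(1, 0.5, 50)
        res = ev.delong_paired_test(s, s, y)
        assert res.diff == 0.0 and res.p == 1.0

    def test_monotone_transform_has_zero_auc_difference(self, rng):
        s = rng.normal(size=80)
        y = rng.binomial(1, 0.4, 80)
        res = ev.delong_paired_test(s, np.exp(s), y)
        assert res.diff == pytest.approx(0.0, abs=1e-12)

    def test_matches_permutation_oracle_on_small_instances(self, rng):
        for seed in range(6):
            r = np.random.default_rng(100 + seed)
            n = 30
            y = np.r_[np.ones(12), np.zeros(18)].astype(int)
            signal = r.normal(0.8, 1, n) * y + r.normal(0, 1, n)
            a = signal + r.normal(0, 0.8, n)
            b = signal + r.normal(0, 0.8, n)
            p_perm = permutation_delong_p(a, b, y, 20_000, seed)
            p_dl = ev.delong_paired_test(a, b, y).p
            assert p_dl == pytest.approx(p_perm, abs=0.035)


class TestAucIncrement:
    def test_redundant_score_adds_nothing(self, rng):
        cov = rng.normal(size=(300, 1))
        y = rng.binomial(1, 1 / (1 + np.exp(-cov[:, 0]))).astype(float)
        res = ev.auc_increment_test(y, cov, cov[:, 0])
        assert abs(res.diff) < 1e-9
        assert res.p > 0.9

    def test_informative_score_detected(self, rng):
        n = 2000
        cov = rng.normal(size=(n, 1))
        s = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * cov[:, 0] + 0.5 * s))))
        res = ev.auc_increment_test(y.astype(float), cov, s)
        assert res.diff > 0 and res.p < 0.05

    def test_empty_covariates_reduce_to_plain_roc(self, rng):
        n = 500
        s = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-s))).astype(float)
        res = ev.auc_increment_test(y, None, s)
        assert res.auc_a == pytest.approx(ev.roc_auc(s, y).auc, abs=1e-9)


class TestQuintileOR:
    def test_exact_split_of_ten_scores(self):
        groups = ev.quintile_assign(np.arange(1, 11))
        assert np.bincount(groups).tolist() == [2, 2, 2, 2, 2]

    def test_hand_2x2_odds_ratio(self):
        """q1 10+/40-, q5 20+/30- -> OR = (20/30)/(10/40) = 8/3."""
        scores = np.arange(250, dtype=float)
        outcome = np.zeros(250)
        outcome[:10] = 1                      # q1: first 50 scores
        outcome[200:220] = 1                  # q5: last 50 scores
        table = ev.quintile_or(scores, outcome)
        assert table.loc[table["quintile"] == 1, "odds_ratio"].iloc[0] == 1.0
        or5 = table.loc[table["quintile"] == 5, "odds_ratio"].iloc[0]
        assert or5 == pytest.approx(8 / 3, rel=1e-12)
        chi2, p, _, _ = stats.chi2_contingency([[20, 30], [10, 40]],
                                               correction=False)
        assert table.loc[table["quintile"] == 5, "p"].iloc[0] == \
            pytest.approx(p, rel=1e-9)

    def test_zero_cell_gets_haldane_correction_and_flag(self):
        scores = np.arange(25, dtype=float)
        outcome = np.zeros(25)
        outcome[-5:] = 1        # q5 all positive, q1 none
        table = ev.quintile_or(scores, outcome)
        row = table[table["quintile"] == 5].iloc[0]
        assert row["corrected"]
        assert np.isfinite(row["odds_ratio"])

    def test_null_cis_cover_one(self, rng):
        covered = 0
        total = 0
        for _ in range(20):
            s = rng.normal(size=500)
            y = rng.binomial(1, 0.3, 500).astype(float)
            table = ev.quintile_or(s, y)
            upper = table[table["quintile"] > 1]
            covered += int(((upper["ci_low"] <= 1) & (upper["ci_high"] >= 1)).sum())
            total += len(upper)
        assert covered / total >= 0.9

    def test_monotone_risk_gives_increasing_ors(self, rng):
        increasing = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            s = r.normal(size=3000)
            y = r.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.6 * s)))).astype(float)
            ors = ev.quintile_or(s, y)["odds_ratio"].to_numpy()
            increasing += int((np.diff(ors) >= 0).all())
        assert increasing >= 8


class TestTrendAnovaGlm:
    def test_trend_slope_recovers_unit_spacing(self, rng):
        levels = np.repeat([0, 1, 2], 50)
        scores = 10.0 + levels + rng.normal(0, 0.05, 150)
        slope, p = ev.ordinal_trend_test(scores, levels)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert p < 1e-3
        slope_rev, _ = ev.ordinal_trend_test(scores, 2 - levels)
        assert slope_rev == pytest.approx(-slope, abs=1e-9)

    def test_single_level_rejected(self):
        with pytest.raises(ComputationError):
            ev.ordinal_trend_test([1.0, 2.0], [1, 1])

    def test_constant_scores_give_zero_f(self):
        table = ev.two_way_anova_grs(np.ones(40), np.tile([0, 1], 20),
                                     np.repeat([0, 1], 20))
        assert (table["F"].fillna(0) == 0).all()

    def test_balanced_additive_design(self, rng):
        a = np.tile([0, 0, 1, 1], 25)
        r = np.tile([0, 1, 0, 1], 25)
        scores = 1.0 * a + 2.0 * r + rng.normal(0, 1e-6, 100)
        table = ev.two_way_anova_grs(scores, a, r).set_index("term")
        assert table.loc["interaction", "F"] < 1e-3 * table.loc["age", "F"]
        assert table.loc["age", "p"] < 1e-10
        assert table.loc["renal", "p"] < 1e-10

    def test_sequential_matches_statsmodels_anova_lm(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        a = rng.binomial(1, 0.5, 120)
        r = rng.binomial(1, 0.4, 120)
        s = 0.3 * a - 0.2 * r + 0.4 * a * r + rng.normal(size=120)
        mine = ev.two_way_anova_grs(s, a, r).set_index("term")
        df = pd.DataFrame({"s": s, "a": a, "r": r})
        ref = anova_lm(smf.ols("s ~ C(a) * C(r)", df).fit(), typ=1)
        assert mine.loc["age", "F"] == pytest.approx(ref["F"].iloc[0], rel=1e-8)
        assert mine.loc["renal", "F"] == pytest.approx(ref["F"].iloc[1], rel=1e-8)
        assert mine.loc["interaction", "F"] == pytest.approx(ref["F"].iloc[2],
                                                             rel=1e-8)

    def test_empty_cell_omits_interaction(self, rng):
        a = np.r_[np.zeros(30), np.ones(30)].astype(int)
        r = np.r_[np.zeros(30), np.zeros(15), np.ones(15)].astype(int)
        # cell (a=0, r=1) is empty
        table = ev.two_way_anova_grs(rng.normal(size=60), a, r)
        assert table.set_index("term").loc["interaction", "omitted"]

    def test_glm_constant_predictor_raises_rank_error(self):
        with pytest.raises(ComputationError, match="collinear"):
            ev.glm_association(np.array([0, 1, 0, 1.0]),
                               pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}),
                               family="logistic")

    def test_logistic_saturated_2x2_closed_form(self):
        """Balanced binary predictor: beta = ln(ad/bc) exactly."""
        a, b, c, d = 30, 20, 15, 35
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        out = ev.glm_association(y, pd.DataFrame({"x": x}), family="logistic")
        beta = out.set_index("term").loc["x", "beta"]
        assert beta == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_linear_onset_slope_recovered_with_ci_coverage(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = r.normal(size=800)
            onset = 35.0 - 1.5 * g + r.normal(0, 8, 800)
            out = ev.glm_association(onset, pd.DataFrame({"g": g}),
                                     family="linear").set_index("term")
            lo = out.loc["g", "beta"] - 1.96 * out.loc["g", "se"]
            hi = out.loc["g", "beta"] + 1.96 * out.loc["g", "se"]
            hits += int(lo <= -1.5 <= hi)
        assert hits >= 9

    def test_interaction_term_built_from_products(self, rng):
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        y = 1.0 + 0.5 * x1 * x2 + rng.normal(0, 0.3, 300)
        out = ev.glm_association(y, pd.DataFrame({"x1": x1, "x2": x2}),
                                 family="linear", interactions=[("x1", "x2")])
        beta = out.set_index("term").loc["x1:x2", "beta"]
        assert beta == pytest.approx(0.5, abs=0.1)


class TestPower:
    @staticmethod
    def closed_form(or_, raf, alpha, n_case, n_control):
        """Independent evaluation of the allelic two-proportion formula."""
        p0 = raf
        p1 = p0 * or_ / (1 + p0 * (or_ - 1))
        m1, m0 = 2 * n_case, 2 * n_control
        pbar = (p1 * m1 + p0 * m0) / (m1 + m0)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m0))
        se1 = np.sqrt(p1 * (1 - p1) / m1 + p0 * (1 - p0) / m0)
        z = stats.norm.ppf(1 - alpha / 2)
        d = abs(p1 - p0)
        return stats.norm.cdf((d - z * se0) / se1) \
            + stats.norm.cdf((-d - z * se0) / se1)

    def test_null_or_gives_alpha(self):
        spec = ev.PowerSpec(or_allele=1.0, raf=0.3, alpha=0.05,
                            n_case=500, n_control=500)
        assert ev.case_control_power(spec) == pytest.approx(0.05, abs=1e-6)

    def test_huge_samples_saturate(self):
        spec = ev.PowerSpec(or_allele=1.1, raf=0.3, alpha=5e-8,
                            n_case=10 ** 8, n_control=10 ** 8)
        assert ev.case_control_power(spec) > 0.999

    def test_renal_gwas_scenario_near_087(self):
        spec = ev.PowerSpec(or_allele=1.5, raf=0.2, alpha=5e-8,
                            n_case=1152, n_control=1949)
        power = ev.case_control_power(spec)
        assert power == pytest.approx(
            self.closed_form(1.5, 0.2, 5e-8, 1152, 1949), abs=1e-12)
        assert power == pytest.approx(0.87, abs=0.01)

    def test_monotone_in_or_n_and_alpha(self):
        base = dict(raf=0.25, alpha=1e-6, n_case=1000, n_control=1500)
        p_or = [ev.case_control_power(ev.PowerSpec(or_allele=o, **base))
                for o in (1.2, 1.4, 1.6)]
        assert p_or[0] < p_or[1] < p_or[2]
        p_n = [ev.case_control_power(ev.PowerSpec(
            or_allele=1.3, raf=0.25, alpha=1e-6, n_case=n, n_control=n))
            for n in (500, 1000, 2000)]
        assert p_n[0] < p_n[1] < p_n[2]
        p_a = [ev.case_control_power(ev.PowerSpec(
            or_allele=1.3, raf=0.25, alpha=al, n_case=1000, n_control=1500))
            for al in (1e-8, 1e-4, 0.05)]
        assert p_a[0] < p_a[1] < p_a[2]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            ev.PowerSpec(or_allele=0.0, raf=0.2, alpha=0.05,
                         n_case=10, n_control=10)
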