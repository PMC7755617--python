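"""Statistics battery: counts, kappa, McNemar, paired tests, reliability, ANOVA.

Hand-computed oracles are frozen here; pingouin / scikit-learn / scipy serve
as independent cross-checks of the in-package implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hippoquant.rater_study import (
    CATEGORIES,
    ConfusionCounts,
    UnbalancedDesignError,
    UndefinedKappaError,
    accuracy_pct,
    cohen_kappa,
    confidence_anova,
    confusion_counts,
    cronbach_alpha,
    icc,
    kappa_band,
    lateralisation_accuracy_pct,
    mcnemar,
    paired_test,
    sensitivity_pct,
    specificity_pct,
)

# ---------------------------------------------------------------------------
# detection counts


class TestConfusionAndRates:
    GOLD = pd.Series(
        {f"c{i}": cat for i, cat in enumerate(["right"] * 10 + ["left"] * 5 + ["bilateral"] * 5
                                              + ["normal"] * 23)}
    )

    def test_all_correct(self):
        cc = confusion_counts(self.GOLD, self.GOLD)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (20, 23, 0, 0)
        assert accuracy_pct(cc) == 100.0

    def test_mislateralisation_still_counts_as_detection(self):
        ratings = self.GOLD.copy()
        ratings.iloc[0] = "left"  # gold right, rated left
        cc = confusion_counts(ratings, self.GOLD)
        assert cc.tp == 20 and cc.fn == 0
        assert lateralisation_accuracy_pct(ratings, self.GOLD) == pytest.approx(95.0)

    def test_accuracy_formula(self):
        cc = ConfusionCounts(tp=35, tn=5, fp=1, fn=2)
        assert accuracy_pct(cc) == pytest.approx(100 * 40 / 43)
        assert round(accuracy_pct(cc), 2) == 93.02
        assert sensitivity_pct(ConfusionCounts(10, 0, 0, 0)) == 100.0

    def test_zero_denominators_rejected(self):
        with pytest.raises(ZeroDivisionError):
            accuracy_pct(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ZeroDivisionError):
            sensitivity_pct(ConfusionCounts(0, 5, 1, 0))
        with pytest.raises(ZeroDivisionError):
            specificity_pct(ConfusionCounts(5, 0, 0, 1))

    def test_empty_and_unmatched_cases_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts({}, self.GOLD)
        with pytest.raises(ValueError):
            confusion_counts({"other": "normal"}, self.GOLD)

    def test_lateralisation_requires_abnormal_cases(self):
        gold = pd.Series({"a": "normal"})
        with pytest.raises(ValueError):
            lateralisation_accuracy_pct(gold, gold)

    def test_category_swap_breaks_lateralisation_not_detection(self):
        swapped = self.GOLD.replace({"right": "left", "left": "right"})
        cc = confusion_counts(swapped, self.GOLD)
        assert cc.tp == 20  # all detections kept
        assert lateralisation_accuracy_pct(swapped, self.GOLD) == pytest.approx(100 * 5 / 20)


# ---------------------------------------------------------------------------
# kappa


class TestKappa:
    def test_identical_ratings(self):
        r = ["normal", "right", "left", "bilateral"] * 3
        assert cohen_kappa(r, r) == 1.0

    def test_toy_confusion_hand_value(self):
        # confusion [[4,1],[1,4]]: p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        a = ["x"] * 5 + ["y"] * 5
        b = ["x"] * 4 + ["y"] + ["x"] + ["y"] * 4
        assert cohen_kappa(a, b, categories=("x", "y")) == pytest.approx(0.6)

    def test_independent_ratings_near_zero(self, rng):
        n = 100_000
        a = rng.choice(CATEGORIES, size=n, p=[0.5, 0.2, 0.2, 0.1])
        b = rng.choice(CATEGORIES, size=n, p=[0.4, 0.3, 0.2, 0.1])
        assert abs(cohen_kappa(a, b)) < 0.01

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.choice(CATEGORIES, size=200)
        b = np.where(rng.random(200) < 0.6, a, rng.choice(CATEGORIES, size=200))
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_degenerate_chance_agreement(self):
        # both raters constant on the same category: perfect agreement even
        # though chance agreement is also 1
        assert cohen_kappa(["normal"] * 5, ["normal"] * 5) == 1.0
        # constant but different categories: no agreement beyond chance
        assert cohen_kappa(["normal"] * 5, ["left"] * 5,
                           categories=("normal", "left")) == 0.0

    @given(perm=st.permutations(list(CATEGORIES)))
    def test_label_permutation_invariance(self, perm):
        rng = np.random.default_rng(17)
        a = rng.choice(CATEGORIES, size=60)
        b = np.where(rng.random(60) < 0.5, a, rng.choice(CATEGORIES, size=60))
        mapping = dict(zip(CATEGORIES, perm))
        k1 = cohen_kappa(a, b)
        k2 = cohen_kappa([mapping[x] for x in a], [mapping[x] for x in b])
        assert k1 == pytest.approx(k2, abs=1e-12)


class TestKappaBand:
    @pytest.mark.parametrize(
        "value,label",
        [(0.74, "moderate"), (0.86, "strong"), (0.60, "moderate"), (0.90, "strong"),
         (0.95, "almost perfect"), (0.45, "weak"), (0.25, "minimal"), (0.05, "none")],
    )
    def test_bands(self, value, label):
        assert kappa_band(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.2)


# ---------------------------------------------------------------------------
# McNemar


class TestMcNemar:
    def test_symmetric_discordance(self):
        r = mcnemar(5, 5)
        assert r.p == 1.0 and r.method == "exact"

    def test_exact_binomial_hand_sum(self):
        # 2 * P[X <= 2 | n=10, 1/2] = 2 * (1 + 10 + 45)/1024
        r = mcnemar(8, 2)
        assert r.p == pytest.approx(0.109375, abs=1e-12)

    def test_chi_square_with_continuity_correction(self):
        r = mcnemar(30, 10)
        assert r.statistic == pytest.approx((19.0**2) / 40.0)
        assert r.method == "chi2_cc"

    def test_no_discordance_convention(self):
        assert mcnemar(0, 0) == mcnemar(0, 0)
        assert mcnemar(0, 0).p == 1.0

    @given(b=st.integers(0, 60), c=st.integers(0, 60))
    def test_symmetry(self, b, c):
        assert mcnemar(b, c).p == pytest.approx(mcnemar(c, b).p, abs=1e-12)


# ---------------------------------------------------------------------------
# paired tests


class TestPairedTest:
    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_hand_arithmetic(self):
        r = paired_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])  # diffs (1, 2, 3)
        assert r.t == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2
        assert r.d_z == pytest.approx(2.0)
        assert r.g_z == pytest.approx(2.0 * (1 - 3 / 7))

    def test_cross_check_scipy(self, rng):
        from scipy import stats

        x = rng.normal(size=12)
        y = x + rng.normal(0.4, 0.5, size=12)
        mine = paired_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_effect_threshold(self):
        from hippoquant.rater_study import effect_size_label

        assert effect_size_label(0.81) == "large"
        assert effect_size_label(0.79) == "medium"


# ---------------------------------------------------------------------------
# reliability


class TestReliability:
    def test_alpha_identical_columns(self, rng):
        col = rng.normal(size=50)
        assert cronbach_alpha(np.column_stack([col] * 3)) == pytest.approx(1.0)

    def test_alpha_independent_columns_near_zero(self, rng):
        m = rng.normal(size=(100_000, 3))
        assert abs(cronbach_alpha(m)) < 0.02

    def test_alpha_spearman_brown_limit(self, rng):
        n = 100_000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        assert cronbach_alpha(np.column_stack([x, y])) == pytest.approx(2 / 3, abs=0.01)

    def test_alpha_cross_check_pingouin(self, rng):
        import pingouin as pg

        m = rng.normal(size=(40, 4)) + rng.normal(size=(40, 1))
        ref = pg.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert cronbach_alpha(m) == pytest.approx(ref, abs=1e-10)

    def test_icc_identical_columns(self, rng):
        col = rng.normal(size=30)
        m = np.column_stack([col] * 4)
        assert icc(m, "single") == pytest.approx(1.0)
        assert icc(m, "average") == pytest.approx(1.0)

    def test_icc_independent_columns_near_zero(self, rng):
        m = rng.normal(size=(50_000, 3))
        assert abs(icc(m, "single")) < 0.02
        assert abs(icc(m, "average")) < 0.05

    def test_icc_average_at_least_single(self, rng):
        for _ in range(10):
            m = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1))
            if icc(m, "single") >= 0:  # MS_R >= MS_E
                assert icc(m, "average") >= icc(m, "single")

    def test_icc_cross_check_pingouin(self, rng):
        import pingouin as pg

        m = rng.normal(size=(30, 3)) + 2.0 * rng.normal(size=(30, 1))
        long = pd.DataFrame(
            [(i, j, m[i, j]) for i, j in itertools.product(range(30), range(3))],
            columns=["targets", "raters", "ratings"],
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        # ICC(C,1)/(C,k): two-way consistency, single / average measures
        assert icc(m, "single") == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert icc(m, "average") == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cronbach_alpha(np.ones((10, 3)))
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)), "single")


# ---------------------------------------------------------------------------
# ANOVA


def _brute_force_ss(df, dv, subject, within, between=None):
    """Independent sums-of-squares oracle via explicit mean tables."""
    out = {}
    gm = df[dv].mean()
    out["total"] = ((df[dv] - gm) ** 2).sum()

    def means(cols):
        return df.groupby(cols, sort=True)[dv].mean()

    cells_per = {}
    all_factors = within + ([between] if between else [])
    for r in range(1, len(all_factors) + 1):
        for combo in itertools.combinations(all_factors, r):
            cells_per[combo] = means(list(combo))

    n_per_level = {f: df[f].nunique() for f in all_factors + [subject]}
    n_obs = len(df)

    def effect_ss(factors):
        # alternating-sign inclusion-exclusion around the grand mean
        levels = [sorted(df[f].unique()) for f in factors]
        total = 0.0
        reps = n_obs / np.prod([len(lv) for lv in levels])
        for combo in itertools.product(*levels):
            dev = 0.0
            for r in range(1, len(factors) + 1):
                for sub_idx in itertools.combinations(range(len(factors)), r):
                    key = tuple(factors[i] for i in sub_idx)
                    val = tuple(combo[i] for i in sub_idx)
                    m = cells_per[key]
                    dev += (-1) ** (len(factors) - r) * m[val if len(val) > 1 else val[0]]
            dev += (-1) ** len(factors) * gm
            total += reps * dev**2
        return total

    for r in range(1, len(all_factors) + 1):
        for combo in itertools.combinations(all_factors, r):
            out[" x ".join(combo)] = effect_ss(list(combo))
    return out


class TestConfidenceAnova:
    @staticmethod
    def _within_2x2(seed=1, effect_a=1.0, n_sub=9):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sub):
            off = rng.normal(0, 1)
            for a in ("a1", "a2"):
                for b in ("b1", "b2"):
                    rows.append(dict(subject=f"s{s}", A=a, B=b,
                                     y=off + (effect_a if a == "a2" else 0) + rng.normal(0, 0.3)))
        return pd.DataFrame(rows)

    def test_equal_cells_give_zero_f(self):
        rows = [dict(subject=f"s{s}", A=a, B=b, y=float(s))
                for s in range(5) for a in ("a1", "a2") for b in ("b1", "b2")]
        t = confidence_anova(pd.DataFrame(rows), "y", "subject", ["A", "B"])
        effects = t[t["source"].isin(["A", "B", "A x B"])]
        assert (effects["F"] == 0).all()
        assert (effects["partial_eta_sq"] == 0).all()

    def test_constructed_main_effect_detected(self):
        df = self._within_2x2(effect_a=1.0)
        t = confidence_anova(df, "y", "subject", ["A", "B"]).set_index("source")
        assert t.loc["A", "F"] > 30
        assert t.loc["B", "F"] < 5
        oracle = _brute_force_ss(df, "y", "subject", ["A", "B"])
        assert t.loc["A", "SS"] == pytest.approx(oracle["A"], abs=1e-9)
        assert t.loc["B", "SS"] == pytest.approx(oracle["B"], abs=1e-9)
        assert t.loc["A x B", "SS"] == pytest.approx(oracle["A x B"], abs=1e-9)

    def test_ss_total_conservation(self):
        df = self._within_2x2(seed=7, effect_a=0.5)
        t = confidence_anova(df, "y", "subject", ["A", "B"])
        assert t["SS"].sum() == pytest.approx(t.attrs["SS_total"], abs=1e-9)

    def test_cross_check_pingouin_two_way_rm(self):
        import pingouin as pg

        df = self._within_2x2(seed=3, effect_a=0.7)
        mine = confidence_anova(df, "y", "subject", ["A", "B"]).set_index("source")
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subject",
                          detailed=True).set_index("Source")
        for src, ref_src in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            assert mine.loc[src, "F"] == pytest.approx(ref.loc[ref_src, "F"], abs=1e-9)
            assert mine.loc[src, "p"] == pytest.approx(ref.loc[ref_src, "p_unc"], abs=1e-9)

    def test_cross_check_pingouin_mixed(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        rows = []
        for g_i, g in enumerate(("g1", "g2", "g3")):
            for s in range(3):
                off = rng.normal(g_i * 0.5, 1)
                for a in ("a1", "a2"):
                    rows.append(dict(subject=f"{g}-s{s}", group=g, A=a,
                                     y=off + (0.8 if a == "a2" else 0) + rng.normal(0, 0.3)))
        df = pd.DataFrame(rows)
        mine = confidence_anova(df, "y", "subject", ["A"], between="group").set_index("source")
        ref = pg.mixed_anova(data=df, dv="y", within="A", subject="subject",
                             between="group").set_index("Source")
        assert mine.loc["A", "F"] == pytest.approx(ref.loc["A", "F"], abs=1e-9)
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], abs=1e-9)
        assert mine.loc["A x group", "F"] == pytest.approx(ref.loc["Interaction", "F"], abs=1e-9)
        assert mine.loc["A", "partial_eta_sq"] == pytest.approx(ref.loc["A", "np2"], abs=1e-9)

    def test_mixed_2x2x3_matches_brute_force(self):
        rng = np.random.default_rng(11)
        rows = []
        for g_i, g in enumerate(("expert", "trainee", "analyst")):
            for s in range(3):
                off = rng.normal(0.3 * g_i, 1)
                for a in ("with", "without"):
                    for b in ("normal", "abnormal"):
                        y = off + (0.6 if a == "with" else 0) + (0.2 if b == "abnormal" else 0)
                        rows.append(dict(subject=f"{g}{s}", group=g, A=a, B=b,
                                         y=y + rng.normal(0, 0.2)))
        df = pd.DataFrame(rows)
        t = confidence_anova(df, "y", "subject", ["A", "B"], between="group")
        oracle = _brute_force_ss(df, "y", "subject", ["A", "B"], between="group")
        got = t.set_index("source")["SS"]
        assert got["A"] == pytest.approx(oracle["A"], abs=1e-9)
        assert got["B"] == pytest.approx(oracle["B"], abs=1e-9)
        assert got["group"] == pytest.approx(oracle["group"], abs=1e-9)
        assert got["A x B"] == pytest.approx(oracle["A x B"], abs=1e-9)
        assert got["A x group"] == pytest.approx(oracle["A x group"], abs=1e-9)
        assert got["B x group"] == pytest.approx(oracle["B x group"], abs=1e-9)
        assert got["A x B x group"] == pytest.approx(oracle["A x B x group"], abs=1e-9)
        assert t["SS"].sum() == pytest.approx(t.attrs["SS_total"], abs=1e-9)
        # between factor is tested against subjects-within-groups
        assert t.set_index("source").loc["group", "err_df"] == 6

    def test_unbalanced_rejected(self):
        df = self._within_2x2().iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            confidence_anova(df, "y", "subject", ["A", "B"])
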