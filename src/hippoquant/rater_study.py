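"""Reader-study statistics battery and rater-response simulator.

Implements the full hierarchy of a paired diagnostic reader study in which
raters of three experience groups (experts, trainees, image analysts)
categorise each case as normal / right / left / bilateral hippocampal
sclerosis, once with and once without a quantitative report, against a
clinicopathological gold standard:

- detection counts (TP/TN/FP/FN on the normal-vs-abnormal dichotomy, with
  any abnormal category counting as a detection) and the derived accuracy,
  sensitivity and specificity percentages;
- exact-category lateralisation accuracy over the abnormal cases;
- unweighted 4-category Cohen's kappa of each rater against the gold
  standard, with verbal agreement bands;
- McNemar's test on paired correct/incorrect designations (exact binomial
  for < 25 discordant pairs, continuity-corrected chi-square otherwise);
- paired t tests across raters with the paired-samples effect sizes d_z and
  Hedges' g_z (small-sample corrected), plus an average-SD classical d;
- Cronbach's alpha and two-way mixed-effects consistency ICC (single and
  average measures) as inter-rater reliability;
- balanced repeated-measures / mixed ANOVA with partial eta squared for the
  confidence analyses (2 correctness x 2 report conditions within raters,
  optionally crossed with the 3-level experience group between raters).

A parametric simulator generates complete rater-study tables under known
sensitivity / specificity / lateralisation parameters so the whole battery
is testable end to end and recovery of generating parameters can be
checked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "CONDITIONS",
    "GROUPS",
    "ConfusionCounts",
    "McNemarResult",
    "PairedTestResult",
    "StudyDesign",
    "RaterParams",
    "StudyResult",
    "UndefinedKappaError",
    "UnbalancedDesignError",
    "confusion_counts",
    "accuracy_pct",
    "sensitivity_pct",
    "specificity_pct",
    "lateralisation_accuracy_pct",
    "cohen_kappa",
    "kappa_band",
    "mcnemar",
    "paired_test",
    "cronbach_alpha",
    "icc",
    "confidence_anova",
    "simulate_rater_study",
    "analyze_study",
]

CATEGORIES = ("normal", "right", "left", "bilateral")
CONDITIONS = ("without_report", "with_report")
GROUPS = ("expert", "trainee", "analyst")

#: ordinal coding of the categorical rating used for alpha / ICC
_RATING_CODE = {c: i for i, c in enumerate(CATEGORIES)}

TABLE_COLUMNS = [
    "rater", "group", "case", "condition", "rating",
    "confidence_normality", "confidence_lateralisation",
]


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 with imperfect observed agreement."""


class UnbalancedDesignError(ValueError):
    """The ANOVA requires a complete, balanced design."""


# ---------------------------------------------------------------------------
# detection counts and rates


@dataclass(frozen=True)
class ConfusionCounts:
    """Normal-vs-abnormal detection counts; any abnormal category is a
    detection even when the lateralisation is wrong (lateralisation is
    scored separately)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_series(ratings) -> pd.Series:
    if isinstance(ratings, pd.Series):
        s = ratings
    elif isinstance(ratings, dict):
        s = pd.Series(ratings)
    else:
        s = pd.Series(list(ratings))
    if len(s) == 0:
        raise ValueError("empty ratings")
    return s


def confusion_counts(ratings, gold) -> ConfusionCounts:
    """Count TP/TN/FP/FN of ratings against the gold standard."""
    r = _as_series(ratings)
    g = _as_series(gold)
    missing = g.index.difference(r.index)
    if len(missing) > 0:
        raise ValueError(f"ratings missing for cases: {list(missing)[:5]}")
    r = r.loc[g.index]
    rated_abn = r != "normal"
    gold_abn = g != "normal"
    return ConfusionCounts(
        tp=int((rated_abn & gold_abn).sum()),
        tn=int((~rated_abn & ~gold_abn).sum()),
        fp=int((rated_abn & ~gold_abn).sum()),
        fn=int((~rated_abn & gold_abn).sum()),
    )


def accuracy_pct(c: ConfusionCounts) -> float:
    """100 x (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ZeroDivisionError("no assessments")
    return 100.0 * (c.tp + c.tn) / c.total


def sensitivity_pct(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("no abnormal gold cases")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity_pct(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("no normal gold cases")
    return 100.0 * c.tn / (c.tn + c.fp)


def lateralisation_accuracy_pct(ratings, gold) -> float:
    """Share of abnormal gold cases whose exact category was matched."""
    r = _as_series(ratings)
    g = _as_series(gold)
    abn = g[g != "normal"]
    if len(abn) == 0:
        raise ValueError("no abnormal gold cases")
    return 100.0 * float((r.loc[abn.index] == abn).mean())


# ---------------------------------------------------------------------------
# agreement


def cohen_kappa(ratings_a, ratings_b, categories=CATEGORIES) -> float:
    """Unweighted Cohen's kappa, chance agreement from marginal products."""
    a = pd.Categorical(_as_series(ratings_a), categories=categories)
    b = pd.Categorical(_as_series(ratings_b), categories=categories)
    if len(a) != len(b):
        raise ValueError("rating sequences differ in length")
    if len(a) < 2:
        raise ValueError("need at least 2 cases")
    n = len(a)
    table = pd.crosstab(a, b, dropna=False).reindex(
        index=categories, columns=categories, fill_value=0
    ).to_numpy()
    p_o = np.trace(table) / n
    p_e = float(table.sum(axis=1) @ table.sum(axis=0)) / n**2
    if p_o == 1.0:
        return 1.0
    if p_e >= 1.0:
        raise UndefinedKappaError("chance agreement 1 with imperfect agreement")
    return float((p_o - p_e) / (1.0 - p_e))


#: verbal agreement bands; the 0.60-0.79 / 0.80-0.90 bands follow the
#: McHugh-style scale, extended below and above in the same family
_KAPPA_BANDS = [
    (0.20, "none"),
    (0.40, "minimal"),
    (0.60, "weak"),
    (0.80, "moderate"),
    (0.90 + 1e-12, "strong"),  # strong band closed at 0.90
    (np.inf, "almost perfect"),
]


def kappa_band(kappa: float) -> str:
    """Verbal label: moderate on [0.60, 0.80), strong on [0.80, 0.90]."""
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    for upper, label in _KAPPA_BANDS:
        if kappa < upper:
            return label
    return "almost perfect"


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p: float
    method: str


def mcnemar(b: int, c: int) -> McNemarResult:
    """McNemar test on the two discordant counts.

    Exact two-sided binomial when b + c < 25, else the continuity-corrected
    chi-square (|b-c|-1)^2/(b+c) on 1 df. b = c = 0 gives p = 1 by
    convention. Symmetric in (b, c).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return McNemarResult(statistic=0.0, p=1.0, method="exact")
    if n < 25:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return McNemarResult(statistic=float(min(b, c)), p=float(p), method="exact")
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return McNemarResult(statistic=float(chi2), p=float(stats.chi2.sf(chi2, 1)),
                         method="chi2_cc")


# ---------------------------------------------------------------------------
# paired tests and effect sizes


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d_z: float
    g_z: float
    d_av: float  # mean difference over the average of the two SDs
    mean_diff: float
    sd_diff: float


def paired_test(x, y) -> PairedTestResult:
    """Two-sided paired t test with paired-samples effect sizes.

    d_z = mean(d)/SD(d); Hedges' g_z applies the small-sample correction
    1 - 3/(4 df - 1); d_av divides by the average of the two conditions'
    SDs (reported because group-level d on summary SDs is also in common
    use, and the two can differ noticeably at small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and paired")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences")
    mean = d.mean()
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    d_z = mean / sd
    g_z = d_z * (1.0 - 3.0 / (4.0 * df - 1.0))
    sd_av = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    d_av = mean / sd_av if sd_av > 0 else math.nan
    return PairedTestResult(t=float(t), df=df, p=float(p), d_z=float(d_z),
                            g_z=float(g_z), d_av=float(d_av),
                            mean_diff=float(mean), sd_diff=float(sd))


def effect_size_label(d: float) -> str:
    """Cohen's rule of thumb; |d| > 0.8 is a large effect."""
    a = abs(d)
    if a > 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# reliability


def cronbach_alpha(matrix) -> float:
    """alpha = k/(k-1) (1 - sum item variances / variance of case sums)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a cases x raters matrix with >= 2 of each")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("zero variance of case-wise sums")
    item_var = m.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def icc(matrix, form: str = "single") -> float:
    """Two-way mixed-effects, consistency-definition intraclass correlation.

    single  = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    average = (MS_R - MS_E) / MS_R
    with MS_R the between-cases and MS_E the residual mean square of the
    two-way (cases x raters) ANOVA without replication.
    """
    if form not in ("single", "average"):
        raise ValueError(f"form must be 'single' or 'average', got {form!r}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete cases x raters matrix with >= 2 of each")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete")
    n, k = m.shape
    gm = m.mean()
    ss_rows = k * ((m.mean(axis=1) - gm) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - gm) ** 2).sum()
    ss_total = ((m - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        raise ZeroDivisionError("degenerate mean squares (no between-case variance)")
    if form == "single":
        return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e))
    return float((ms_r - ms_e) / ms_r)


# ---------------------------------------------------------------------------
# balanced repeated-measures / mixed ANOVA


def _balanced_cube(df: pd.DataFrame, dv: str, subject: str,
                   within: list[str], between: str | None):
    """Arrange a long table as Y[group, subject, A, C]; reject imbalance."""
    levels_w = [sorted(df[w].unique()) for w in within]
    if between is not None:
        groups = sorted(df[between].unique())
        per_group = [sorted(df.loc[df[between] == g, subject].unique()) for g in groups]
        sizes = {len(s) for s in per_group}
        if len(sizes) != 1:
            raise UnbalancedDesignError(f"unequal group sizes {sorted(len(s) for s in per_group)}")
        if min(sizes) < 2:
            raise UnbalancedDesignError("need >= 2 subjects per between-level")
    else:
        groups = [None]
        per_group = [sorted(df[subject].unique())]

    a = len(levels_w[0])
    c = len(levels_w[1]) if len(within) == 2 else 1
    s = len(per_group[0])
    y = np.full((len(groups), s, a, c), np.nan)
    index = {w: {lv: i for i, lv in enumerate(lvs)} for w, lvs in zip(within, levels_w)}
    for g_i, subs in enumerate(per_group):
        sub_idx = {sub: i for i, sub in enumerate(subs)}
        sel = df if between is None else df[df[between] == groups[g_i]]
        for _, row in sel.iterrows():
            i_a = index[within[0]][row[within[0]]]
            i_c = index[within[1]][row[within[1]]] if c > 1 else 0
            slot = (g_i, sub_idx[row[subject]], i_a, i_c)
            if not np.isnan(y[slot]):
                raise UnbalancedDesignError("duplicate cell observation")
            y[slot] = row[dv]
    if np.isnan(y).any():
        raise UnbalancedDesignError("incomplete design (missing cells)")
    return y, groups, levels_w


def confidence_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> pd.DataFrame:
    """Balanced repeated-measures (1-2 within factors) / mixed ANOVA.

    Sums of squares by the standard balanced decomposition: within-subject
    effects are tested against their factor x subject(within-group) error
    stratum, the between factor against subjects within groups. Partial eta
    squared is SS_effect / (SS_effect + SS_error-stratum). Unbalanced or
    incomplete designs are rejected, not approximated.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("need 1 or 2 within factors")
    y, groups, levels_w = _balanced_cube(table, dv, subject, within, between)
    b, s, a, c = y.shape
    gm = y.mean()
    n_sub = b * s

    m_g = y.mean(axis=(1, 2, 3))
    m_gs = y.mean(axis=(2, 3))
    m_i = y.mean(axis=(0, 1, 3))
    m_k = y.mean(axis=(0, 1, 2))
    m_gi = y.mean(axis=(1, 3))
    m_gk = y.mean(axis=(1, 2))
    m_ik = y.mean(axis=(0, 1))
    m_gik = y.mean(axis=1)
    m_gsi = y.mean(axis=3)
    m_gsk = y.mean(axis=2)

    rows = []

    def add(source, ss, df, err_ss=None, err_df=None, err_name=None):
        rows.append(dict(source=source, SS=float(ss), df=int(df),
                         err_SS=err_ss, err_df=err_df, err_name=err_name))

    ss_subj = a * c * ((m_gs - m_g[:, None]) ** 2).sum()
    df_subj = b * (s - 1)
    if between is not None:
        ss_b = s * a * c * ((m_g - gm) ** 2).sum()
        add(between, ss_b, b - 1, ss_subj, df_subj, "subjects")
    add("subjects", ss_subj, df_subj)

    A = within[0]
    ss_a = n_sub * c * ((m_i - gm) ** 2).sum()
    ss_as = c * ((m_gsi - m_gs[:, :, None] - m_gi[:, None, :] + m_g[:, None, None]) ** 2).sum()
    df_as = (a - 1) * b * (s - 1)
    add(A, ss_a, a - 1, ss_as, df_as, f"{A} x subjects")
    if between is not None:
        ss_ab = s * c * ((m_gi - m_g[:, None] - m_i[None, :] + gm) ** 2).sum()
        add(f"{A} x {between}", ss_ab, (a - 1) * (b - 1), ss_as, df_as, f"{A} x subjects")
    add(f"{A} x subjects", ss_as, df_as)

    if c > 1:
        C = within[1]
        ss_c = n_sub * a * ((m_k - gm) ** 2).sum()
        ss_cs = a * ((m_gsk - m_gs[:, :, None] - m_gk[:, None, :] + m_g[:, None, None]) ** 2).sum()
        df_cs = (c - 1) * b * (s - 1)
        add(C, ss_c, c - 1, ss_cs, df_cs, f"{C} x subjects")
        if between is not None:
            ss_cb = s * a * ((m_gk - m_g[:, None] - m_k[None, :] + gm) ** 2).sum()
            add(f"{C} x {between}", ss_cb, (c - 1) * (b - 1), ss_cs, df_cs, f"{C} x subjects")
        add(f"{C} x subjects", ss_cs, df_cs)

        ss_ac = n_sub * ((m_ik - m_i[:, None] - m_k[None, :] + gm) ** 2).sum()
        df_acs = (a - 1) * (c - 1) * b * (s - 1)
        ss_total = ((y - gm) ** 2).sum()
        ss_acs = ss_total - sum(r["SS"] for r in rows) - ss_ac
        ss_acb = 0.0
        if between is not None:
            ss_acb = s * ((m_gik - m_gi[:, :, None] - m_gk[:, None, :] - m_ik[None, :, :]
                           + m_g[:, None, None] + m_i[None, :, None] + m_k[None, None, :]
                           - gm) ** 2).sum()
            ss_acs -= ss_acb
        add(f"{A} x {C}", ss_ac, (a - 1) * (c - 1), ss_acs, df_acs, f"{A} x {C} x subjects")
        if between is not None:
            add(f"{A} x {C} x {between}", ss_acb, (a - 1) * (c - 1) * (b - 1),
                ss_acs, df_acs, f"{A} x {C} x subjects")
        add(f"{A} x {C} x subjects", ss_acs, df_acs)

    out = []
    for r in rows:
        if r["err_SS"] is not None and r["SS"] <= 1e-12:
            F, p, pes = 0.0, 1.0, 0.0
        elif r["err_SS"] is not None and r["err_df"] > 0 and r["err_SS"] > 0:
            ms = r["SS"] / r["df"] if r["df"] > 0 else np.nan
            ms_err = r["err_SS"] / r["err_df"]
            F = ms / ms_err
            p = float(stats.f.sf(F, r["df"], r["err_df"]))
            pes = r["SS"] / (r["SS"] + r["err_SS"])
        else:
            F = p = pes = np.nan
        out.append(dict(source=r["source"], SS=r["SS"], df=r["df"],
                        F=F, p=p, partial_eta_sq=pes,
                        error_term=r["err_name"], err_df=r["err_df"]))
    result = pd.DataFrame(out)
    result.attrs["SS_total"] = float(((y - gm) ** 2).sum())
    return result


# ---------------------------------------------------------------------------
# simulator


@dataclass
class StudyDesign:
    """Case mix and rater panel of the reader study.

    Defaults reproduce the validation study's design: 43 cases (23 normal,
    9 right, 6 left, 5 bilateral), three raters in each of three experience
    groups, two paired conditions.
    """

    n_cases: dict[str, int] = field(default_factory=lambda: {
        "normal": 23, "right": 9, "left": 6, "bilateral": 5})
    raters_per_group: int = 3

    @property
    def total_cases(self) -> int:
        return sum(self.n_cases.values())


@dataclass
class RaterParams:
    """Generating response parameters for one experience group.

    Probabilities apply without the report; ``delta_*`` are added when the
    report is present. ``lateralisation`` is the probability of the exact
    abnormal category given detection; otherwise the error is uniform over
    the remaining abnormal categories. Confidence is a discretised Gaussian
    clipped to 1..5 whose mean depends on correctness and condition.
    """

    sensitivity: float = 0.875
    specificity: float = 0.874
    lateralisation: float = 0.905
    delta_sensitivity: float = 0.025
    delta_specificity: float = 0.076
    delta_lateralisation: float = 0.06
    conf_correct_mean: float = 3.8
    conf_incorrect_mean: float = 3.0
    conf_delta_report: float = 0.35
    conf_sd: float = 0.8

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "lateralisation"):
            base = getattr(self, name)
            shifted = base + getattr(self, f"delta_{name}")
            if not (0 <= base <= 1 and 0 <= shifted <= 1):
                raise ValueError(f"{name} and its report delta must stay in [0, 1]")


def default_group_params() -> dict[str, RaterParams]:
    """Group response parameters in the regime of the validation study
    (experts most sensitive/specific, analysts gaining most from the
    report)."""
    return {
        "expert": RaterParams(sensitivity=0.967, specificity=0.884, lateralisation=0.93,
                              delta_sensitivity=0.016, delta_specificity=0.058,
                              delta_lateralisation=0.04),
        "trainee": RaterParams(sensitivity=0.761, specificity=0.942, lateralisation=0.88,
                               delta_sensitivity=0.039, delta_specificity=0.0,
                               delta_lateralisation=0.05),
        "analyst": RaterParams(sensitivity=0.90, specificity=0.797, lateralisation=0.87,
                               delta_sensitivity=0.017, delta_specificity=0.16,
                               delta_lateralisation=0.08,
                               conf_delta_report=0.55),
    }


def simulate_rater_study(
    design: StudyDesign | None = None,
    params: dict[str, RaterParams] | RaterParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a complete paired rater study; returns (table, gold).

    Draw order: raters in group order (expert, trainee, analyst; numbered
    within group), conditions (without_report, with_report), cases in gold
    order; per assessment: detection uniform, category uniform, then the two
    confidence Gaussians (normality, lateralisation).
    """
    design = design or StudyDesign()
    if params is None:
        params = default_group_params()
    if isinstance(params, RaterParams):
        params = {g: params for g in GROUPS}
    rng = np.random.default_rng(seed)

    gold = pd.Series(
        {f"case{j + 1:03d}": cat
         for j, cat in enumerate(
             c for cat_ in CATEGORIES for c in [cat_] * design.n_cases.get(cat_, 0))},
        name="gold",
    )

    def draw_conf(mean: float, sd: float) -> int:
        return int(np.clip(np.rint(rng.normal(mean, sd)), 1, 5))

    records = []
    for group in GROUPS:
        p = params[group]
        for r in range(design.raters_per_group):
            rater = f"{group}-{r + 1}"
            for condition in CONDITIONS:
                with_rep = condition == "with_report"
                sens = p.sensitivity + (p.delta_sensitivity if with_rep else 0.0)
                spec = p.specificity + (p.delta_specificity if with_rep else 0.0)
                lat = p.lateralisation + (p.delta_lateralisation if with_rep else 0.0)
                conf_delta = p.conf_delta_report if with_rep else 0.0
                for case, truth in gold.items():
                    if truth == "normal":
                        if rng.random() < spec:
                            rating = "normal"
                        else:
                            rating = CATEGORIES[1:][rng.integers(3)]
                    else:
                        if rng.random() < sens:
                            if rng.random() < lat:
                                rating = truth
                            else:
                                others = [c for c in CATEGORIES[1:] if c != truth]
                                rating = others[rng.integers(len(others))]
                        else:
                            rating = "normal"
                    correct_norm = (rating != "normal") == (truth != "normal")
                    correct_lat = rating == truth
                    base_n = p.conf_correct_mean if correct_norm else p.conf_incorrect_mean
                    base_l = p.conf_correct_mean if correct_lat else p.conf_incorrect_mean
                    records.append(
                        (rater, group, case, condition, rating,
                         draw_conf(base_n + conf_delta, p.conf_sd),
                         draw_conf(base_l + conf_delta, p.conf_sd))
                    )
    table = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    return table, gold


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class StudyResult:
    per_rater: pd.DataFrame
    group_summary: pd.DataFrame
    paired: pd.DataFrame
    mcnemar_result: McNemarResult
    reliability: pd.DataFrame
    anova_2x2: pd.DataFrame | None
    anova_mixed: pd.DataFrame | None
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def df(d):
            return None if d is None else json.loads(d.to_json(orient="records"))

        return json.dumps(
            {
                "per_rater": df(self.per_rater),
                "group_summary": df(self.group_summary),
                "paired": df(self.paired),
                "mcnemar": self.mcnemar_result.__dict__,
                "reliability": df(self.reliability),
                "anova_2x2": df(self.anova_2x2),
                "anova_mixed": df(self.anova_mixed),
                "notes": self.notes,
                "provenance": {
                    "icc_model": "two-way mixed effects, consistency, single/average measures",
                    "kappa": "unweighted, 4 nominal categories",
                    "mcnemar": "exact binomial < 25 discordant, chi-square with continuity correction otherwise",
                },
            },
            indent=1,
            sort_keys=True,
        )

    def export_csv(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.per_rater.to_csv(os.path.join(out_dir, "per_rater.csv"), index=False)
        self.group_summary.to_csv(os.path.join(out_dir, "group_summary.csv"), index=False)
        self.paired.to_csv(os.path.join(out_dir, "paired_tests.csv"), index=False)
        self.reliability.to_csv(os.path.join(out_dir, "reliability.csv"), index=False)
        for name, df in (("anova_2x2", self.anova_2x2), ("anova_mixed", self.anova_mixed)):
            if df is not None:
                df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        with open(os.path.join(out_dir, "study_result.json"), "w") as fh:
            fh.write(self.to_json())


_RATE_METRICS = ["accuracy", "sensitivity", "specificity", "lateralisation_accuracy", "kappa"]


def _validate_table(table: pd.DataFrame, gold: pd.Series) -> None:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    bad_conf = table[["confidence_normality", "confidence_lateralisation"]].to_numpy()
    if ((bad_conf < 1) | (bad_conf > 5)).any():
        raise ValueError("confidences must be integers in 1..5")
    dup = table.duplicated(subset=["rater", "case", "condition"])
    if dup.any():
        raise ValueError("more than one record per (rater, case, condition)")
    per = table.groupby(["rater", "condition"])["case"].nunique()
    if (per != len(gold)).any():
        raise ValueError("every rater must rate every gold case in both conditions")


def analyze_study(table: pd.DataFrame, gold: pd.Series) -> StudyResult:
    """Run the complete battery on a rater-study table.

    Hierarchy: per-rater detection statistics and kappa per condition;
    group and overall summaries (unweighted means over raters); McNemar on
    pooled paired designations; paired t tests across raters per metric with
    d_z / g_z; Cronbach's alpha and ICC per condition; the 2 (correctness) x
    2 (condition) repeated-measures confidence ANOVA and the 2 x 2
    (normal/abnormal) x 3 (group) mixed ANOVA on correctly diagnosed scans.
    ANOVAs that cannot be formed (an empty cell, e.g. a rater with no
    incorrect assessment) are reported as None with a note.
    """
    gold = _as_series(gold)
    _validate_table(table, gold)
    notes: list[str] = []

    rows = []
    for (rater, condition), sub in table.groupby(["rater", "condition"], sort=True):
        ratings = sub.set_index("case")["rating"]
        cc = confusion_counts(ratings, gold)
        kap = cohen_kappa(ratings.loc[gold.index], gold)
        rows.append(
            dict(
                rater=rater,
                group=sub["group"].iloc[0],
                condition=condition,
                tp=cc.tp, tn=cc.tn, fp=cc.fp, fn=cc.fn,
                accuracy=accuracy_pct(cc),
                sensitivity=sensitivity_pct(cc),
                specificity=specificity_pct(cc),
                lateralisation_accuracy=lateralisation_accuracy_pct(ratings, gold),
                kappa=kap,
                kappa_band=kappa_band(kap),
            )
        )
    per_rater = pd.DataFrame(rows).sort_values(["group", "rater", "condition"]).reset_index(drop=True)

    # group and combined summaries: unweighted means over the group's raters
    summaries = []
    for scope, sel in [("combined", per_rater)] + [
        (g, per_rater[per_rater["group"] == g]) for g in GROUPS
    ]:
        for condition, sub in sel.groupby("condition"):
            entry = dict(scope=scope, condition=condition, n_raters=sub["rater"].nunique())
            for m in _RATE_METRICS:
                entry[f"{m}_mean"] = float(sub[m].mean())
                entry[f"{m}_sd"] = float(sub[m].std(ddof=1))
            summaries.append(entry)
    group_summary = pd.DataFrame(summaries)

    # paired contrasts with vs without report, across raters
    wide = per_rater.pivot(index="rater", columns="condition")
    paired_rows = []
    for m in _RATE_METRICS:
        x = wide[(m, "with_report")].to_numpy()
        y = wide[(m, "without_report")].to_numpy()
        try:
            r = paired_test(x, y)
            paired_rows.append(dict(metric=m, **r.__dict__,
                                    effect_label=effect_size_label(r.d_z)))
        except ZeroDivisionError:
            paired_rows.append(dict(metric=m, t=np.nan, df=len(x) - 1, p=np.nan,
                                    d_z=np.nan, g_z=np.nan, d_av=np.nan,
                                    mean_diff=float(np.mean(x - y)), sd_diff=0.0,
                                    effect_label="undefined (zero-variance differences)"))
            notes.append(f"paired test on {m}: zero-variance differences")
    paired = pd.DataFrame(paired_rows)

    # McNemar on pooled paired (rater, case) designations
    merged = table.merge(gold.rename("gold"), left_on="case", right_index=True)
    merged["correct"] = (merged["rating"] != "normal") == (merged["gold"] != "normal")
    piv = merged.pivot_table(index=["rater", "case"], columns="condition",
                             values="correct", aggfunc="first")
    b = int((piv["without_report"] & ~piv["with_report"]).sum())
    c = int((~piv["without_report"] & piv["with_report"]).sum())
    mcn = mcnemar(b, c)

    # reliability per condition on ordinally coded ratings
    rel_rows = []
    for condition, sub in merged.groupby("condition"):
        m = sub.pivot(index="case", columns="rater", values="rating").loc[gold.index]
        coded = m.apply(lambda col: col.map(_RATING_CODE)).to_numpy(dtype=float)
        rel_rows.append(
            dict(condition=condition,
                 cronbach_alpha=cronbach_alpha(coded),
                 icc_single=icc(coded, "single"),
                 icc_average=icc(coded, "average"))
        )
    reliability = pd.DataFrame(rel_rows)

    # confidence ANOVAs
    merged["correctness"] = np.where(merged["correct"], "correct", "incorrect")
    cell_means = (
        merged.groupby(["rater", "group", "condition", "correctness"])["confidence_normality"]
        .mean().rename("confidence").reset_index()
    )
    anova_2x2 = None
    try:
        anova_2x2 = confidence_anova(cell_means, dv="confidence", subject="rater",
                                     within=["correctness", "condition"])
    except UnbalancedDesignError as exc:
        notes.append(f"2x2 confidence ANOVA not formed: {exc}")

    correct_only = merged[merged["correct"]].copy()
    correct_only["normality"] = np.where(correct_only["gold"] == "normal", "normal", "abnormal")
    mixed_cells = (
        correct_only.groupby(["rater", "group", "condition", "normality"])["confidence_normality"]
        .mean().rename("confidence").reset_index()
    )
    anova_mixed = None
    try:
        anova_mixed = confidence_anova(mixed_cells, dv="confidence", subject="rater",
                                       within=["condition", "normality"], between="group")
    except UnbalancedDesignError as exc:
        notes.append(f"2x2x3 mixed confidence ANOVA not formed: {exc}")

    return StudyResult(
        per_rater=per_rater,
        group_summary=group_summary,
        paired=paired,
        mcnemar_result=mcn,
        reliability=reliability,
        anova_2x2=anova_2x2,
        anova_mixed=anova_mixed,
        notes=notes,
    )
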