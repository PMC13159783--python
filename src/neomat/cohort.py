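"""Cohort analysis: ASQ-3 scoring, group comparisons, and odds ratios.

The ASQ-3 (Ages and Stages Questionnaire, third edition) is a
parent-reported developmental screen with five domains — communication,
gross motor, fine motor, problem solving, personal-social — of six items
each, scored yes = 10 / sometimes = 5 / not yet = 0 (domain range 0–60).
A domain is abnormal below its cut-off (35 for communication, 25 for the
others, roughly two standard deviations below the age norm); a total score
of 220 or less is abnormal. With one or two missing items the domain score
is adjusted to the mean of the answered items times six; more than two
missing items leave the domain unscored. Responses are analyzable only
when completed between 21 and 26 months of corrected age.

Group comparisons of the maturation-delay biomarker (ΔHRV at 34 weeks PMA)
default to rank tests — Mann-Whitney-Wilcoxon for two categories (exact
permutation enumeration for small samples), Kruskal-Wallis beyond —
with Student/ANOVA parametric alternatives behind a flag. Categorical
associations use Fisher's exact test when any expected cell count is
below 5 (2x2 tables), chi-square otherwise. Outcome models are univariate
maximum-likelihood logistic regressions reported as odds ratios with Wald
95% confidence intervals; multivariate adjustment is deliberately not the
default because abnormal outcomes are sparse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic import ASQ_DOMAINS, ASQ_THRESHOLDS, ITEMS_PER_DOMAIN, InfantRecord

__all__ = [
    "ASQRecord",
    "ComparisonRow",
    "score_asq",
    "compare_delta_by_factor",
    "categorical_assoc",
    "logistic_or",
    "build_table1",
    "apply_inclusion_criteria",
    "InclusionFlow",
]

ITEM_POINTS = {"yes": 10, "sometimes": 5, "not_yet": 0}
TOTAL_CUTOFF = 220
AGE_WINDOW_MONTHS = (21.0, 26.0)
MAX_MISSING_ITEMS = 2

#: Mann-Whitney comparisons at or below this combined sample size use exact
#: permutation enumeration (handles ties; p = 1 for identical groups)
EXACT_MWW_MAX_N = 20


# ---------------------------------------------------------------------------
# ASQ scoring
# ---------------------------------------------------------------------------


@dataclass
class ASQRecord:
    """ASQ-3 item responses and (after scoring) domain/total results."""

    patient_id: str
    age_months: float
    responses: dict[str, list[str | None]]
    domain_scores: dict[str, float | None] = field(default_factory=dict)
    domain_abnormal: dict[str, bool | None] = field(default_factory=dict)
    total_score: float | None = None
    total_abnormal: bool | None = None
    analyzable: bool = True


def _score_domain(items: Sequence[str | None]) -> float | None:
    pts, n_missing = [], 0
    for item in items:
        if item is None or item == "missing":
            n_missing += 1
            continue
        if item not in ITEM_POINTS:
            raise ValueError(
                f"invalid ASQ response {item!r}; expected one of "
                f"{sorted(ITEM_POINTS)} or 'missing'"
            )
        pts.append(ITEM_POINTS[item])
    if n_missing > MAX_MISSING_ITEMS:
        return None
    if n_missing:
        return sum(pts) / len(pts) * ITEMS_PER_DOMAIN
    return float(sum(pts))


def score_asq(record: ASQRecord) -> ASQRecord:
    """Score an ASQ record: domain scores, abnormality flags, total.

    Returns a new record; the input is not modified. A record completed
    outside 21-26 months of corrected age is flagged ``analyzable=False``
    (scores are still computed).
    """
    scores: dict[str, float | None] = {}
    flags: dict[str, bool | None] = {}
    for domain in ASQ_DOMAINS:
        items = record.responses.get(domain, [])
        if len(items) != ITEMS_PER_DOMAIN:
            raise ValueError(
                f"domain {domain!r} has {len(items)} items, expected {ITEMS_PER_DOMAIN}"
            )
        score = _score_domain(items)
        scores[domain] = score
        flags[domain] = None if score is None else score < ASQ_THRESHOLDS[domain]
    if any(s is None for s in scores.values()):
        total: float | None = None
        total_abnormal: bool | None = None
    else:
        total = float(sum(scores.values()))  # type: ignore[arg-type]
        total_abnormal = total <= TOTAL_CUTOFF
    lo, hi = AGE_WINDOW_MONTHS
    return ASQRecord(
        patient_id=record.patient_id,
        age_months=record.age_months,
        responses=record.responses,
        domain_scores=scores,
        domain_abnormal=flags,
        total_score=total,
        total_abnormal=total_abnormal,
        analyzable=lo <= record.age_months <= hi,
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class ComparisonRow:
    """One category row of a descriptive comparison table."""

    variable: str
    category: str
    n: int
    percent: float
    median: float
    q1: float
    q3: float
    test_name: str
    p_value: float


def _exact_rank_p(groups: list[np.ndarray]) -> float:
    """Two-sided exact permutation p-value for the 2-group rank-sum test."""
    from itertools import combinations

    x, y = groups
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    expected = n1 * (len(pooled) + 1) / 2.0
    observed = abs(ranks[:n1].sum() - expected)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        s = abs(ranks[list(idx)].sum() - expected)
        total += 1
        if s >= observed - 1e-12:
            count += 1
    return count / total


def compare_delta_by_factor(
    df: pd.DataFrame,
    variable: str,
    value_col: str = "delta34_weeks",
    parametric: bool = False,
) -> list[ComparisonRow]:
    """Describe and test ΔHRV across the categories of one factor.

    Reports N (%) and median (Q1; Q3) per category; the test is
    Mann-Whitney-Wilcoxon for two categories (exact for small samples) or
    Kruskal-Wallis beyond, with Student's t / one-way ANOVA when
    ``parametric=True``. Empty categories are dropped with a warning.
    """
    if variable not in df.columns:
        raise KeyError(f"variable {variable!r} not in data")
    data = df[[variable, value_col]].dropna()
    cats = [c for c in data[variable].unique()]
    try:
        cats = sorted(cats)
    except TypeError:
        cats = sorted(cats, key=str)
    groups = [data.loc[data[variable] == c, value_col].to_numpy(float) for c in cats]
    nonempty = [(c, g) for c, g in zip(cats, groups) if g.size > 0]
    if len(nonempty) < len(groups):
        warnings.warn(f"dropping empty categories of {variable!r}", stacklevel=2)
    cats, groups = [c for c, _ in nonempty], [g for _, g in nonempty]
    if len(groups) < 2:
        raise ValueError(f"variable {variable!r} needs at least 2 non-empty categories")
    total_n = sum(g.size for g in groups)
    if parametric:
        if len(groups) == 2:
            test_name = "student_t"
            p = float(stats.ttest_ind(*groups).pvalue)
        else:
            test_name = "anova"
            p = float(stats.f_oneway(*groups).pvalue)
    elif len(groups) == 2:
        if total_n <= EXACT_MWW_MAX_N:
            test_name = "mann_whitney_exact"
            p = _exact_rank_p(groups)
        else:
            test_name = "mann_whitney"
            p = float(stats.mannwhitneyu(*groups, alternative="two-sided").pvalue)
    else:
        test_name = "kruskal_wallis"
        p = float(stats.kruskal(*groups).pvalue)
    rows = []
    for c, g in zip(cats, groups):
        q1, med, q3 = np.quantile(g, [0.25, 0.5, 0.75])
        rows.append(
            ComparisonRow(
                variable=variable,
                category=str(c),
                n=int(g.size),
                percent=round(100.0 * g.size / total_n, 1),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                test_name=test_name,
                p_value=p,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Categorical association and logistic odds ratios
# ---------------------------------------------------------------------------


@dataclass
class CategoricalTest:
    test_name: str
    p_value: float
    min_expected: float
    note: str = ""


def categorical_assoc(table) -> CategoricalTest:
    """Chi-square or Fisher's exact test on a two-way count table.

    Fisher's exact test is chosen for 2x2 tables with any expected cell
    count below 5; otherwise chi-square (without continuity correction).
    The dispatch is a pure function of the table and is recorded in the
    result.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("table must be a 2-D array of non-negative integer counts")
    row_m, col_m = counts.sum(axis=1), counts.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0):
        raise ValueError("degenerate table: zero row or column margin")
    expected = np.outer(row_m, col_m) / counts.sum()
    min_exp = float(expected.min())
    if counts.shape == (2, 2) and min_exp < 5:
        p = float(stats.fisher_exact(counts.astype(int))[1])
        return CategoricalTest("fisher_exact", p, min_exp)
    res = stats.chi2_contingency(counts, correction=False)
    note = "" if min_exp >= 5 else "expected count < 5 in a non-2x2 table"
    return CategoricalTest("chi_square", float(res.pvalue), min_exp, note)


@dataclass
class LogisticOrResult:
    """Univariate logistic regression summarized as an odds ratio."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    n: int
    n_events: int
    separation: bool = False


def logistic_or(
    df: pd.DataFrame, outcome: str, predictor: str
) -> LogisticOrResult:
    """Univariate ML logistic fit of a binary outcome on one predictor.

    The odds ratio is per unit of the predictor (per week for ΔHRV) with a
    Wald 95% CI. Complete separation is detected and reported as a flagged
    result with an infinite-OR sentinel instead of silently diverging.
    """
    data = df[[outcome, predictor]].dropna()
    y = data[outcome].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise ValueError(f"outcome {outcome!r} must be binary with both classes present")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se) or abs(coef) > 15 or se > 10:
            raise PerfectSeparationError("separation")
        return LogisticOrResult(
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p_value=float(res.pvalues[1]),
            coef=coef,
            n=int(y.size),
            n_events=int(y.sum()),
        )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        sign = 1.0 if np.mean(x[y == 1]) >= np.mean(x[y == 0]) else -1.0
        inf = math.inf if sign > 0 else 0.0
        return LogisticOrResult(
            odds_ratio=inf,
            ci_low=0.0,
            ci_high=math.inf,
            p_value=float("nan"),
            coef=sign * math.inf,
            n=int(y.size),
            n_events=int(y.sum()),
            separation=True,
        )


# ---------------------------------------------------------------------------
# Inclusion flow and descriptive tables
# ---------------------------------------------------------------------------


@dataclass
class InclusionFlow:
    """Counts along the cohort inclusion filter."""

    n_eligible: int
    n_no_ecg: int
    n_model_training: int
    n_included: int
    n_followup: int

    @property
    def followup_percent(self) -> int:
        return round(100.0 * self.n_followup / self.n_included)

    @property
    def included_percent(self) -> float:
        return round(100.0 * self.n_included / self.n_eligible, 1)


def apply_inclusion_criteria(
    records: Sequence[InfantRecord],
) -> tuple[list[InfantRecord], InclusionFlow]:
    """Apply the study's exclusions to eligible (<30-week-GA) records.

    Excludes infants without the necessary ECG recordings and infants used
    to train the maturation model; counts ASQ follow-up among the included.
    """
    no_ecg = [r for r in records if not r.has_ecg]
    training = [r for r in records if r.has_ecg and r.used_for_training]
    included = [r for r in records if r.has_ecg and not r.used_for_training]
    flow = InclusionFlow(
        n_eligible=len(records),
        n_no_ecg=len(no_ecg),
        n_model_training=len(training),
        n_included=len(included),
        n_followup=sum(1 for r in included if r.followup),
    )
    return included, flow


#: Table-1-style variable blocks (cohort columns; categorical 0/1 unless
#: listed as a stratification)
TABLE1_VARIABLES = (
    "hypertension",
    "chorioamnionitis",
    "prom",
    "diabetes",
    "betamethasone",
    "magnesium",
    "tobacco",
    "ga_stratum",
    "sex",
    "apgar5_lt7",
    "ventilation",
    "chest_compression",
    "late_onset_sepsis",
    "nec",
    "neuro_lesions",
    "bpd",
    "pda",
)


def build_table1(
    cohort: pd.DataFrame,
    value_col: str = "delta34_weeks",
    variables: Sequence[str] = TABLE1_VARIABLES,
) -> pd.DataFrame:
    """Descriptive table: N (%), ΔHRV median (Q1; Q3) and p per variable.

    Variables absent from the cohort are omitted with a warning; the
    percent denominators exclude rows missing that variable.
    """
    rows: list[ComparisonRow] = []
    for var in variables:
        if var not in cohort.columns:
            warnings.warn(f"variable {var!r} absent from cohort; omitted", stacklevel=2)
            continue
        try:
            rows.extend(compare_delta_by_factor(cohort, var, value_col=value_col))
        except ValueError as exc:
            warnings.warn(f"variable {var!r} skipped: {exc}", stacklevel=2)
    return pd.DataFrame([r.__dict__ for r in rows])


def asq_outcome_table(
    cohort: pd.DataFrame, value_col: str = "delta34_weeks"
) -> pd.DataFrame:
    """ΔHRV by abnormal/normal status of each scored ASQ domain."""
    rows: list[ComparisonRow] = []
    for domain in ASQ_DOMAINS:
        col = f"asq_{domain}_abnormal"
        if col not in cohort.columns:
            continue
        try:
            rows.extend(compare_delta_by_factor(cohort, col, value_col=value_col))
        except ValueError:
            continue  # e.g. no abnormal cases in the domain
    return pd.DataFrame([r.__dict__ for r in rows])
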