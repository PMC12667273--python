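"""Stratified cohort statistics for the detected sleep parameters.

All group statistics aggregate to the participant level first (one mean
per participant per parameter) so that nights are never treated as
independent observations; standard errors are across participants.
Group comparisons use Student's pooled-variance two-sample t-test
(Welch behind a flag) and one-way ANOVA at alpha = 0.05 per contrast,
without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

__all__ = [
    "GroupSummary", "FitResult", "EffectSize", "TestResult",
    "participant_means", "summarize_groups", "weekday_weekend_contrast",
    "fit_age_trend", "cohens_d", "two_sample_t", "oneway_anova",
    "dichotomize_symptom", "selfreport_association_report", "age_bin_midpoint",
]

WEEKEND_DOW = ("Sat", "Sun")

SYMPTOM_NO = "not at all"
SYMPTOM_YES = ("several days", "more than half the days", "nearly every day")


@dataclass
class GroupSummary:
    stratum: tuple
    parameter: str
    n: int
    mean: float
    se: float            # sample SD / sqrt(n); NaN when n < 2
    pct_of_total: float  # 100 * n / N, rounded to 2 decimals


@dataclass
class FitResult:
    parameter: str
    sex: str
    order: int
    coefficients: np.ndarray  # ascending powers
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))


@dataclass
class EffectSize:
    d: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not self.ci_lo <= self.d <= self.ci_hi:
            raise ValueError("confidence interval must bracket d")


@dataclass
class TestResult:
    kind: str            # "t_two_sample" | "anova_oneway"
    statistic: float
    df: tuple
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# group summaries

def participant_means(nights: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: mean onset/wake/duration over their nights."""
    g = nights.groupby("participant_id")[["onset_min", "wake_min", "duration_min"]].mean()
    g.columns = ["onset", "wake", "duration"]
    g["n_nights"] = nights.groupby("participant_id").size()
    return g.reset_index()


def summarize_groups(
    nights: pd.DataFrame,
    participants: pd.DataFrame,
    by: tuple = ("sex", "age_bin"),
    parameters: tuple = ("onset", "wake", "duration"),
    n_total: int | None = None,
) -> pd.DataFrame:
    """n / mean / SE per stratum per parameter, participant-level first.

    ``parameters`` may include ``wake_activity`` if the participants
    table carries it.  ``pct_of_total`` uses ``n_total`` (default: the
    number of participants present).
    """
    means = participant_means(nights).merge(participants, on="participant_id", how="inner")
    n_total = len(means) if n_total is None else n_total
    rows = []
    for key, grp in means.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for param in parameters:
            vals = grp[param].dropna().to_numpy()
            n = vals.size
            if n == 0:
                continue
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
            rows.append({
                **dict(zip(by, key)), "parameter": param, "n": n,
                "mean": float(vals.mean()), "se": se,
                "pct_of_total": round(100.0 * n / n_total, 2),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# weekday/weekend

def weekday_weekend_contrast(
    nights: pd.DataFrame,
    participants: pd.DataFrame,
    by: tuple = ("sex", "age_bin"),
    parameter: str = "duration_min",
    weekend_dow: tuple = WEEKEND_DOW,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum weekend-minus-weekday mean difference with paired t.

    The contrast is formed within participant (mean over weekend nights
    minus mean over weekday nights, by wake-day label) and then averaged
    across participants; participants lacking either night type are
    dropped and counted in ``n_dropped``.
    """
    df = nights.copy()
    df["is_weekend"] = df["dow"].isin(weekend_dow)
    per = df.pivot_table(index="participant_id", columns="is_weekend",
                         values=parameter, aggfunc="mean")
    per = per.rename(columns={False: "weekday", True: "weekend"})
    for col in ("weekday", "weekend"):
        if col not in per.columns:
            per[col] = np.nan
    per["diff"] = per["weekend"] - per["weekday"]
    merged = per.reset_index().merge(participants, on="participant_id", how="inner")
    rows = []
    for key, grp in merged.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        diffs = grp["diff"].dropna().to_numpy()
        n_dropped = int(grp["diff"].isna().sum())
        if diffs.size < 2:
            continue
        t, p = stats.ttest_1samp(diffs, 0.0)
        rows.append({
            **dict(zip(by, key)), "parameter": parameter,
            "n": diffs.size, "n_dropped": n_dropped,
            "mean_diff": float(diffs.mean()),
            "se": float(np.std(diffs, ddof=1) / np.sqrt(diffs.size)),
            "t": float(t), "df": diffs.size - 1, "p_value": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trends, effect sizes, tests

def age_bin_midpoint(label: str) -> float:
    lo, hi = label.split("-")
    return (float(lo) + float(hi)) / 2.0


def fit_age_trend(x: np.ndarray, y: np.ndarray, order: int,
                  parameter: str = "", sex: str = "") -> FitResult:
    """OLS polynomial fit of group means against age-bin midpoints."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if x.size < order + 2:
        raise ValueError(f"need at least {order + 2} points for order {order}")
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=order)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return FitResult(parameter=parameter, sex=sex, order=order,
                     coefficients=coeffs, r_squared=r2)


def cohens_d(a, b, alpha: float = 0.05) -> EffectSize:
    """Cohen's d with a normal-approximation confidence interval.

    d = (mean_a - mean_b) / pooled SD, pooled with n-1 weights and no
    small-sample correction; the CI uses the usual large-sample variance
    (na+nb)/(na*nb) + d^2 / (2*(na+nb-2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((a.mean() - b.mean()) / pooled)
    se = np.sqrt((na + nb) / (na * nb) + d * d / (2 * (na + nb - 2)))
    z = stats.norm.ppf(1 - alpha / 2)
    return EffectSize(d=d, ci_lo=d - z * se, ci_hi=d + z * se)


def two_sample_t(a, b, alpha: float = 0.05, welch: bool = False) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TestResult(kind="t_two_sample", statistic=float(res.statistic),
                      df=(df,), p_value=float(res.pvalue),
                      significant=bool(res.pvalue < alpha))


def oneway_anova(groups: list, alpha: float = 0.05) -> TestResult:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    return TestResult(kind="anova_oneway", statistic=float(f),
                      df=(k - 1, n - k), p_value=float(p),
                      significant=bool(p < alpha))


def dichotomize_symptom(response: str) -> str:
    """Map the four frequency options onto No ("not at all") vs Yes."""
    if response == SYMPTOM_NO:
        return "No"
    if response in SYMPTOM_YES:
        return "Yes"
    raise ValueError(f"unknown symptom response {response!r}")


# ---------------------------------------------------------------------------
# self-report associations

def selfreport_association_report(
    nights: pd.DataFrame,
    participants: pd.DataFrame,
    reports: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    reported_hours_groups: tuple = (6, 7, 8, 9),
) -> dict:
    """Objective sleep/activity by self-report level, with tests.

    Returns a dict of two tidy tables: ``"reported_hours"`` (objective
    duration by reported 6-9 h group per sex x age bin, one-way ANOVA)
    and ``"binary_items"`` (Yes/No summaries of onset, wake, duration
    and wake activity for the sleep items and the dichotomized mood
    items, two-sample t-tests).  Cells with fewer than two participants
    per level are skipped.
    """
    alpha = cfg.alpha if cfg is not None else 0.05
    welch = cfg.welch if cfg is not None else False
    data = participant_means(nights).merge(participants, on="participant_id") \
                                    .merge(reports, on="participant_id")
    for item in ("depression", "anhedonia"):
        data[f"{item}_yes"] = data[item].map(dichotomize_symptom)

    hour_rows = []
    for (sex, age_bin), grp in data.groupby(["sex", "age_bin"], sort=True):
        groups = [grp.loc[grp["reported_hours"] == h, "duration"].to_numpy()
                  for h in reported_hours_groups]
        kept = [(h, g) for h, g in zip(reported_hours_groups, groups) if g.size >= 2]
        if len(kept) < 2:
            continue
        test = oneway_anova([g for _, g in kept], alpha=alpha)
        for h, g in kept:
            hour_rows.append({
                "sex": sex, "age_bin": age_bin, "reported_hours": h,
                "n": g.size, "mean_duration": float(g.mean()),
                "se": float(np.std(g, ddof=1) / np.sqrt(g.size)),
                "F": test.statistic, "df1": test.df[0], "df2": test.df[1],
                "p_value": test.p_value, "significant": test.significant,
            })

    binary_items = {
        "too_much_sleep": "too_much_sleep",
        "waking_too_early": "waking_too_early",
        "depression": "depression_yes",
        "anhedonia": "anhedonia_yes",
    }
    params = ["onset", "wake", "duration"]
    if "wake_activity" in data.columns:
        params.append("wake_activity")
    bin_rows = []
    for item, col in binary_items.items():
        for (sex, age_bin), grp in data.groupby(["sex", "age_bin"], sort=True):
            for param in params:
                yes = grp.loc[grp[col] == "Yes", param].dropna().to_numpy()
                no = grp.loc[grp[col] == "No", param].dropna().to_numpy()
                if yes.size < 2 or no.size < 2:
                    continue
                test = two_sample_t(yes, no, alpha=alpha, welch=welch)
                bin_rows.append({
                    "item": item, "sex": sex, "age_bin": age_bin, "parameter": param,
                    "n_yes": yes.size, "n_no": no.size,
                    "mean_yes": float(yes.mean()), "mean_no": float(no.mean()),
                    "se_yes": float(np.std(yes, ddof=1) / np.sqrt(yes.size)),
                    "se_no": float(np.std(no, ddof=1) / np.sqrt(no.size)),
                    "t": test.statistic, "df": test.df[0],
                    "p_value": test.p_value, "significant": test.significant,
                })
    return {"reported_hours": pd.DataFrame(hour_rows),
            "binary_items": pd.DataFrame(bin_rows)}
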