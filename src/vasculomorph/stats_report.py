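"""Group-comparison statistics for vascular metrics.

One-way ANOVA with Tukey HSD post hoc tests, two-way (e.g. age x sex) ANOVA
with Sidak-adjusted within-age sex comparisons, covariance ellipses for
metric scatter plots, and advisory normality checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaEffect",
    "PairwiseComparison",
    "AnovaResult",
    "CovarianceEllipse",
    "compare_one_way",
    "compare_two_way",
    "covariance_ellipse",
    "normality_report",
]

AGE_BINS = ("1-3", "4-6", "7-9", "12-15")  # months
SEXES = ("M", "F")


@dataclass
class GroupSample:
    """Values of one metric with their group labels.

    ``groups`` is the primary factor (e.g. age bin); ``sex`` optionally adds
    the second factor for two-way designs.
    """

    metric: str
    values: np.ndarray
    groups: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
            if len(self.sex) != len(self.values):
                raise ValueError("sex labels must match values")
        if len(self.groups) != len(self.values):
            raise ValueError("group labels must match values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric: str) -> "GroupSample":
        """Build from a tidy frame with columns age_bin, sex, metric, value."""
        sub = df[df["metric"] == metric]
        if sub.empty:
            raise ValueError(f"no rows for metric {metric!r}")
        sex = sub["sex"].to_numpy() if "sex" in sub.columns else None
        return cls(metric, sub["value"].to_numpy(), sub["age_bin"].to_numpy(), sex)


@dataclass
class AnovaEffect:
    name: str
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float


@dataclass
class PairwiseComparison:
    label: str
    difference: float
    p_adjusted: float
    method: str


@dataclass
class AnovaResult:
    design: str
    effects: list[AnovaEffect]
    posthoc: list[PairwiseComparison]

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.effects])


def compare_one_way(sample: GroupSample, posthoc: bool = True) -> AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise post hoc comparisons.

    The F statistic is computed from explicit between/within sums of squares
    (MSB/MSW); the p-value comes from the F(k-1, n-k) survival function.
    With zero between-group variance the result is F = 0, p = 1.
    """
    labels = list(dict.fromkeys(sample.groups.tolist()))
    if len(labels) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    arrays = [sample.values[sample.groups == g] for g in labels]
    for g, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    n = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = float(np.concatenate(arrays).mean())
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = 1.0 if f == 0 else float(sps.f.sf(f, df_b, df_w))
    effects = [AnovaEffect("group", float(f), df_b, df_w, p)]

    comparisons: list[PairwiseComparison] = []
    if posthoc:
        tk = sps.tukey_hsd(*arrays)
        for i in range(k):
            for j in range(i + 1, k):
                comparisons.append(
                    PairwiseComparison(
                        label=f"{labels[i]} vs {labels[j]}",
                        difference=float(np.mean(arrays[i]) - np.mean(arrays[j])),
                        p_adjusted=float(tk.pvalue[i, j]),
                        method="tukey",
                    )
                )
    return AnovaResult("one-way", effects, comparisons)


def compare_two_way(sample: GroupSample, ss_type: int = 2) -> AnovaResult:
    """Two-way ANOVA (primary factor x sex) with Sidak post hoc tests.

    Main effects and the interaction use Type II sums of squares by default
    (Type III via ``ss_type=3``), tolerating mild imbalance. The Sidak family
    is the within-level male-vs-female comparisons, one per level of the
    primary factor, using the pooled residual variance of the full model.
    """
    if sample.sex is None:
        raise ValueError("two-way design requires sex labels")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": sample.values, "a": sample.groups, "b": sample.sex})
    levels_a = list(dict.fromkeys(df["a"].tolist()))
    levels_b = list(dict.fromkeys(df["b"].tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need >= 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if ((df["a"] == la) & (df["b"] == lb)).sum() == 0:
                raise ValueError(f"empty cell: ({la!r}, {lb!r})")

    if np.ptp(sample.values) == 0:  # all values identical: every effect is null
        effects = [AnovaEffect(n, 0.0, len(levels_a) - 1, 0.0, 1.0) for n in ("group", "sex", "interaction")]
        posthoc = [
            PairwiseComparison(f"{la}: {levels_b[0]} vs {levels_b[1]}", 0.0, 1.0, "sidak")
            for la in levels_a
        ]
        return AnovaResult("two-way", effects, posthoc)

    if ss_type == 3:
        model = smf.ols(
            "value ~ C(a, Sum) * C(b, Sum)", data=df
        ).fit()
        table = sm.stats.anova_lm(model, typ=3).drop(index="Intercept")
    else:
        model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)

    name_map = {}
    for idx in table.index:
        if idx == "Residual":
            continue
        if ":" in idx:
            name_map[idx] = "interaction"
        elif "C(a" in idx:
            name_map[idx] = "group"
        else:
            name_map[idx] = "sex"
    df_resid = float(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"]) / df_resid
    effects = []
    for idx in table.index:
        if idx == "Residual":
            continue
        f_val = float(table.loc[idx, "F"])
        p_val = float(table.loc[idx, "PR(>F)"])
        if not np.isfinite(f_val):  # zero residual variance
            f_val, p_val = (0.0, 1.0) if float(table.loc[idx, "sum_sq"]) < 1e-12 else (float("inf"), 0.0)
        effects.append(
            AnovaEffect(name_map[idx], f_val, float(table.loc[idx, "df"]), df_resid, p_val)
        )

    # Sidak: within-level sex comparisons against the pooled residual variance
    m = len(levels_a)
    posthoc = []
    b0, b1 = levels_b[0], levels_b[1]
    for la in levels_a:
        v0 = df.loc[(df["a"] == la) & (df["b"] == b0), "value"].to_numpy()
        v1 = df.loc[(df["a"] == la) & (df["b"] == b1), "value"].to_numpy()
        diff = float(np.mean(v0) - np.mean(v1))
        se = np.sqrt(mse * (1.0 / len(v0) + 1.0 / len(v1)))
        if se == 0:
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p_raw = 2.0 * sps.t.sf(abs(t), df_resid)
        p_adj = 1.0 - (1.0 - p_raw) ** m
        posthoc.append(
            PairwiseComparison(
                label=f"{la}: {b0} vs {b1}", difference=diff, p_adjusted=float(p_adj), method="sidak"
            )
        )
    return AnovaResult("two-way", effects, posthoc)


@dataclass
class CovarianceEllipse:
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float  # principal axis angle in [-90, 90)
    coverage_k: float
    covariance_sign: int
    correlation: float

    def boundary(self, n: int = 100) -> np.ndarray:
        """(n, 2) points on the ellipse boundary, for plotting."""
        t = np.linspace(0, 2 * np.pi, n)
        th = np.deg2rad(self.orientation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = rot @ np.vstack([self.semi_major * np.cos(t), self.semi_minor * np.sin(t)])
        return pts.T + np.asarray(self.center)


def covariance_ellipse(x: np.ndarray, y: np.ndarray, k: float = 2.0) -> CovarianceEllipse:
    """Covariance ellipse of paired points: axes k * sqrt(eigenvalues).

    Orientation is the principal eigenvector's angle, mapped into [-90, 90).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate input: all points identical")
    cov = np.cov(x, y, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    major_vec = evecs[:, 1]
    angle = np.degrees(np.arctan2(major_vec[1], major_vec[0]))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    denom = np.sqrt(cov[0, 0] * cov[1, 1])
    corr = float(cov[0, 1] / denom) if denom > 0 else 0.0
    return CovarianceEllipse(
        center=(float(np.mean(x)), float(np.mean(y))),
        semi_major=float(k * np.sqrt(evals[1])),
        semi_minor=float(k * np.sqrt(evals[0])),
        orientation_deg=float(angle),
        coverage_k=float(k),
        covariance_sign=int(np.sign(cov[0, 1])),
        correlation=corr,
    )


def normality_report(values: np.ndarray) -> dict:
    """Advisory normality checks; never gates the ANOVA."""
    values = np.asarray(values, dtype=float)
    out: dict = {"n": int(len(values))}
    if len(values) >= 8:
        k2, p = sps.normaltest(values)
        out["dagostino_pearson_p"] = float(p)
    if 3 <= len(values) <= 5000:
        w, p = sps.shapiro(values)
        out["shapiro_wilk_p"] = float(p)
    return out
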