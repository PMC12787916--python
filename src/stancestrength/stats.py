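"""Benchmarking statistics for stratified relative-strength data.

Implements the analysis layer that turns per-participant relative
strength scores (N/kg) into normative benchmarks:

* percent difference between group means, 100 * (M1 - M2) / M2;
* independent-samples t-tests (pooled-variance Student by default,
  Welch by flag) with the percent difference attached;
* one-way ANOVA with the Games-Howell post hoc test (pairwise Welch
  standard errors, Welch-Satterthwaite degrees of freedom, p-values
  from the studentized-range distribution);
* two-way ANOVA (sex x age group) with Type II sums of squares —
  identical to the classical decomposition when the design is balanced
  — and partial eta squared as the effect size;
* normative tables (stratum x direction -> n, mean, SD) and per-patient
  deficit reports (z-score, percent of norm, percent deficit).

No multiple-testing correction is applied across the six directions by
default; a Bonferroni flag exists for callers who want one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import AGE_GROUPS, DIRECTION_CODES, SEXES, AssessmentResult

__all__ = [
    "GroupSummary",
    "TTestComparison",
    "AnovaRow",
    "GamesHowellPair",
    "NormativeTable",
    "DeficitReport",
    "StatsError",
    "percent_difference",
    "independent_t",
    "one_way_anova",
    "games_howell",
    "two_way_anova",
    "f_from_ss",
    "partial_eta_squared",
    "build_normative_table",
    "deficit_score",
    "ALPHA",
]

ALPHA = 0.05


class StatsError(ValueError):
    """Degenerate or invalid statistical input."""


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError(f"group {self.label!r} needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise StatsError(f"group {self.label!r} has negative sd")


@dataclass(frozen=True)
class TTestComparison:
    group1: GroupSummary
    group2: GroupSummary
    t: float
    df: float
    p: float
    pct_diff: float
    variant: str


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float
    f: float | None
    p: float | None
    eta_p2: float | None


@dataclass(frozen=True)
class GamesHowellPair:
    group_i: str
    group_j: str
    mean_diff: float
    se: float
    df_welch: float
    q: float
    p_adj: float


def percent_difference(m1: float, m2: float) -> float:
    """Percent difference between two means relative to the second: 100*(M1-M2)/M2."""
    if m2 == 0:
        raise StatsError("percent difference undefined against a zero reference mean")
    return 100.0 * (m1 - m2) / m2


def _summary(x: np.ndarray, label: str) -> GroupSummary:
    return GroupSummary(label=label, n=len(x), mean=float(x.mean()),
                        sd=float(x.std(ddof=1)))


def independent_t(
    group1: Sequence[float],
    group2: Sequence[float],
    variant: str = "student",
    labels: tuple[str, str] = ("group1", "group2"),
) -> TTestComparison:
    """Two-sided independent-samples t-test with the percent difference attached.

    ``variant='student'`` pools the variances (df = n1 + n2 - 2);
    ``'welch'`` uses the unequal-variance form with Welch-Satterthwaite df.
    """
    if variant not in ("student", "welch"):
        raise StatsError(f"variant must be 'student' or 'welch', got {variant!r}")
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise StatsError("each group needs at least 2 observations")
    if x1.std(ddof=1) == 0 and x2.std(ddof=1) == 0 and x1.mean() == x2.mean():
        raise StatsError("t statistic undefined: both groups constant and equal")
    res = sps.ttest_ind(x1, x2, equal_var=(variant == "student"))
    return TTestComparison(
        group1=_summary(x1, labels[0]),
        group2=_summary(x2, labels[1]),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        pct_diff=percent_difference(float(x1.mean()), float(x2.mean())),
        variant=variant,
    )


def one_way_anova(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None) -> list[AnovaRow]:
    """One-way fixed-effects ANOVA from the between/within decomposition."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("one-way ANOVA needs at least two groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise StatsError(f"group {i} needs at least 2 observations")
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in arrays))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    df_between = len(arrays) - 1
    df_within = len(all_x) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            raise StatsError("F undefined: zero variance between and within groups")
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return [
        AnovaRow("between", ss_between, df_between, ms_between, f_stat, p,
                 ss_between / (ss_between + ss_within) if (ss_between + ss_within) else None),
        AnovaRow("within", ss_within, df_within, ms_within, None, None, None),
    ]


def games_howell(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None) -> list[GamesHowellPair]:
    """Games-Howell pairwise post hoc test.

    Robust to unequal variances and sample sizes: each pair uses its own
    Welch standard error sqrt(s_i^2/n_i + s_j^2/n_j) and
    Welch-Satterthwaite df; q = |diff| * sqrt(2) / se is referred to the
    studentized-range distribution with k groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise StatsError("Games-Howell needs at least two groups")
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(k)]
    means = [float(g.mean()) for g in arrays]
    variances = [float(g.var(ddof=1)) for g in arrays]
    ns = [len(g) for g in arrays]
    for i, (n, v) in enumerate(zip(ns, variances)):
        if n < 2:
            raise StatsError(f"group {labels[i]} needs at least 2 observations")
    out = []
    for i, j in combinations(range(k), 2):
        vi, vj = variances[i] / ns[i], variances[j] / ns[j]
        se = float(np.sqrt(vi + vj))
        if se == 0.0:
            raise StatsError(
                f"degenerate pair ({labels[i]}, {labels[j]}): zero variance in both groups"
            )
        df = (vi + vj) ** 2 / (
            vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1)
        )
        diff = means[i] - means[j]
        q = abs(diff) * np.sqrt(2.0) / se
        p_adj = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        out.append(
            GamesHowellPair(
                group_i=labels[i],
                group_j=labels[j],
                mean_diff=diff,
                se=se,
                df_welch=float(df),
                q=float(q),
                p_adj=p_adj,
            )
        )
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of an OLS fit (rank-deficiency tolerant)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _dummies(levels: np.ndarray) -> np.ndarray:
    uniq = np.unique(levels)
    return (levels[:, None] == uniq[None, 1:]).astype(float)


def two_way_anova(
    data: Mapping[tuple[str, str], Sequence[float]],
    factor_names: tuple[str, str] = ("gender", "age_group"),
) -> list[AnovaRow]:
    """Two-way fixed-effects ANOVA with Type II sums of squares.

    ``data`` maps (level_a, level_b) cells to observations; every cell
    must be non-empty.  Type II attributes to each main effect the
    reduction in residual SS it provides given the other main effect
    (SS(A|B), SS(B|A)); the interaction is tested against the additive
    model.  With balanced cells this coincides with the classical
    orthogonal decomposition.  Effect size is partial eta squared.
    """
    cells = {key: np.asarray(v, dtype=float) for key, v in data.items()}
    if not cells:
        raise StatsError("no data")
    for key, v in cells.items():
        if len(v) == 0:
            raise StatsError(f"empty cell {key}")
    y = np.concatenate(list(cells.values()))
    a = np.concatenate([np.full(len(v), key[0]) for key, v in cells.items()])
    b = np.concatenate([np.full(len(v), key[1]) for key, v in cells.items()])
    n = len(y)
    levels_a, levels_b = np.unique(a), np.unique(b)
    df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
    df_ab = df_a * df_b
    n_cells = len(levels_a) * len(levels_b)
    if len(cells) < n_cells:
        raise StatsError("every factor-level combination needs at least one observation")
    df_err = n - n_cells
    if df_err < 1:
        raise StatsError("no residual degrees of freedom")

    ones = np.ones((n, 1))
    A = _dummies(a)
    B = _dummies(b)
    AB = np.hstack([A[:, [i]] * B[:, [j]] for i in range(A.shape[1]) for j in range(B.shape[1])]) \
        if df_ab else np.empty((n, 0))

    rss_a = _rss(y, np.hstack([ones, A]))
    rss_b = _rss(y, np.hstack([ones, B]))
    rss_ab_add = _rss(y, np.hstack([ones, A, B]))
    rss_full = _rss(y, np.hstack([ones, A, B, AB]))

    ss_a = rss_b - rss_ab_add  # SS(A | B)
    ss_b = rss_a - rss_ab_add  # SS(B | A)
    ss_inter = rss_ab_add - rss_full
    ss_err = rss_full
    ms_err = ss_err / df_err

    def row(source: str, ss: float, df: int) -> AnovaRow:
        ss = max(ss, 0.0)  # guard tiny negative round-off
        ms = ss / df
        f = ms / ms_err if ms_err > 0 else float("inf")
        p = float(sps.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return AnovaRow(source, ss, df, ms, f, p, eta)

    return [
        row(factor_names[0], ss_a, df_a),
        row(factor_names[1], ss_b, df_b),
        row("interaction", ss_inter, df_ab),
        AnovaRow("error", ss_err, df_err, ms_err, None, None, None),
    ]


def f_from_ss(ss_effect: float, df_effect: int, ss_error: float, df_error: int) -> float:
    """F statistic from sums of squares: (SS_e/df_e) / (SS_err/df_err)."""
    if df_effect < 1 or df_error < 1:
        raise StatsError("degrees of freedom must be >= 1")
    if ss_effect < 0 or ss_error < 0:
        raise StatsError("sums of squares must be non-negative")
    if ss_error == 0:
        raise StatsError("F undefined with zero error sum of squares")
    return (ss_effect / df_effect) / (ss_error / df_error)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error <= 0:
        if ss_effect == 0 and ss_error == 0:
            raise StatsError("partial eta squared undefined: both sums of squares zero")
        if ss_error <= 0:
            raise StatsError("ss_error must be > 0")
        raise StatsError("ss_effect must be >= 0")
    return ss_effect / (ss_effect + ss_error)


@dataclass
class NormativeTable:
    """Stratum (sex, age group) x direction -> n, mean, SD of relative strength."""

    entries: dict[tuple[str, str, str], GroupSummary] = field(default_factory=dict)

    def get(self, sex: str, age_group: str, direction: str) -> GroupSummary:
        key = (sex, age_group, direction)
        if key not in self.entries:
            raise StatsError(f"stratum {key} absent from normative table")
        return self.entries[key]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sex": sex,
                "age_group": grp,
                "direction": d,
                "n": s.n,
                "mean_n_per_kg": s.mean,
                "sd_n_per_kg": s.sd,
            }
            for (sex, grp, d), s in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class DeficitReport:
    """Per-direction comparison of one patient against their normative stratum."""

    patient_id: str
    sex: str
    age_group: str
    directions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def build_normative_table(cohort: Sequence[AssessmentResult]) -> NormativeTable:
    """Aggregate a cohort into the normative table.

    Strata with fewer than two participants cannot yield an SD and are
    omitted with a warning.
    """
    if not cohort:
        raise StatsError("empty cohort")
    by_stratum: dict[tuple[str, str], list[AssessmentResult]] = {}
    for res in cohort:
        by_stratum.setdefault(res.participant.stratum, []).append(res)
    table = NormativeTable()
    for (sex, grp), members in by_stratum.items():
        if len(members) < 2:
            warnings.warn(
                f"stratum {(sex, grp)} has n={len(members)} < 2; omitted from the table",
                stacklevel=2,
            )
            continue
        for d in DIRECTION_CODES:
            vals = np.array([m.relative[d] for m in members])
            table.entries[(sex, grp, d)] = GroupSummary(
                label=f"{sex}/{grp}/{d}", n=len(vals),
                mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
            )
    return table


def deficit_score(patient: AssessmentResult, table: NormativeTable) -> DeficitReport:
    """Score a patient against their stratum: z, percent of norm, percent deficit."""
    sex, grp = patient.participant.stratum
    report = DeficitReport(patient_id=patient.participant.id, sex=sex, age_group=grp)
    for d in DIRECTION_CODES:
        try:
            norm = table.get(sex, grp, d)
        except StatsError:
            available = sorted({(s, g) for (s, g, _dd) in table.entries})
            raise StatsError(
                f"stratum {(sex, grp)} absent from the normative table; "
                f"nearest available strata: {available}"
            ) from None
        x = patient.relative[d]
        report.directions[d] = {
            "value_n_per_kg": x,
            "norm_mean": norm.mean,
            "norm_sd": norm.sd,
            "z": (x - norm.mean) / norm.sd if norm.sd > 0 else float("nan"),
            "pct_of_norm": 100.0 * x / norm.mean,
            "pct_deficit": percent_difference(x, norm.mean),
        }
    return report
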