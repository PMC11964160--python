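"""Slope-based drug-effect quantification and the group-comparison decision tree.

Per animal and response parameter, an ordinary least-squares line is fitted
to the parameter values over recording time; slopes whose two-sided t test
against zero is not significant are gated to exactly zero before group
comparison.  Groups are then compared following a fixed decision tree:
Shapiro–Wilk normality per group and Levene variance across groups → one-way
ANOVA with Tukey post hoc when both pass; a log transform is attempted when
normality fails on positive data; otherwise Kruskal–Wallis (ANOVA on ranks)
with Dunn post hoc.  Paired designs use a one-way repeated-measures ANOVA on
per-animal condition means.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SlopeRecord",
    "GroupTestResult",
    "fit_parameter_slope",
    "slopes_from_features",
    "run_group_comparison",
    "run_rm_comparison",
]

ALPHA_DEFAULT = 0.05


@dataclasses.dataclass
class SlopeRecord:
    experiment_id: str
    parameter: str
    slope: float  # parameter-units per minute; NaN when undefined
    intercept: float
    p_slope: float  # two-sided p of slope vs 0
    gated_slope: float  # slope if significant, else exactly 0.0
    n_points: int


@dataclasses.dataclass
class GroupTestResult:
    test: str  # "one-way ANOVA" | "ANOVA on ranks" | "RM ANOVA"
    transform: str  # "none" | "log"
    statistic: float  # F or H
    df_between: int
    df_residual: int | None
    p: float
    normality_pass: bool
    variance_pass: bool
    posthoc: pd.DataFrame | None = None
    notes: list = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# per-animal slopes


def fit_parameter_slope(
    times: np.ndarray,
    values: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
    experiment_id: str = "",
    parameter: str = "",
) -> SlopeRecord:
    """OLS slope of a response parameter over time, gated by a t test.

    ``times`` are minutes since electrode placement; missing values are
    dropped pairwise.  With fewer than 3 complete points the slope is
    missing and the gated slope 0.  An exact (zero-residual) fit is treated
    as significant, the limiting behavior of the diverging t statistic.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    ok = np.isfinite(times) & np.isfinite(values)
    t, y = times[ok], values[ok]
    n = t.size
    if n < 3:
        return SlopeRecord(experiment_id, parameter, math.nan, math.nan, math.nan, 0.0, n)
    if np.ptp(t) == 0:
        raise ValueError("zero variance in times: slope is undefined")

    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    sse = float(np.sum(resid**2))
    scale = max(float(np.sum((y - ym) ** 2)), 1.0)
    if sse <= 1e-12 * scale:
        p = 0.0  # exact fit: t statistic diverges
    else:
        se = math.sqrt(sse / (n - 2) / sxx)
        tstat = slope / se
        p = 2.0 * float(sps.t.sf(abs(tstat), n - 2))
    gated = slope if p < alpha else 0.0
    return SlopeRecord(experiment_id, parameter, slope, intercept, p, gated, n)


def slopes_from_features(
    features: pd.DataFrame,
    parameters: tuple[str, ...] = ("latency", "f6ap", "spa", "n_aps_early", "n_aps_llpr"),
    alpha: float = ALPHA_DEFAULT,
    id_col: str = "experiment_id",
    time_col: str = "stimulation_time",
) -> pd.DataFrame:
    """Per-animal, per-parameter gated slopes from a long feature table."""
    rows = []
    label_cols = [c for c in ("condition", "zt") if c in features.columns]
    for exp_id, sub in features.groupby(id_col, sort=False):
        labels = {c: sub[c].iloc[0] for c in label_cols}
        for param in parameters:
            if param not in sub.columns:
                continue
            rec = fit_parameter_slope(
                sub[time_col].to_numpy(), sub[param].to_numpy(),
                alpha=alpha, experiment_id=str(exp_id), parameter=param,
            )
            rows.append({**dataclasses.asdict(rec), **labels})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decision tree


def _all_equal(groups: list[np.ndarray]) -> bool:
    allv = np.concatenate(groups)
    return bool(np.all(allv == allv[0]))


def _normality(groups: list[np.ndarray], alpha: float, notes: list) -> bool:
    for g in groups:
        if g.size < 3 or np.ptp(g) == 0:
            notes.append("normality untestable for a group (n<3 or constant); counted as pass")
            continue
        if sps.shapiro(g).pvalue < alpha:
            return False
    return True


def _variance(groups: list[np.ndarray], alpha: float) -> bool:
    if any(np.ptp(g) == 0 for g in groups) and _all_equal(groups):
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.levene(*groups, center="median")
    if not np.isfinite(p):
        return True
    return p >= alpha


def _anova(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df_b, df_r = k - 1, n_total - k
    if _all_equal(groups):
        return 0.0, 1.0, df_b, df_r
    f, p = sps.f_oneway(*groups)
    return float(f), float(p), df_b, df_r


def _tukey(labels: list[str], groups: list[np.ndarray]) -> pd.DataFrame:
    if _all_equal(groups):  # degenerate: no variance anywhere
        rows = [dict(group_a=labels[i], group_b=labels[j], statistic=0.0, p=1.0,
                     method="Tukey")
                for i, j in itertools.combinations(range(len(groups)), 2)]
        return pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append(
            dict(group_a=labels[i], group_b=labels[j],
                 statistic=float(res.statistic[i, j]), p=float(res.pvalue[i, j]),
                 method="Tukey")
        )
    return pd.DataFrame(rows)


def _dunn(labels: list[str], groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank post hoc with tie correction, Bonferroni-adjusted."""
    allv = np.concatenate(groups)
    n = allv.size
    ranks = sps.rankdata(allv)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(2.0 * float(sps.norm.sf(abs(z))) * m, 1.0)
        rows.append(dict(group_a=labels[i], group_b=labels[j], statistic=z, p=p, method="Dunn"))
    return pd.DataFrame(rows)


def run_group_comparison(
    groups: dict,
    alpha: float = ALPHA_DEFAULT,
    transform_policy: str = "auto",
) -> GroupTestResult:
    """Compare ≥2 independent groups following the decision tree.

    Both-pass → one-way ANOVA + Tukey.  Normality failure on strictly
    positive data → log-transform and retest; if the transformed data pass
    both checks, ANOVA on the logs.  Any remaining failure (including a
    variance failure on normal data) → Kruskal–Wallis, reported as H, with
    Bonferroni-adjusted Dunn post hoc.
    """
    if transform_policy not in ("auto", "never"):
        raise ValueError(f"unknown transform_policy {transform_policy!r}")
    labels = list(groups)
    arrays = []
    for lab in labels:
        g = np.asarray(groups[lab], dtype=float)
        g = g[np.isfinite(g)]
        if g.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        arrays.append(g)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")

    notes: list = []
    norm_ok = _normality(arrays, alpha, notes)
    var_ok = _variance(arrays, alpha) if norm_ok else False

    if norm_ok and var_ok:
        f, p, df_b, df_r = _anova(arrays)
        return GroupTestResult("one-way ANOVA", "none", f, df_b, df_r, p,
                               True, True, _tukey(labels, arrays), notes)

    if not norm_ok and transform_policy == "auto":
        if all((g > 0).all() for g in arrays):
            logs = [np.log10(g) for g in arrays]
            if _normality(logs, alpha, notes) and _variance(logs, alpha):
                f, p, df_b, df_r = _anova(logs)
                return GroupTestResult("one-way ANOVA", "log", f, df_b, df_r, p,
                                       True, True, _tukey(labels, logs), notes)
            notes.append("log transform did not restore normality/equal variance")
        else:
            notes.append("log transform skipped: non-positive values present")

    if _all_equal(arrays):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return GroupTestResult("ANOVA on ranks", "none", float(h), len(arrays) - 1, None,
                           float(p), norm_ok, var_ok, _dunn(labels, arrays), notes)


# ---------------------------------------------------------------------------
# repeated measures


def run_rm_comparison(
    per_animal_values: dict,
    alpha: float = ALPHA_DEFAULT,
    transform_policy: str = "auto",
) -> GroupTestResult:
    """One-way repeated-measures ANOVA across conditions.

    ``per_animal_values`` maps animal → {condition → value} (each value a
    per-animal mean over that recording's stimulations).  Animals missing
    any condition are excluded listwise with a note; no sphericity
    correction is applied.  Normality failure on positive data triggers a
    log transform, as in the independent-groups tree.
    """
    conditions = sorted({c for v in per_animal_values.values() for c in v})
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    notes: list = []
    rows = []
    for animal, vals in per_animal_values.items():
        finite = {c: vals[c] for c in conditions
                  if c in vals and np.isfinite(vals[c])}
        if len(finite) < len(conditions):
            if len(finite) <= 1:
                notes.append(f"animal {animal!r} excluded: only one condition observed")
            else:
                notes.append(f"animal {animal!r} excluded listwise: missing conditions")
            continue
        rows.append([finite[c] for c in conditions])
    data = np.asarray(rows, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("fewer than 2 complete animals for RM ANOVA")

    transform = "none"
    cols = [data[:, j] for j in range(data.shape[1])]
    norm_ok = _normality(cols, alpha, notes)
    var_ok = _variance(cols, alpha)
    # the paired protocol also uses the log transform to equalize variance
    if (not norm_ok or not var_ok) and transform_policy == "auto" and (data > 0).all():
        logs = np.log10(data)
        logcols = [logs[:, j] for j in range(logs.shape[1])]
        if _normality(logcols, alpha, notes) and _variance(logcols, alpha):
            data, transform = logs, "log"
            norm_ok = var_ok = True

    f, p, df_b, df_r = _rm_anova_f(data)
    posthoc = _tukey(conditions, [data[:, j] for j in range(data.shape[1])])
    return GroupTestResult("RM ANOVA", transform, f, df_b, df_r, p,
                           norm_ok, var_ok, posthoc, notes)


def _rm_anova_f(data: np.ndarray) -> tuple[float, float, int, int]:
    """Sum-of-squares decomposition for a complete subjects × conditions table."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * float(np.sum((data.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_cond - ss_subj
    df_b = k - 1
    df_r = (k - 1) * (n - 1)
    if ss_err <= 1e-30:
        if ss_cond <= 1e-30:
            return 0.0, 1.0, df_b, df_r
        return math.inf, 0.0, df_b, df_r
    f = (ss_cond / df_b) / (ss_err / df_r)
    p = float(sps.f.sf(f, df_b, df_r))
    return f, p, df_b, df_r
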