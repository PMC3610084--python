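"""Cohort statistics: omnibus tests, post-hocs, correlations, descriptives.

The battery mirrors a standard developmental-cohort analysis: one-way
ANOVAs (raw data or reconstructed from printed group summaries) and
Kruskal-Wallis tests across diagnostic groups, Tukey and Fisher-LSD
post-hocs, Pearson correlation matrices between articulatory features and
behavioral scores per group, a verbal-IQ median-style split of the ASD
group, descriptive statistics with a Shapiro-Wilk normality flag, and
per-group band-presence percentages. Tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, PreconditionError
from .records import ParticipantRecord, get_value, records_to_frame

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    significant: bool
    note: str = ""


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    group_summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    posthoc: tuple[PairwiseResult, ...] = ()
    note: str = ""


def _check_groups(values_by_group: dict[str, np.ndarray], min_n: int = 2):
    if len(values_by_group) < 2:
        raise PreconditionError("need at least 2 groups")
    clean = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < min_n:
            raise PreconditionError(f"group {name!r} has fewer than {min_n} values")
        clean[name] = arr
    return clean


def _summaries(groups: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    return {
        name: {"n": len(v), "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
        for name, v in groups.items()
    }


def kruskal_wallis(values_by_group: dict[str, np.ndarray]) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df."""
    groups = _check_groups(values_by_group)
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # no rank information at all
    else:
        h, p = sps.kruskal(*groups.values())
    return StatResult(
        test_name="kruskal_wallis", statistic=float(h),
        df=(len(groups) - 1,), p_value=float(p),
        group_summaries=_summaries(groups),
    )


def one_way_anova(values_by_group: dict[str, np.ndarray]) -> StatResult:
    """Between-groups F test, df = (k - 1, N - k)."""
    groups = _check_groups(values_by_group)
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    msw = np.mean(
        np.concatenate([(v - v.mean()) ** 2 for v in groups.values()])
    )
    note = ""
    if msw == 0:
        f, p = math.nan, math.nan
        note = "zero within-group variance: F undefined"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*groups.values())
        if not np.isfinite(f):
            f, p, note = math.nan, math.nan, "F undefined"
    return StatResult(
        test_name="one_way_anova", statistic=float(f),
        df=(k - 1, n_total - k), p_value=float(p),
        group_summaries=_summaries(groups), note=note,
    )


def anova_from_summary(
    means: list[float], sds: list[float], ns: list[int]
) -> StatResult:
    """One-way ANOVA F reconstructed from per-group mean/SD/n summaries.

    Between-group SS comes from the group means and sizes, within-group SS
    from the SDs; identical to :func:`one_way_anova` on any raw data having
    exactly these summaries.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    if not len(means) == len(sds) == len(ns):
        raise ParameterError("means, sds, ns must have equal length")
    if np.any(sds <= 0):
        raise ParameterError("all SDs must be > 0")
    if np.any(ns < 2):
        raise ParameterError("all ns must be >= 2")
    k = len(means)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, n_total - k
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return StatResult(
        test_name="anova_from_summary", statistic=float(f),
        df=(df1, df2), p_value=p,
        group_summaries={
            str(i): {"n": float(n), "mean": float(m), "sd": float(s)}
            for i, (m, s, n) in enumerate(zip(means, sds, ns))
        },
    )


def chi_square_independence(table: np.ndarray) -> StatResult:
    """Pearson chi-square for an r x c count table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ParameterError("table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return StatResult(
        test_name="chi_square_independence", statistic=float(chi2),
        df=(float(df),), p_value=float(p),
    )


def tukey_posthoc(
    values_by_group: dict[str, np.ndarray],
    ranked: bool = False,
    alpha: float = ALPHA,
) -> tuple[PairwiseResult, ...]:
    """Tukey(-Kramer) pairwise comparisons via the studentized range.

    ``ranked=True`` runs the comparison on pooled mid-ranks — the pragmatic
    pairing of a rank-based omnibus with Tukey post-hocs; results are
    flagged as rank-based.
    """
    groups = _check_groups(values_by_group)
    names = list(groups)
    note = ""
    if ranked:
        pooled = np.concatenate([groups[n] for n in names])
        ranks = sps.rankdata(pooled)
        out, pos = {}, 0
        for n in names:
            out[n] = ranks[pos : pos + len(groups[n])]
            pos += len(groups[n])
        groups = out
        note = "computed on rank-transformed data"
    res = sps.tukey_hsd(*[groups[n] for n in names])
    results = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        results.append(
            PairwiseResult(
                pair=(names[i], names[j]),
                statistic=float(res.statistic[i, j]),
                p_value=p, significant=p < alpha, note=note,
            )
        )
    return tuple(results)


def fisher_lsd_posthoc(
    values_by_group: dict[str, np.ndarray],
    alpha: float = ALPHA,
    require_omnibus: bool = True,
) -> tuple[PairwiseResult, ...]:
    """Fisher's protected LSD: pooled-MSW pairwise t tests.

    t_ij = (mean_i - mean_j) / sqrt(MSW * (1/n_i + 1/n_j)) on N - k df.
    When the omnibus ANOVA is not significant the pairwise results are
    reported but flagged suppressed (the LSD protection rule).
    """
    groups = _check_groups(values_by_group)
    names = list(groups)
    omnibus = one_way_anova(values_by_group)
    n_total = sum(len(v) for v in groups.values())
    k = len(groups)
    df_w = n_total - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_w
    protected = (not require_omnibus) or (omnibus.p_value < alpha)
    results = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = groups[names[i]], groups[names[j]]
        se = math.sqrt(msw * (1 / len(a) + 1 / len(b)))
        t = (a.mean() - b.mean()) / se if se > 0 else math.nan
        p = float(2 * sps.t.sf(abs(t), df_w)) if np.isfinite(t) else math.nan
        results.append(
            PairwiseResult(
                pair=(names[i], names[j]), statistic=float(t), p_value=p,
                significant=bool(protected and np.isfinite(p) and p < alpha),
                note="" if protected else "omnibus not significant: suppressed",
            )
        )
    return tuple(results)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_correlations(
    records: list[ParticipantRecord],
    feature_names: list[str],
    score_names: list[str],
) -> dict[str, pd.DataFrame]:
    """Per-group Pearson r matrices between features and scores.

    Returns, per group, a DataFrame indexed by feature with one column per
    score holding (r, p, stars) tuples; cells with a constant margin or
    fewer than 3 complete pairs are flagged NaN.
    """
    frame = records_to_frame(records)
    out: dict[str, pd.DataFrame] = {}
    for group, sub in frame.groupby("group", sort=False):
        cells = {}
        for feat in feature_names:
            row = {}
            for score in score_names:
                if feat not in sub or score not in sub:
                    raise KeyError(f"unknown column {feat!r}/{score!r}")
                pair = sub[[feat, score]].dropna()
                if len(pair) < 3 or pair[feat].nunique() == 1 or pair[score].nunique() == 1:
                    row[score] = (math.nan, math.nan, "")
                    continue
                r, p = sps.pearsonr(pair[feat], pair[score])
                row[score] = (float(r), float(p), _stars(p))
            cells[feat] = row
        out[str(group)] = pd.DataFrame.from_dict(cells, orient="index")
    return out


def split_by_viq(
    records: list[ParticipantRecord], cutoff: float | None = None
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Split ASD records into (high-VIQ, low-VIQ) at *cutoff*.

    Default cutoff is the sample mean VIQ. Values strictly above the cutoff
    go high; values at or below go low ("more than" defines the high group).
    """
    asd = [r for r in records if r.group == "ASD"]
    if not asd:
        raise PreconditionError("no ASD records to split")
    viqs = np.array([r.viq for r in asd])
    if cutoff is None:
        cutoff = float(viqs.mean())
    high = [r for r in asd if r.viq > cutoff]
    low = [r for r in asd if r.viq <= cutoff]
    if not low:
        warnings.warn("all VIQ values above cutoff: low-VIQ set empty", stacklevel=2)
    if not high:
        warnings.warn("all VIQ values at/below cutoff: high-VIQ set empty", stacklevel=2)
    return high, low


def descriptive_stats(values: np.ndarray) -> dict[str, float | bool]:
    """Mean, SD, SEM, 95% CI half-width (t-based), range, normality flag.

    Normality is Shapiro-Wilk at alpha = 0.05 (n >= 3; smaller samples are
    flagged non-assessable with normal=False).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise PreconditionError("need at least 2 values")
    n = len(v)
    sd = float(v.std(ddof=1))
    sem = sd / math.sqrt(n)
    ci = float(sps.t.ppf(0.975, n - 1) * sem)
    if n >= 3 and sd > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_norm = sps.shapiro(v)
        normal = bool(p_norm >= ALPHA)
    else:
        normal = False
    return {
        "n": n,
        "mean": float(v.mean()),
        "sd": sd,
        "sem": sem,
        "ci95_halfwidth": ci,
        "range": float(v.max() - v.min()),
        "normal": normal,
    }


def presence_percentages(
    records: list[ParticipantRecord],
    bands: tuple[str, ...] = ("SR", "FT", "POA"),
) -> pd.DataFrame:
    """Percentage of participants per group with contour bins in each band."""
    if not records:
        raise PreconditionError("no records")
    rows = {}
    groups = sorted({r.group for r in records})
    for group in groups:
        members = [r for r in records if r.group == group]
        row = {}
        for band in bands:
            flags = [
                bool(r.features.presence.get(band, False))
                for r in members if r.features is not None
            ]
            row[band] = 100.0 * np.mean(flags) if flags else math.nan
        rows[group] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def group_values(
    records: list[ParticipantRecord], column: str,
    groups: tuple[str, ...] | None = None,
    labels: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Collect a named value per group for the omnibus tests."""
    out: dict[str, list[float]] = {}
    for rec in records:
        label = (labels or {}).get(rec.id, rec.group)
        if groups is not None and label not in groups:
            continue
        out.setdefault(label, []).append(get_value(rec, column))
    return {k: np.asarray(v) for k, v in out.items()}
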