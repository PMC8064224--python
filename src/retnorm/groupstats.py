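"""Cross-sectional and longitudinal statistics on thickness summaries.

Group differences (wild-type vs 3xTg-AD) are assessed with two-sided
t-tests — Welch by default, pooled Student's as a sensitivity variant —
reported at the fixed significance tiers 5%, 1% and 0.1% (strict
inequalities).  Nasal-temporal asymmetry is a paired contrast of the nasal
and temporal block columns across eyes.  The four monthly time points are
analysed with a one-within-factor repeated-measures ANOVA (F = MS_time /
MS_subject-by-time) on complete cases only, with Greenhouse-Geisser
adjustment reported alongside and Tukey HSD (studentized range on the
within-subject error term) for the six pairwise age contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry as geom
from .errors import (DataError, DegenerateDistributionError,
                     InsufficientDataError, ParameterError)
from .normative import NormativeCell

log = logging.getLogger(__name__)

#: Significance tiers and their (strict) p thresholds, most stringent first.
TIERS = (("0.1%", 0.001), ("1%", 0.01), ("5%", 0.05))


def tier_of(p: float) -> str:
    """Map a p-value to its significance tier; p >= 0.05 (incl. boundary) is ns."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p must be in [0, 1], got {p!r}")
    for name, threshold in TIERS:
        if p < threshold:
            return name
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-sided comparison."""

    statistic: float
    df: float
    p: float
    tier: str
    mean_difference: float | None = None


def _summarize(sample) -> tuple[float, float, int]:
    """(mean, sd, n) from a raw sample, a NormativeCell or a triple."""
    if isinstance(sample, NormativeCell):
        return sample.mean, sample.sd, sample.n
    if isinstance(sample, tuple) and len(sample) == 3:
        mean, sd, n = sample
        return float(mean), float(sd), int(n)
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ParameterError("raw samples must be 1-D")
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def two_sample_test(a, b, variant: str = "welch") -> ComparisonResult:
    """Two-sided t-test between two groups, from raw samples or summaries.

    Either argument may be a 1-D sample, a ``(mean, sd, n)`` triple or a
    :class:`~retnorm.normative.NormativeCell`; raw samples are reduced to
    the same summary statistics, so both input forms give identical
    results.  ``variant="welch"`` (default) uses the Welch-Satterthwaite
    degrees of freedom; ``"student"`` pools the variances.
    """
    ma, sa, na = _summarize(a)
    mb, sb, nb = _summarize(b)
    if na < 2 or nb < 2:
        raise InsufficientDataError("each side needs n >= 2")
    if sa == 0 and sb == 0:
        if ma == mb:
            raise DegenerateDistributionError(
                "both sides constant and equal; t undefined")
        t, df = math.inf, na + nb - 2
        return ComparisonResult(t, df, 0.0, tier_of(0.0), ma - mb)
    va, vb = sa ** 2 / na, sb ** 2 / nb
    if variant == "welch":
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    elif variant == "student":
        sp2 = ((na - 1) * sa ** 2 + (nb - 1) * sb ** 2) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        raise ParameterError(f"variant must be 'welch' or 'student', got {variant!r}")
    t = (ma - mb) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(float(t), float(df), float(p), tier_of(p), ma - mb)


def asymmetry_test(grids, layer: str | None = None) -> ComparisonResult:
    """Paired nasal-vs-temporal contrast across a collection of block grids.

    For each eye the mean of the retained nasal-column blocks (3, 6, 9 on
    the standardized map) and of the temporal column (1, 4, 7) are
    computed; eyes lacking a retained block in either column are dropped.
    The per-eye differences (nasal minus temporal) enter a paired two-sided
    t-test, so a positive ``mean_difference`` means nasal thicker.
    """
    diffs = []
    for grid in grids:
        if layer is not None and grid.layer != layer:
            continue
        nasal = grid.column_mean(geom.NASAL_BLOCKS)
        temporal = grid.column_mean(geom.TEMPORAL_BLOCKS)
        if math.isnan(nasal) or math.isnan(temporal):
            log.warning("eye %s lacks a valid nasal or temporal column; dropped",
                        grid.subject)
            continue
        diffs.append(nasal - temporal)
    if len(diffs) < 2:
        raise InsufficientDataError(
            f"need >= 2 eyes with both columns valid, got {len(diffs)}")
    d = np.asarray(diffs)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError("all paired differences identical")
    t = d.mean() / (sd / math.sqrt(d.size))
    df = d.size - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(float(t), float(df), float(p), tier_of(p),
                            float(d.mean()))


# ---- longitudinal analysis ----------------------------------------------


@dataclass
class LongitudinalTable:
    """Complete-case subjects x ages matrix of one thickness summary.

    ``data`` is a wide DataFrame indexed by subject with one column per age
    (months); ``dropped`` counts the subjects removed for missing any time
    point.
    """

    data: pd.DataFrame
    dropped: int = 0

    def __post_init__(self):
        if self.data.isna().any().any():
            raise DataError("longitudinal table holds incomplete cases")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def ages(self) -> tuple:
        return tuple(self.data.columns)


def select_complete_cases(records: pd.DataFrame,
                          ages: Sequence[int] = geom.AGES_MONTHS,
                          value: str = "value") -> LongitudinalTable:
    """Pivot tidy per-visit records and keep subjects seen at every age.

    ``records`` needs columns subject, age_months and ``value``.  Subjects
    missing any of ``ages`` are dropped and counted.
    """
    required = {"subject", "age_months", value}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"records missing columns {sorted(missing)}")
    if not len(records):
        return LongitudinalTable(
            pd.DataFrame(columns=list(ages)).rename_axis("subject"), dropped=0)
    wide = records.pivot_table(index="subject", columns="age_months",
                               values=value, aggfunc="mean")
    wide = wide.reindex(columns=list(ages))
    complete = wide.dropna()
    return LongitudinalTable(complete, dropped=len(wide) - len(complete))


@dataclass(frozen=True)
class RanovaResult:
    F: float
    df_time: float
    df_error: float
    p: float
    gg_epsilon: float
    p_gg: float


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, LongitudinalTable):
        y = table.values
    else:
        y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ParameterError("expected a subjects x ages matrix")
    if np.isnan(y).any():
        raise DataError("incomplete rows must be removed before RANOVA")
    return y


def ranova(table) -> RanovaResult:
    """One-within-factor repeated-measures ANOVA over the age time points.

    ``table`` is a :class:`LongitudinalTable` or a complete subjects x ages
    matrix with at least three subjects.  The F statistic is
    MS_time / MS_subject-by-time with (k-1) and (k-1)(n-1) degrees of
    freedom.  The Greenhouse-Geisser epsilon (from the double-centred
    covariance of the columns) and the adjusted p are reported alongside
    the uncorrected p, which is the primary result.

    A table whose rows are all identical (e.g. a single subject duplicated)
    has no within-subject error and is rejected as degenerate rather than
    scored.
    """
    y = _as_matrix(table)
    n, k = y.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete subjects, got {n}")
    if k < 2:
        raise ParameterError("need >= 2 time points")
    grand = y.mean()
    time_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_time = n * ((time_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_time <= 1e-12 * max(ss_total, 1.0):
        # no time effect at all: F = 0, p = 1 by convention, even when the
        # error term is also null (all-constant rows)
        return RanovaResult(0.0, df_time, df_err, 1.0, 1.0, 1.0)
    ms_err = ss_err / df_err
    if ms_err <= 1e-12 * max(ss_total / max(n * k - 1, 1), 1e-300):
        raise DegenerateDistributionError(
            "zero within-subject error (identical subjects?); F undefined")
    F = (ss_time / df_time) / ms_err
    p = float(stats.f.sf(F, df_time, df_err))
    # Greenhouse-Geisser epsilon from the double-centred covariance matrix
    S = np.cov(y, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    lam = np.linalg.eigvalsh(Sc)
    eps = float(lam.sum() ** 2 / (df_time * (lam ** 2).sum()))
    eps = min(max(eps, 1.0 / df_time), 1.0)
    p_gg = float(stats.f.sf(F, eps * df_time, eps * df_err))
    return RanovaResult(float(F), float(df_time), float(df_err), p, eps, p_gg)


def tukey_pairwise(table) -> dict[tuple, ComparisonResult]:
    """Tukey HSD over the age means, using the within-subject error term.

    Each of the six age pairs is scored with the studentized-range
    distribution at k = 4 groups and the RANOVA error degrees of freedom,
    so the p-values are corrected for the family of pairwise contrasts.
    Returns ``{(age_i, age_j): ComparisonResult}``.
    """
    y = _as_matrix(table)
    n, k = y.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete subjects, got {n}")
    ages = (tuple(table.ages) if isinstance(table, LongitudinalTable)
            else tuple(range(1, k + 1)))
    grand = y.mean()
    time_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_time = n * ((time_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_err = ((y - grand) ** 2).sum() - ss_time - ss_subj
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        raise DegenerateDistributionError("zero within-subject error term")
    results = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = time_means[i] - time_means[j]
            q = abs(diff) / math.sqrt(ms_err / n)
            p = float(stats.studentized_range.sf(q, k, df_err))
            p = min(max(p, 0.0), 1.0)
            results[(ages[i], ages[j])] = ComparisonResult(
                float(q), float(df_err), p, tier_of(p), float(diff))
    return results
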