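"""Intra-/inter-plate variability statistics for plate-based kD screening.

Coefficients of variation (plain and pooled), one-way and repeated-measures
ANOVA with the ``F > F_crit and p <= alpha`` double significance rule,
Bonferroni-corrected post-hoc t-tests, the range-based "span kD" dispersion
metric, and machine-readable approach summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation, ``100 * SD / |mean|`` with sample SD."""
    x = np.asarray(list(values), float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    mean = float(np.mean(x))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(x, ddof=1)) / abs(mean)


@dataclass(frozen=True)
class PooledCv:
    cv_pct: float
    pooled_sd: float
    grand_mean: float
    df: int


def pooled_intra_cv(groups: Mapping[Hashable, Sequence[float]] | Sequence[Sequence[float]]) -> PooledCv:
    """Intra-plate CV: pooled within-group SD over the grand mean, in percent.

    ``pooled SD = sqrt( sum (n_i - 1) s_i^2 / sum (n_i - 1) )``; the grand
    mean averages every value entering the pooled SD.  Singleton groups
    contribute to the mean but not to the SD; all-singleton input is an
    error.
    """
    seqs = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    arrays = [np.asarray(list(g), float) for g in seqs if len(g) > 0]
    if not arrays:
        raise ValueError("no groups given")
    df = sum(a.size - 1 for a in arrays)
    if df == 0:
        raise ValueError("pooled SD needs at least one group with n >= 2")
    ss = sum((a.size - 1) * float(np.var(a, ddof=1)) for a in arrays if a.size > 1)
    pooled_sd = math.sqrt(ss / df)
    grand = float(np.mean(np.concatenate(arrays)))
    if grand == 0:
        raise ValueError("CV undefined for zero grand mean")
    return PooledCv(cv_pct=100.0 * pooled_sd / abs(grand), pooled_sd=pooled_sd,
                    grand_mean=grand, df=df)


def average_intra_cv(runs: Sequence[Mapping[Hashable, Sequence[float]] | Sequence[Sequence[float]]]) -> float:
    """Average intra-plate CV: arithmetic mean of each run's pooled CV."""
    if not runs:
        raise ValueError("no runs given")
    return float(np.mean([pooled_intra_cv(r).cv_pct for r in runs]))


# ------------------------------------------------------------------- ANOVA
@dataclass(frozen=True)
class AnovaResult:
    f: float
    f_crit: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    alpha: float

    @property
    def significant(self) -> bool:
        """The double rule: reject when F > F_crit and p <= alpha."""
        return self.f > self.f_crit and self.p <= self.alpha


def anova_oneway(
    groups: Mapping[Hashable, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way fixed-effects ANOVA from the between/within decomposition."""
    seqs = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    arrays = [np.asarray(list(g), float) for g in seqs]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("one-way ANOVA needs >= 2 groups with n >= 2 each")
    all_x = np.concatenate(arrays)
    grand = float(np.mean(all_x))
    ssb = sum(a.size * (float(np.mean(a)) - grand) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - np.mean(a)) ** 2)) for a in arrays)
    dfb = len(arrays) - 1
    dfw = all_x.size - len(arrays)
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0:
        f = 0.0 if msb == 0 else float("inf")
    else:
        f = msb / msw
    p = float(scipy.stats.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0
    f_crit = float(scipy.stats.f.ppf(1.0 - alpha, dfb, dfw))
    return AnovaResult(f=float(f), f_crit=f_crit, p=p, df_between=dfb, df_within=dfw,
                       ss_between=float(ssb), ss_within=float(ssw), alpha=alpha)


@dataclass(frozen=True)
class RepeatedAnovaResult:
    f_run: float
    p_run: float
    f_sample: float
    p_sample: float
    df_run: tuple[int, int]
    df_sample: tuple[int, int]
    alpha: float

    @property
    def significant_run(self) -> bool:
        return self.p_run <= self.alpha


def anova_repeated(matrix, alpha: float = 0.05) -> RepeatedAnovaResult:
    """Repeated-measures ANOVA (two-factor without replication).

    ``matrix`` is samples x runs (rows = the repeatedly measured samples,
    columns = runs); the run factor F is the test of run-to-run
    consistency.  Missing cells are rejected.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete samples x runs matrix, >= 2 each")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells in repeated-measures matrix")
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_cols = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_tot = float(np.sum((x - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    df_rows, df_cols = n - 1, k - 1
    df_err = df_rows * df_cols
    ms_err = ss_err / df_err
    def _f(ss, df):
        ms = ss / df
        if ms_err == 0:
            return (0.0, 1.0) if ms == 0 else (float("inf"), 0.0)
        f = ms / ms_err
        return float(f), float(scipy.stats.f.sf(f, df, df_err))
    f_run, p_run = _f(ss_cols, df_cols)
    f_sample, p_sample = _f(ss_rows, df_rows)
    return RepeatedAnovaResult(
        f_run=f_run, p_run=p_run, f_sample=f_sample, p_sample=p_sample,
        df_run=(df_cols, df_err), df_sample=(df_rows, df_err), alpha=alpha,
    )


@dataclass(frozen=True)
class PairwiseTest:
    group1: Hashable
    group2: Hashable
    t: float
    df: int
    p: float
    p_adjusted: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted <= alpha


def posthoc_ttests(
    groups: Mapping[Hashable, Sequence[float]],
    correction: str = "bonferroni",
) -> list[PairwiseTest]:
    """Pooled-variance two-sample t-tests for every group pair.

    ``correction`` is ``"bonferroni"`` (default, multiply p by the number
    of pairs) or ``"none"``.
    """
    arrays = {k: np.asarray(list(v), float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs n >= 2")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        x, y = arrays[a], arrays[b]
        n1, n2 = x.size, y.size
        sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
        denom = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        diff = float(np.mean(x) - np.mean(y))
        if denom == 0:
            t = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
        else:
            t = diff / denom
        df = n1 + n2 - 2
        p = float(2.0 * scipy.stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        out.append(PairwiseTest(group1=a, group2=b, t=float(t), df=df, p=p, p_adjusted=p_adj))
    return out


# ----------------------------------------------------------------- span kD
SPAN_DEFINITIONS = ("range_over_min", "range_over_reference", "range_over_mean")


@dataclass(frozen=True)
class SpanResult:
    percent: float
    definition: str
    low: float
    high: float


def span_kd(
    values: Sequence[float],
    reference: float | None = None,
    definition: str = "range_over_min",
) -> SpanResult:
    """Range-based dispersion of a set of single-kD estimates, in percent.

    The primary definition is ``100 (max - min) / |min|``; alternatives
    divide the range by ``|reference|`` or by ``|mean|``.  The definition
    used is always reported alongside the number.
    """
    x = np.asarray(list(values), float)
    if x.size < 2:
        raise ValueError("span needs at least two kD values")
    lo, hi = float(np.min(x)), float(np.max(x))
    rng = hi - lo
    if definition == "range_over_min":
        denom = abs(lo)
    elif definition == "range_over_reference":
        if reference is None:
            raise ValueError("reference-relative span needs a reference kD")
        denom = abs(reference)
    elif definition == "range_over_mean":
        denom = abs(float(np.mean(x)))
    else:
        raise ValueError(f"unknown span definition {definition!r}; choose from {SPAN_DEFINITIONS}")
    if denom == 0:
        raise ValueError(f"span denominator is zero under {definition!r}")
    return SpanResult(percent=100.0 * rng / denom, definition=definition, low=lo, high=hi)


# ------------------------------------------------------- approach summaries
def summarize_approaches(
    kd_lists: Mapping[str, Sequence[float]],
    points_per_kd: Mapping[str, object] | None = None,
    span_definition: str = "range_over_min",
) -> pd.DataFrame:
    """Summary table across kD-calculation approaches.

    One row per approach (mean kD, SD, number of single kD values, data
    points per single kD, CV in percent, span in percent) plus a total
    row ``"Av."`` pooling every value across approaches.
    """
    rows = []
    pooled: list[float] = []
    for name, values in kd_lists.items():
        x = np.asarray(list(values), float)
        if x.size < 2:
            raise ValueError(f"approach {name!r} needs >= 2 single-kD values")
        pooled.extend(x.tolist())
        rows.append(
            {
                "approach": name,
                "avg_kd_ml_g": float(np.mean(x)),
                "sd_kd_ml_g": float(np.std(x, ddof=1)),
                "n_single_kd": int(x.size),
                "points_per_kd": (points_per_kd or {}).get(name, ""),
                "cv_pct": cv(x),
                "span_pct": span_kd(x, definition=span_definition).percent,
            }
        )
    total = np.asarray(pooled, float)
    rows.append(
        {
            "approach": "Av.",
            "avg_kd_ml_g": float(np.mean(total)),
            "sd_kd_ml_g": float(np.std(total, ddof=1)),
            "n_single_kd": int(total.size),
            "points_per_kd": "n.a.",
            "cv_pct": cv(total),
            "span_pct": span_kd(total, definition=span_definition).percent,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["span_definition"] = span_definition
    return df
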