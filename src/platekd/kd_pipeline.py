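"""Outlier-screened estimation of the diffusion interaction parameter kD.

Per-well diffusion coefficients are grouped by concentration, screened
with an iterative two-sided single-outlier Grubbs test (preceded by
Kolmogorov-Smirnov normality and F-test variance checks), and fitted by
ordinary least squares to ``D = D0 (1 + kD c)``: the intercept is D0, and
kD is slope over intercept.  Concentrations are handled in g/mL so that
``kD * c`` is dimensionless with kD in mL/g; plate files remain in mg/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats


class KdFitError(ValueError):
    """Raised when a kD fit is impossible (singular design, D0 <= 0, ...)."""


# ------------------------------------------------------------ Grubbs screen
def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical value of the single-outlier Grubbs statistic.

    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with ``t``
    the upper ``alpha/(2n)`` quantile of Student's t with ``n-2`` degrees
    of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    t = scipy.stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


@dataclass(frozen=True)
class GrubbsDecision:
    """One iteration of the Grubbs test on one replicate group."""

    value: float
    g_statistic: float
    g_critical: float
    removed: bool


@dataclass
class GroupScreen:
    """Screening outcome for one replicate group."""

    n_before: int
    n_after: int
    tested: bool
    decisions: list[GrubbsDecision] = field(default_factory=list)
    ks_p: float = float("nan")
    note: str = ""

    @property
    def removed_values(self) -> list[float]:
        return [d.value for d in self.decisions if d.removed]


@dataclass
class OutlierScreenReport:
    """Per-group Grubbs decisions plus global distribution checks."""

    groups: dict[Hashable, GroupScreen] = field(default_factory=dict)
    alpha: float = 0.05
    f_tests: list[tuple[Hashable, Hashable, float, float]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(len(g.removed_values) for g in self.groups.values())

    def excluded(self) -> list[tuple[Hashable, float, float]]:
        """(group, value, G) for every excluded point."""
        out = []
        for key, g in self.groups.items():
            out.extend(
                (key, d.value, d.g_statistic) for d in g.decisions if d.removed
            )
        return out


def ks_normality(
    x: Sequence[float], mean: float | None = None, sd: float | None = None
) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic and p-value against a normal reference.

    With ``mean``/``sd`` given the reference is fully specified and the
    test holds its nominal level; when estimated from the data (the
    default, as spreadsheet practice does) the test is conservative.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("normality check needs n >= 3")
    m = float(np.mean(x)) if mean is None else mean
    s = float(np.std(x, ddof=1)) if sd is None else sd
    if s == 0:
        return 0.0, 1.0
    res = scipy.stats.kstest(x, "norm", args=(m, s))
    return float(res.statistic), float(res.pvalue)


def f_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided F-test of variance equality, larger variance on top."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    d1, d2 = x.size - 1, y.size - 1
    if v1 < v2:
        v1, v2, d1, d2 = v2, v1, d2, d1
    if v2 == 0:
        return float("inf") if v1 > 0 else 1.0, 0.0 if v1 > 0 else 1.0
    f = v1 / v2
    p = min(1.0, 2.0 * float(scipy.stats.f.sf(f, d1, d2)))
    return float(f), p


def grubbs_screen(
    groups: Mapping[Hashable, Sequence[float]],
    alpha: float = 0.05,
    max_removals: int = 2,
    *,
    check_normality: bool = True,
) -> tuple[dict[Hashable, np.ndarray], OutlierScreenReport]:
    """Iterative two-sided single-outlier Grubbs test per replicate group.

    Each group is screened independently: the extreme studentized
    deviate ``G = max |x_i - mean| / sd`` is compared against the
    closed-form critical value, and the extreme point is removed while
    ``G > G_crit``, up to ``max_removals`` times (never below n = 3).
    Groups with n < 3 pass through untested but flagged; zero-variance
    groups report "no outlier".  Returns the cleaned groups and a report
    with every decision, KS normality p-values, and pairwise F-tests.
    """
    cleaned: dict[Hashable, np.ndarray] = {}
    report = OutlierScreenReport(alpha=alpha)
    for key, values in groups.items():
        x = np.asarray(list(values), float)
        screen = GroupScreen(n_before=x.size, n_after=x.size, tested=False)
        if x.size < 3:
            screen.note = "too few replicates for Grubbs' test"
            cleaned[key] = x
            report.groups[key] = screen
            continue
        screen.tested = True
        if check_normality:
            try:
                _, screen.ks_p = ks_normality(x)
            except ValueError:
                pass
        removed = 0
        while removed < max_removals and x.size >= 3:
            mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if sd == 0:
                screen.note = "zero variance: no outlier"
                break
            i = int(np.argmax(np.abs(x - mean)))
            g = abs(x[i] - mean) / sd
            g_crit = grubbs_critical_value(x.size, alpha)
            is_out = g > g_crit
            screen.decisions.append(
                GrubbsDecision(value=float(x[i]), g_statistic=float(g),
                               g_critical=float(g_crit), removed=bool(is_out))
            )
            if not is_out:
                break
            x = np.delete(x, i)
            removed += 1
        screen.n_after = x.size
        cleaned[key] = x
        report.groups[key] = screen
    keys = [k for k, v in cleaned.items() if v.size >= 2]
    for a, b in combinations(keys, 2):
        f, p = f_test(cleaned[a], cleaned[b])
        report.f_tests.append((a, b, f, p))
    return cleaned, report


@dataclass
class DistributionReport:
    """Normality and variance-equality summary across replicate groups."""

    ks: dict[Hashable, tuple[float, float]]
    f_tests: list[tuple[Hashable, Hashable, float, float]]
    degenerate: list[Hashable]


def distribution_checks(
    groups: Mapping[Hashable, Sequence[float]], alpha: float = 0.05
) -> DistributionReport:
    """KS normality per group and pairwise two-sided F-tests of variances."""
    ks: dict[Hashable, tuple[float, float]] = {}
    degenerate: list[Hashable] = []
    arrays: dict[Hashable, np.ndarray] = {}
    for key, values in groups.items():
        x = np.asarray(list(values), float)
        if x.size < 3:
            raise ValueError(f"group {key!r} has n < 3")
        arrays[key] = x
        if np.std(x, ddof=1) == 0:
            degenerate.append(key)
            ks[key] = (0.0, 1.0)
        else:
            ks[key] = ks_normality(x)
    f_tests = []
    for a, b in combinations(arrays, 2):
        f, p = f_test(arrays[a], arrays[b])
        f_tests.append((a, b, f, p))
    return DistributionReport(ks=ks, f_tests=f_tests, degenerate=degenerate)


# ------------------------------------------------------------------ kD fit
@dataclass(frozen=True)
class KdResult:
    """One linear D-vs-c fit: D0, kD and its provenance."""

    d0_m2_s: float
    kd_ml_g: float
    r2: float
    n_points: int
    slope: float
    slope_se: float
    intercept_se: float
    concentrations_g_ml: tuple[float, ...]
    excluded: tuple[tuple[Hashable, float, float], ...] = ()

    @property
    def kd_se_ml_g(self) -> float:
        """First-order (delta-method) standard error of kD = slope / D0."""
        if self.d0_m2_s == 0:
            return float("nan")
        rel = (self.slope_se / self.slope) ** 2 if self.slope else float("inf")
        rel += (self.intercept_se / self.d0_m2_s) ** 2
        return abs(self.kd_ml_g) * math.sqrt(rel) if self.slope else (
            self.slope_se / self.d0_m2_s
        )


def fit_kd(
    concentrations_g_ml: Sequence[float],
    d_values: Sequence[float],
    *,
    screen: bool = False,
    alpha: float = 0.05,
    max_removals: int = 2,
) -> KdResult:
    """OLS fit of ``D = D0 (1 + kD c)``; optionally Grubbs-screened.

    With ``screen=True`` the D values are grouped by concentration and
    passed through :func:`grubbs_screen` first ("based on averaged data"
    in plate-screening parlance); ``screen=False`` fits the raw data.
    Raises :class:`KdFitError` for fewer than two distinct concentrations
    or a non-positive fitted D0.
    """
    c = np.asarray(list(concentrations_g_ml), float)
    d = np.asarray(list(d_values), float)
    if c.shape != d.shape:
        raise ValueError("concentration and D arrays differ in length")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite inputs to kD fit")

    excluded: tuple[tuple[Hashable, float, float], ...] = ()
    if screen:
        groups: dict[float, list[float]] = {}
        for ci, di in zip(c, d):
            groups.setdefault(float(ci), []).append(float(di))
        cleaned, report = grubbs_screen(groups, alpha=alpha, max_removals=max_removals)
        c = np.concatenate([np.full(v.size, k) for k, v in cleaned.items()])
        d = np.concatenate(list(cleaned.values()))
        excluded = tuple(report.excluded())

    if np.unique(c).size < 2:
        raise KdFitError("need at least two distinct concentrations")
    res = scipy.stats.linregress(c, d)
    if res.intercept <= 0:
        raise KdFitError(f"non-positive fitted D0 ({res.intercept:.3g}): kD undefined")
    return KdResult(
        d0_m2_s=float(res.intercept),
        kd_ml_g=float(res.slope / res.intercept),
        r2=float(res.rvalue**2),
        n_points=int(c.size),
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        concentrations_g_ml=tuple(sorted(set(float(x) for x in c))),
        excluded=excluded,
    )


def fit_kd_measurements(
    measurements,
    *,
    groups: Mapping[str, Sequence[str]] | None = None,
    screen: bool = True,
    alpha: float = 0.05,
    max_removals: int = 2,
) -> dict[str, KdResult]:
    """kD per formulation (or per named well group) from a measurement table.

    ``measurements`` is a :class:`~platekd.acf_analysis.MeasurementSet`
    or its DataFrame; only rows with ``ok`` are used, concentrations are
    converted from mg/mL to g/mL.  ``groups`` maps a group name to well
    labels (e.g. the single-kD groups of an approach layout); without it,
    grouping is by formulation.
    """
    frame = measurements.frame if hasattr(measurements, "frame") else measurements
    ok = frame[(frame["ok"]) & (frame["role"] == "sample")]
    results: dict[str, KdResult] = {}
    if groups is None:
        for fid, sub in ok.groupby("formulation_id"):
            results[str(fid)] = fit_kd(
                sub["concentration_mg_ml"].to_numpy() / 1000.0,
                sub["D_m2_per_s"].to_numpy(),
                screen=screen, alpha=alpha, max_removals=max_removals,
            )
    else:
        indexed = ok.set_index("well")
        for name, wells in groups.items():
            sub = indexed.loc[[w for w in wells if w in indexed.index]]
            results[str(name)] = fit_kd(
                sub["concentration_mg_ml"].to_numpy() / 1000.0,
                sub["D_m2_per_s"].to_numpy(),
                screen=screen, alpha=alpha, max_removals=max_removals,
            )
    return results


# ------------------------------------------------------- R_H extrapolation
@dataclass(frozen=True)
class Rh0Result:
    rh0_nm: float
    slope: float
    n_used: int
    excluded_indices: tuple[int, ...]


def extrapolate_rh0(
    concentrations: Sequence[float],
    rh_values_nm: Sequence[float],
    fit_range: tuple[float, float] = (2.0, 7.0),
) -> Rh0Result:
    """Linear extrapolation of R_H to infinite dilution over a fit range.

    Concentrations and ``fit_range`` share whatever unit the caller uses
    (typically mg/mL).  Points outside the range are excluded and
    reported; the intercept is the single-particle radius R_H(c->0).
    """
    c = np.asarray(list(concentrations), float)
    r = np.asarray(list(rh_values_nm), float)
    lo, hi = fit_range
    mask = (c >= lo) & (c <= hi)
    if np.unique(c[mask]).size < 2:
        raise KdFitError("fewer than two distinct concentrations inside the fit range")
    res = scipy.stats.linregress(c[mask], r[mask])
    return Rh0Result(
        rh0_nm=float(res.intercept),
        slope=float(res.slope),
        n_used=int(mask.sum()),
        excluded_indices=tuple(int(i) for i in np.flatnonzero(~mask)),
    )
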