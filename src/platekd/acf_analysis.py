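"""Diffusion coefficients, radii and quality metrics from autocorrelograms.

Two estimators are provided: a second-order cumulant fit (mean decay rate,
polydispersity, baseline and a scaled sum-of-squares quality metric) and a
non-negative Tikhonov-regularized inversion onto a log-spaced radius grid
(size distribution and peak summary).  Both use the single-angle scattering
vector q = (4 pi n / lambda) sin(theta/2) and Stokes-Einstein to convert
between decay rates, diffusion coefficients and hydrodynamic radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from . import _physics
from .dls_simulator import Autocorrelogram, InstrumentConfig, SimulatedPlate
from .plate_model import PlateLayout


class AcfFitError(RuntimeError):
    """Raised when an autocorrelogram carries no usable decay signal."""


def scattering_vector(instrument: InstrumentConfig) -> float:
    """Magnitude of the scattering vector in 1/m."""
    return _physics.scattering_vector_m(
        instrument.wavelength_nm, instrument.scattering_angle_deg, instrument.refractive_index
    )


def stokes_einstein_radius(d_m2_s: float, temperature_k: float, viscosity_mpas: float) -> float:
    """Hydrodynamic radius in nm from a diffusion coefficient in m^2/s."""
    return _physics.stokes_einstein_radius_nm(d_m2_s, temperature_k, viscosity_mpas)


def diffusion_from_radius(rh_nm: float, temperature_k: float, viscosity_mpas: float) -> float:
    """Diffusion coefficient in m^2/s from a hydrodynamic radius in nm."""
    return _physics.diffusion_from_radius_nm(rh_nm, temperature_k, viscosity_mpas)


# ------------------------------------------------------------ cumulant fit
@dataclass(frozen=True)
class CumulantFit:
    """Result of a second-order cumulant fit to one autocorrelogram."""

    gamma: float  # mean decay rate, 1/s
    beta: float  # intercept g2(0) - 1
    mu2: float  # second cumulant, 1/s^2
    pdi: float  # mu2 / gamma^2, clipped at 0
    baseline: float  # long-lag plateau of g2
    sos: float  # residual sum of squares / estimated noise variance
    d_m2_s: float
    n_window: int
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


def _tail_stats(g2: np.ndarray, tail_fraction: float = 0.25) -> tuple[float, float]:
    """Baseline level and noise variance from the long-lag tail."""
    n_tail = max(4, int(round(len(g2) * tail_fraction)))
    tail = g2[-n_tail:]
    return float(np.mean(tail)), float(np.var(tail, ddof=1))


def cumulant_fit(
    acf: Autocorrelogram,
    q: float | None = None,
    instrument: InstrumentConfig | None = None,
    *,
    window_fraction: float = 0.05,
    sos_threshold: float = 20.0,
    baseline_range: tuple[float, float] = (0.997, 1.003),
    pdi_threshold: float = 0.3,
) -> CumulantFit:
    """Weighted second-order cumulant fit of ``ln(g2 - 1)``.

    The fit window keeps lags with ``g2 - 1 > window_fraction * beta_hat``
    (crude ``beta_hat`` from the first lags) to avoid taking logs of
    noise-dominated tail points; weights are proportional to the signal
    so early, high-SNR lags dominate.  ``sos`` is the window residual sum
    of squares divided by the tail-estimated noise variance; fits are
    flagged when the baseline leaves ``baseline_range``, ``sos`` exceeds
    ``sos_threshold`` or the polydispersity index exceeds
    ``pdi_threshold``.  An all-noise signal raises :class:`AcfFitError`.
    """
    if q is None:
        instr = instrument or acf.meta.get("instrument")
        if instr is None:
            raise ValueError("need q or an instrument configuration")
        q = scattering_vector(instr)

    tau = acf.lag_times_s
    y = acf.g2 - 1.0
    baseline, noise_var = _tail_stats(acf.g2)

    beta_crude = float(np.mean(y[:3]))
    if beta_crude <= 0:
        raise AcfFitError(f"no positive intercept at {getattr(acf.well, 'label', '?')}")
    mask = y > window_fraction * beta_crude
    # restrict to the leading contiguous run so late noise spikes are excluded
    if not mask[0]:
        raise AcfFitError("first lag below fit threshold")
    n_window = int(np.argmin(mask)) if not mask.all() else mask.size
    if n_window < 5:
        raise AcfFitError(f"only {n_window} lags above fit threshold")

    tw = tau[:n_window]
    yw = y[:n_window]
    # WLS of ln y on [1, tau, tau^2]; weight ~ y (delta method for log noise)
    coeffs = np.polynomial.polynomial.polyfit(tw, np.log(yw), deg=2, w=yw)
    b0, b1, b2 = coeffs
    gamma = -b1 / 2.0
    mu2 = float(b2)
    beta = float(np.exp(b0))
    if gamma <= 0:
        raise AcfFitError("non-positive decay rate")

    fitted = 1.0 + np.exp(b0 + b1 * tw + b2 * tw**2)
    rss = float(np.sum((acf.g2[:n_window] - fitted) ** 2))
    sos = rss / max(noise_var, 1e-20)

    pdi = max(mu2, 0.0) / gamma**2
    d = gamma / q**2

    flags: list[str] = []
    if not baseline_range[0] <= baseline <= baseline_range[1]:
        flags.append("baseline")
    if sos >= sos_threshold:
        flags.append("sos")
    if pdi > pdi_threshold:
        flags.append("pdi")

    return CumulantFit(
        gamma=float(gamma),
        beta=beta,
        mu2=mu2,
        pdi=float(pdi),
        baseline=baseline,
        sos=sos,
        d_m2_s=float(d),
        n_window=n_window,
        flags=tuple(flags),
    )


# --------------------------------------------------- regularized inversion
@dataclass(frozen=True)
class Peak:
    rh_nm: float
    fraction_pct: float


@dataclass(frozen=True)
class SizeDistribution:
    """Intensity-weighted size distribution on a log radius grid."""

    radii_nm: np.ndarray
    weights: np.ndarray  # non-negative, sum to 1
    peaks: tuple[Peak, ...]  # sorted by radius


def default_radius_grid(n: int = 60, r_min_nm: float = 0.5, r_max_nm: float = 500.0) -> np.ndarray:
    return np.geomspace(r_min_nm, r_max_nm, n)


def regularized_distribution(
    acf: Autocorrelogram,
    instrument: InstrumentConfig | None = None,
    radii_nm: np.ndarray | None = None,
    reg_weight: float = 0.01,
    *,
    operator: str = "curvature",
    peak_min_fraction: float = 0.01,
) -> SizeDistribution:
    """Non-negative Tikhonov-regularized inversion of an ACF.

    Solves ``min || W (A w - s) ||^2 + reg_weight^2 || L w ||^2`` with
    ``w >= 0``, where ``s = sign(g2 - 1) sqrt(|g2 - 1|)`` is the field
    correlation amplitude (the signed square root keeps tail noise
    zero-mean instead of rectifying it), ``A_ij = exp(-Gamma_j tau_i)``
    with decay rates from the radius grid via Stokes-Einstein, ``W`` are
    inverse-SD weights from delta-method error propagation with a
    variance floor (so weights never correlate with the noise sign), and
    ``L`` is a second-difference operator with zero boundary conditions
    (``"curvature"``) or the identity.  Weights are normalized to
    intensity fractions; a peak is a contiguous run of grid mass above
    ``peak_min_fraction`` of the total, summarized by its
    intensity-weighted geometric-mean radius.
    """
    if reg_weight < 0:
        raise ValueError("regularization weight must be >= 0")
    instrument = instrument or acf.meta.get("instrument")
    if instrument is None:
        raise ValueError("need an instrument configuration for the radius grid decay rates")
    radii = default_radius_grid() if radii_nm is None else np.asarray(radii_nm, float)
    if radii.size < 3 or not np.all(np.diff(radii) > 0):
        raise ValueError("radius grid must be increasing with >= 3 points")

    tau = acf.lag_times_s
    y = acf.g2 - 1.0
    if not np.any(y > 0):
        raise AcfFitError("no positive ACF signal to invert")
    s = np.sign(y) * np.sqrt(np.abs(y))
    _, noise_var = _tail_stats(acf.g2)
    sigma = max(math.sqrt(noise_var), 1e-10)
    # var(s) ~ sigma^2 / (4 y); floored at 3 sigma so tail weights are constant
    point_var = sigma**2 / (4.0 * np.clip(y, 3.0 * sigma, None))
    w_pts = 1.0 / np.sqrt(point_var)
    w_pts /= w_pts.mean()

    gammas = np.array([instrument.gamma_for_radius(r) for r in radii])
    design = np.exp(-np.outer(tau, gammas))

    m = radii.size
    if operator == "curvature":
        # second differences assuming w == 0 just outside the grid, which
        # penalizes mass piling up at the grid boundaries
        reg = np.zeros((m + 2, m))
        for k in range(m + 2):
            for off, coef in ((-1, 1.0), (0, -2.0), (1, 1.0)):
                j = k - 1 + off
                if 0 <= j < m:
                    reg[k, j] = coef
    elif operator == "identity":
        reg = np.eye(m)
    else:
        raise ValueError(f"unknown regularization operator {operator!r}")

    a_stacked = np.vstack([design * w_pts[:, None], reg_weight * reg])
    s = s * w_pts
    b_stacked = np.concatenate([s, np.zeros(reg.shape[0])])
    try:
        w, _ = scipy.optimize.nnls(a_stacked, b_stacked)
    except Exception as exc:  # pragma: no cover - degenerate designs
        raise AcfFitError(f"regularized inversion failed: {exc}") from exc
    total = w.sum()
    if total <= 0:
        raise AcfFitError("regularized inversion returned an empty distribution")
    w = w / total

    peaks = _summarize_peaks(radii, w, peak_min_fraction)
    return SizeDistribution(radii_nm=radii, weights=w, peaks=tuple(peaks))


def _summarize_peaks(
    radii: np.ndarray, w: np.ndarray, min_fraction: float
) -> list[Peak]:
    active = w > 1e-12
    peaks: list[Peak] = []
    i = 0
    m = w.size
    while i < m:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and active[j + 1]:
            j += 1
        mass = float(w[i : j + 1].sum())
        if mass >= min_fraction:
            logr = np.log(radii[i : j + 1])
            rh = float(np.exp(np.sum(w[i : j + 1] * logr) / mass))
            peaks.append(Peak(rh_nm=rh, fraction_pct=100.0 * mass))
        i = j + 1
    peaks.sort(key=lambda p: p.rh_nm)
    return peaks


# ----------------------------------------------------------- plate analysis
_RESULT_COLUMNS = [
    "run_id",
    "well",
    "role",
    "formulation_id",
    "concentration_mg_ml",
    "elapsed_time_s",
    "D_m2_per_s",
    "R_H_nm",
    "PDI",
    "SOS",
    "baseline",
    "n_peaks",
    "peak2_RH_nm",
    "peak2_intensity_pct",
    "quality_flags",
    "ok",
]


@dataclass
class MeasurementSet:
    """Per-well analysis results for one run (the plate's measurement table)."""

    run_id: str
    frame: pd.DataFrame

    def ok_samples(self) -> pd.DataFrame:
        f = self.frame
        return f[(f["ok"]) & (f["role"] == "sample")]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def analyze_plate(
    plate: SimulatedPlate | Sequence[Autocorrelogram],
    layout: PlateLayout | None = None,
    instrument: InstrumentConfig | None = None,
    *,
    regularize: str | bool = "auto",
    pdi_gate: float = 0.1,
    second_peak_min_pct: float = 5.0,
    run_id: str | None = None,
) -> MeasurementSet:
    """Cumulant-analyze every well; optionally cross-check with regularization.

    ``regularize`` is ``True`` (always), ``False`` (never) or ``"auto"``:
    run the regularized inversion only when the cumulant PDI exceeds
    ``pdi_gate``, and raise a ``"multimodal"`` flag when it finds a second
    peak of at least ``second_peak_min_pct`` intensity.  Wells whose ACFs
    carry no decay (e.g. buffer controls) are reported with ``ok=False``
    and flag ``"fit_failed"`` rather than dropped.
    """
    if isinstance(plate, SimulatedPlate):
        acfs = plate.acfs
        layout = layout or plate.layout
        instrument = instrument or plate.instrument
        run_id = run_id or plate.run_id
    else:
        acfs = list(plate)
        if instrument is None and acfs:
            instrument = acfs[0].meta.get("instrument")
        run_id = run_id or (acfs[0].run_id if acfs else "")
    if instrument is None:
        raise ValueError("need an instrument configuration")
    q = scattering_vector(instrument)

    rows = []
    for acf in acfs:
        assignment = layout[acf.well] if (layout is not None and acf.well in layout) else None
        role = assignment.role if assignment else "sample"
        conc = assignment.concentration_mg_ml if assignment else float("nan")
        fid = assignment.formulation_id if assignment else ""
        row = {
            "run_id": run_id,
            "well": acf.well.label if acf.well else "",
            "role": role,
            "formulation_id": fid,
            "concentration_mg_ml": conc,
            "elapsed_time_s": acf.elapsed_time_s,
            "D_m2_per_s": float("nan"),
            "R_H_nm": float("nan"),
            "PDI": float("nan"),
            "SOS": float("nan"),
            "baseline": float("nan"),
            "n_peaks": 0,
            "peak2_RH_nm": float("nan"),
            "peak2_intensity_pct": float("nan"),
            "quality_flags": "",
            "ok": False,
        }
        try:
            fit = cumulant_fit(acf, q)
        except AcfFitError:
            row["quality_flags"] = "fit_failed"
            rows.append(row)
            continue
        flags = list(fit.flags)
        n_peaks, peak2 = 1, None
        want_reg = regularize is True or (regularize == "auto" and fit.pdi > pdi_gate)
        if want_reg:
            try:
                dist = regularized_distribution(acf, instrument)
                n_peaks = len(dist.peaks)
                big = [p for p in dist.peaks if p.fraction_pct >= second_peak_min_pct]
                if len(big) >= 2:
                    flags.append("multimodal")
                    peak2 = big[-1]
            except AcfFitError:
                pass
        row.update(
            {
                "D_m2_per_s": fit.d_m2_s,
                "R_H_nm": stokes_einstein_radius(
                    fit.d_m2_s, instrument.temperature_k, instrument.viscosity_mpas
                ),
                "PDI": fit.pdi,
                "SOS": fit.sos,
                "baseline": fit.baseline,
                "n_peaks": n_peaks,
                "peak2_RH_nm": peak2.rh_nm if peak2 else float("nan"),
                "peak2_intensity_pct": peak2.fraction_pct if peak2 else float("nan"),
                "quality_flags": ";".join(flags),
                # baseline/sos/pdi flags mark quality, multimodal wells stay usable;
                # only a failed fit disqualifies the well
                "ok": True,
            }
        )
        rows.append(row)
    return MeasurementSet(run_id=run_id or "", frame=pd.DataFrame(rows, columns=_RESULT_COLUMNS))
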