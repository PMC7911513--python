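"""Forward simulator for a plate-reader DLS run.

Generates per-well intensity autocorrelation functions (ACFs) with the
statistical structure the downstream analysis assumes:

* concentration dependence of the mutual diffusion coefficient,
  ``D(c) = D0 * (1 + kD * c)`` with ``c`` in g/mL and ``kD`` in mL/g;
* solvent evaporation that concentrates samples over elapsed acquisition
  time, faster on edge wells and attenuated at high concentration, with
  per-well and per-run random variation of the rate;
* additive Gaussian ACF noise shrinking with the number of acquisitions;
* optional anomalies: a slow second particle population (soluble
  aggregates) and gross per-well outliers.

Everything is reproducible from ``(layout, parameters, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _physics
from .plate_model import (
    AcquisitionSchedule,
    PlateLayout,
    PositionClass,
    WellAddress,
    WellAssignment,
    acquisition_schedule,
    classify_position,
)


# --------------------------------------------------------------- parameters
@dataclass(frozen=True)
class FormulationTruth:
    """Ground-truth interaction parameters of one formulation.

    ``d0_m2_s`` is the infinite-dilution diffusion coefficient,
    ``kd_ml_g`` the diffusion interaction parameter, and ``rh_nm`` the
    hydrodynamic radius consistent with ``d0_m2_s`` through
    Stokes-Einstein at the simulation temperature.
    """

    formulation_id: str
    d0_m2_s: float
    kd_ml_g: float
    rh_nm: float

    def __post_init__(self) -> None:
        if self.d0_m2_s <= 0 or self.rh_nm <= 0:
            raise ValueError("D0 and R_H must be positive")

    @classmethod
    def from_radius(
        cls,
        formulation_id: str,
        rh_nm: float,
        kd_ml_g: float,
        temperature_k: float = 298.15,
        viscosity_mpas: float = 0.8872,
    ) -> "FormulationTruth":
        d0 = _physics.diffusion_from_radius_nm(rh_nm, temperature_k, viscosity_mpas)
        return cls(formulation_id=formulation_id, d0_m2_s=d0, kd_ml_g=kd_ml_g, rh_nm=rh_nm)


@dataclass(frozen=True)
class EvaporationParams:
    """Linear-in-time fractional volume loss with positional modifiers.

    ``base_rate_per_h`` is the fractional volume loss per hour of a center
    well of dilute sample; edge wells lose volume ``edge_factor`` times
    faster; loss is attenuated by ``exp(-c0 / suppression_scale_mg_ml)``
    for concentrated (more viscous) samples; the volume never falls below
    ``min_volume_fraction`` of the fill volume.  ``rate_jitter_sd`` and
    ``run_factor_sd`` are lognormal sigmas for per-well and per-run random
    rate variation (local airflow, ambient humidity between runs).

    The default ``base_rate_per_h`` is calibrated so that a 2 mg/mL
    lysozyme-like sample (kD = 91.8 mL/g) in a center well read at the end
    of a full-plate run (8 h at 75 s/well) shows a ~2.5% apparent increase
    of D.
    """

    base_rate_per_h: float = 0.0338
    edge_factor: float = 2.0
    suppression_scale_mg_ml: float = 3.0
    min_volume_fraction: float = 0.3
    rate_jitter_sd: float = 0.2
    run_factor_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.base_rate_per_h < 0:
            raise ValueError("base rate must be >= 0")
        if self.edge_factor < 1:
            raise ValueError("edge factor must be >= 1")
        if not 0 < self.min_volume_fraction <= 1:
            raise ValueError("volume floor must lie in (0, 1]")

    @classmethod
    def off(cls) -> "EvaporationParams":
        """No evaporation at all (ideal plate)."""
        return cls(base_rate_per_h=0.0, rate_jitter_sd=0.0, run_factor_sd=0.0)

    @classmethod
    def deterministic(cls, **overrides) -> "EvaporationParams":
        """Default drift without the random jitter terms."""
        return cls(rate_jitter_sd=0.0, run_factor_sd=0.0, **overrides)


@dataclass(frozen=True)
class InstrumentConfig:
    """Optics and acquisition settings of the plate reader.

    Defaults describe a near-backscatter 830 nm instrument measuring
    aqueous samples at 25 C, with one measurement averaging
    ``n_acquisitions`` acquisitions of ``acquisition_time_s`` seconds.
    ``noise_sigma0`` is the ACF noise scale for a single acquisition;
    the per-point noise SD is ``noise_sigma0 / sqrt(n_acquisitions)``.
    """

    wavelength_nm: float = 830.0
    scattering_angle_deg: float = 158.0
    refractive_index: float = 1.331
    temperature_k: float = 298.15
    viscosity_mpas: float = 0.8872
    n_acquisitions: int = 15
    acquisition_time_s: float = 15.0
    noise_sigma0: float = 0.006
    coherence_beta: float = 0.25

    def __post_init__(self) -> None:
        if min(
            self.wavelength_nm,
            self.refractive_index,
            self.temperature_k,
            self.viscosity_mpas,
            self.acquisition_time_s,
        ) <= 0 or self.n_acquisitions < 1:
            raise ValueError("instrument parameters must be positive")
        if not 0.0 < self.scattering_angle_deg < 180.0:
            raise ValueError("scattering angle must lie in (0, 180) degrees")

    @property
    def q_m(self) -> float:
        return _physics.scattering_vector_m(
            self.wavelength_nm, self.scattering_angle_deg, self.refractive_index
        )

    @property
    def noise_sd(self) -> float:
        return self.noise_sigma0 / math.sqrt(self.n_acquisitions)

    def gamma_for_radius(self, rh_nm: float) -> float:
        """Decay rate (1/s) of a particle of hydrodynamic radius ``rh_nm``."""
        d = _physics.diffusion_from_radius_nm(rh_nm, self.temperature_k, self.viscosity_mpas)
        return d * self.q_m**2


@dataclass(frozen=True)
class AnomalySpec:
    """Occasional measurement anomalies injected into a simulated run.

    ``second_population_prob`` wells gain a slow second particle
    population with radius Normal(``rh2_mean_nm``, ``rh2_sd_nm``^2) at
    intensity fraction ``intensity_fraction``; ``outlier_prob`` wells get
    a gross multiplicative error on D (lognormal, sigma
    ``outlier_log_sd``).
    """

    second_population_prob: float = 0.0
    rh2_mean_nm: float = 42.8
    rh2_sd_nm: float = 7.9
    intensity_fraction: float = 0.116
    outlier_prob: float = 0.0
    outlier_log_sd: float = 0.25


# ------------------------------------------------------------------- types
@dataclass
class Autocorrelogram:
    """Lag times and intensity-ACF values g2(tau) for one well measurement."""

    lag_times_s: np.ndarray
    g2: np.ndarray
    well: WellAddress | None = None
    elapsed_time_s: float = 0.0
    run_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lag_times_s = np.asarray(self.lag_times_s, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lag_times_s.size < 16:
            raise ValueError("need at least 16 lag points")
        if self.lag_times_s.shape != self.g2.shape:
            raise ValueError("lag grid and g2 must have equal length")
        if not np.all(np.diff(self.lag_times_s) > 0):
            raise ValueError("lag grid must be strictly increasing")
        if not (np.all(np.isfinite(self.lag_times_s)) and np.all(np.isfinite(self.g2))):
            raise ValueError("non-finite values in autocorrelogram")


def default_lag_grid(n: int = 64, t_min_s: float = 1e-6, t_max_s: float = 1.0) -> np.ndarray:
    """Logarithmically spaced lag grid (default 64 lags, 1 us to 1 s)."""
    return np.geomspace(t_min_s, t_max_s, n)


# -------------------------------------------------------------- operations
def forward_diffusion(c_g_ml: float, truth: FormulationTruth) -> float:
    """Mutual diffusion coefficient D = D0 (1 + kD c); ``c`` in g/mL."""
    if c_g_ml < 0:
        raise ValueError("concentration must be >= 0")
    factor = 1.0 + truth.kd_ml_g * c_g_ml
    if factor <= 0:
        raise ValueError(
            f"1 + kD*c = {factor:.3g} <= 0 at c = {c_g_ml} g/mL: unphysical diffusion"
        )
    return truth.d0_m2_s * factor


def evaporation_trajectory(
    assignment: WellAssignment,
    position: PositionClass | bool,
    elapsed_time_s: float,
    params: EvaporationParams,
    rate_multiplier: float = 1.0,
) -> tuple[float, float]:
    """Volume fraction V(t)/V0 and effective concentration after evaporation.

    Solute mass is conserved exactly (``c_eff * V = c0 * V0``) until the
    volume floor engages.  ``rate_multiplier`` carries the random per-well
    and per-run factors drawn by :func:`simulate_plate` (1.0 = nominal).
    """
    if elapsed_time_s < 0:
        raise ValueError("elapsed time must be >= 0")
    is_edge = position.edge if isinstance(position, PositionClass) else bool(position)
    c0 = assignment.concentration_mg_ml
    rate = params.base_rate_per_h * (params.edge_factor if is_edge else 1.0) * rate_multiplier
    rate *= math.exp(-c0 / params.suppression_scale_mg_ml)
    vf = max(params.min_volume_fraction, 1.0 - rate * elapsed_time_s / 3600.0)
    return vf, c0 / vf


def synthesize_acf(
    d_m2_s: float,
    instrument: InstrumentConfig,
    lag_times_s: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    well: WellAddress | None = None,
    elapsed_time_s: float = 0.0,
    run_id: str = "",
) -> Autocorrelogram:
    """Single-exponential ACF ``g2 = 1 + beta exp(-2 D q^2 tau) + noise``.

    Noise is i.i.d. Gaussian with SD ``noise_sigma0 / sqrt(n_acquisitions)``;
    identical ``rng``/seed gives identical output.
    """
    if d_m2_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    lags = default_lag_grid() if lag_times_s is None else np.asarray(lag_times_s, float)
    rng = np.random.default_rng(rng)
    gamma = d_m2_s * instrument.q_m**2
    beta = instrument.coherence_beta
    g2 = 1.0 + beta * np.exp(-2.0 * gamma * lags)
    if instrument.noise_sigma0 > 0:
        g2 = g2 + rng.normal(0.0, instrument.noise_sd, size=lags.shape)
    return Autocorrelogram(
        lag_times_s=lags,
        g2=g2,
        well=well,
        elapsed_time_s=elapsed_time_s,
        run_id=run_id,
        meta={
            "beta": beta,
            "gammas": (gamma,),
            "weights": (1.0,),
            "noise_sd": instrument.noise_sd if instrument.noise_sigma0 > 0 else 0.0,
            "instrument": instrument,
            "anomaly": False,
        },
    )


def inject_second_population(
    acf: Autocorrelogram,
    rh2_nm: float,
    intensity_fraction: float,
    rng: np.random.Generator | int | None = None,
) -> Autocorrelogram:
    """Add a slow second particle population at the given intensity fraction.

    The field correlation becomes a two-exponential mixture,
    ``g2 - 1 = beta [(1-f) exp(-G1 tau) + f exp(-G2 tau)]^2``, with the
    second decay rate from ``rh2_nm`` via Stokes-Einstein.  Noise is
    redrawn at the stored level and the record is flagged anomalous.
    """
    if not 0.0 < intensity_fraction < 1.0:
        raise ValueError("intensity fraction must lie in (0, 1)")
    meta = acf.meta
    if "instrument" not in meta or "gammas" not in meta:
        raise ValueError("ACF lacks synthesis metadata; cannot recompose")
    instrument: InstrumentConfig = meta["instrument"]
    rng = np.random.default_rng(rng)
    gamma1 = meta["gammas"][0]
    gamma2 = instrument.gamma_for_radius(rh2_nm)
    beta = meta["beta"]
    f = intensity_fraction
    g1 = (1.0 - f) * np.exp(-gamma1 * acf.lag_times_s) + f * np.exp(-gamma2 * acf.lag_times_s)
    g2 = 1.0 + beta * g1**2
    if meta.get("noise_sd", 0.0) > 0:
        g2 = g2 + rng.normal(0.0, meta["noise_sd"], size=g2.shape)
    new_meta = dict(meta)
    new_meta.update(
        {
            "gammas": (gamma1, gamma2),
            "weights": (1.0 - f, f),
            "anomaly": True,
            "rh2_nm": rh2_nm,
            "intensity_fraction": f,
        }
    )
    return Autocorrelogram(
        lag_times_s=acf.lag_times_s.copy(),
        g2=g2,
        well=acf.well,
        elapsed_time_s=acf.elapsed_time_s,
        run_id=acf.run_id,
        meta=new_meta,
    )


# ------------------------------------------------------------- plate runs
@dataclass
class SimulatedPlate:
    """Raw autocorrelograms of one run plus the ground-truth sidecar."""

    run_id: str
    layout: PlateLayout
    instrument: InstrumentConfig
    evaporation: EvaporationParams
    anomalies: AnomalySpec
    seed: int
    schedule: AcquisitionSchedule
    acfs: list[Autocorrelogram]
    truth: pd.DataFrame  # one row per non-empty well

    def measurements_frame(self) -> pd.DataFrame:
        """Long-format measurement table: one row per (well, lag)."""
        frames = []
        for acf in self.acfs:
            frames.append(
                pd.DataFrame(
                    {
                        "run_id": self.run_id,
                        "well": acf.well.label,
                        "elapsed_time_s": acf.elapsed_time_s,
                        "lag_s": acf.lag_times_s,
                        "g2": acf.g2,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write(self, outdir: str | Path) -> None:
        """Write measurements CSV, plate map CSV, and truth sidecar JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measurements_frame().to_csv(outdir / "measurements.csv", index=False)
        self.layout.to_csv(outdir / "plate_map.csv")
        sidecar = {
            "run_id": self.run_id,
            "seed": self.seed,
            "instrument": dataclasses.asdict(self.instrument),
            "evaporation": dataclasses.asdict(self.evaporation),
            "anomalies": dataclasses.asdict(self.anomalies),
            "wells": self.truth.to_dict(orient="records"),
        }
        (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))


def simulate_plate(
    layout: PlateLayout,
    truths: Mapping[str, FormulationTruth],
    instrument: InstrumentConfig | None = None,
    evaporation: EvaporationParams | None = None,
    anomalies: AnomalySpec | None = None,
    *,
    seed: int = 0,
    dwell_s: float = 75.0,
    order: str = "row_major",
    run_id: str = "run-1",
    lag_times_s: np.ndarray | None = None,
) -> SimulatedPlate:
    """Forward-simulate one DLS plate run.

    Every non-empty well gets one autocorrelogram at its scheduled elapsed
    time; sample wells decay according to the formulation truth at the
    evaporation-concentrated effective concentration, control/placebo
    wells contain solvent only (noise around a flat baseline).  The truth
    sidecar records the effective concentration, true D, and anomaly
    flags per well.
    """
    instrument = instrument or InstrumentConfig()
    evaporation = evaporation or EvaporationParams()
    anomalies = anomalies or AnomalySpec()
    missing = {a.formulation_id for a in layout.sample_wells()} - set(truths)
    if missing:
        raise KeyError(f"no truth entry for formulations {sorted(missing)}")

    rng = np.random.default_rng(seed)
    schedule = acquisition_schedule(layout, order=order, dwell_s=dwell_s)
    lags = default_lag_grid() if lag_times_s is None else np.asarray(lag_times_s, float)

    run_factor = (
        float(np.exp(rng.normal(0.0, evaporation.run_factor_sd)))
        if evaporation.run_factor_sd > 0
        else 1.0
    )

    acfs: list[Autocorrelogram] = []
    truth_rows: list[dict] = []
    for addr, elapsed in schedule:
        a = layout[addr]
        pos = classify_position(addr)
        row: dict = {
            "well": addr.label,
            "role": a.role,
            "formulation_id": a.formulation_id,
            "elapsed_time_s": elapsed,
            "edge": pos.edge,
            "band": pos.band,
        }
        if a.role == "sample":
            truth = truths[a.formulation_id]
            jitter = (
                float(np.exp(rng.normal(0.0, evaporation.rate_jitter_sd)))
                if evaporation.rate_jitter_sd > 0
                else 1.0
            )
            vf, c_eff = evaporation_trajectory(
                a, pos, elapsed, evaporation, rate_multiplier=run_factor * jitter
            )
            d_true = forward_diffusion(c_eff / 1000.0, truth)
            d_meas = d_true
            is_outlier = anomalies.outlier_prob > 0 and rng.random() < anomalies.outlier_prob
            if is_outlier:
                d_meas = d_true * float(np.exp(rng.normal(0.0, anomalies.outlier_log_sd)))
            acf = synthesize_acf(
                d_meas, instrument, lags, rng, well=addr, elapsed_time_s=elapsed, run_id=run_id
            )
            second = (
                anomalies.second_population_prob > 0
                and rng.random() < anomalies.second_population_prob
            )
            if second:
                rh2 = float(
                    abs(rng.normal(anomalies.rh2_mean_nm, anomalies.rh2_sd_nm))
                )
                acf = inject_second_population(acf, rh2, anomalies.intensity_fraction, rng)
            row.update(
                {
                    "concentration_mg_ml": a.concentration_mg_ml,
                    "volume_fraction": vf,
                    "c_eff_mg_ml": c_eff,
                    "d_true_m2_s": d_true,
                    "d_simulated_m2_s": d_meas,
                    "outlier": bool(is_outlier),
                    "second_population": bool(second),
                }
            )
        else:
            # solvent-only wells: flat baseline, pure noise
            g2 = np.ones_like(lags)
            if instrument.noise_sigma0 > 0:
                g2 = g2 + rng.normal(0.0, instrument.noise_sd, size=lags.shape)
            acf = Autocorrelogram(
                lag_times_s=lags,
                g2=g2,
                well=addr,
                elapsed_time_s=elapsed,
                run_id=run_id,
                meta={"beta": 0.0, "instrument": instrument, "anomaly": False},
            )
            row.update(
                {
                    "concentration_mg_ml": 0.0,
                    "volume_fraction": 1.0,
                    "c_eff_mg_ml": 0.0,
                    "d_true_m2_s": float("nan"),
                    "d_simulated_m2_s": float("nan"),
                    "outlier": False,
                    "second_population": False,
                }
            )
        acfs.append(acf)
        truth_rows.append(row)

    return SimulatedPlate(
        run_id=run_id,
        layout=layout,
        instrument=instrument,
        evaporation=evaporation,
        anomalies=anomalies,
        seed=seed,
        schedule=schedule,
        acfs=acfs,
        truth=pd.DataFrame(truth_rows),
    )


def example_truths() -> dict[str, FormulationTruth]:
    """Representative formulation truths used in examples and evaluations.

    Radii and kD magnitudes follow typical lysozyme / small-peptide
    values: lysozyme monomer at 1.9 nm with a strongly repulsive kD in
    low-salt acetate buffer, and a 4.7 kDa peptide with repulsive
    (acetate) or attractive (phosphate) interactions.
    """
    return {
        "lysozyme": FormulationTruth.from_radius("lysozyme", 1.9, 91.8),
        "lysozyme+NaCl": FormulationTruth.from_radius("lysozyme+NaCl", 2.0, -12.0),
        "peptide12-ac": FormulationTruth.from_radius("peptide12-ac", 1.6, 57.0),
        "peptide12-ph": FormulationTruth.from_radius("peptide12-ph", 1.6, -14.8),
    }
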