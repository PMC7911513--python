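"""Screening plate layouts: recommended designs, reference designs, budgets.

Two recommended designs for kD screening are generated deterministically:

* ``low_risk`` - 8 formulations, 5 concentrations (2, 4, 6, 8, 10 mg/mL),
  6 vertical replicates = 240 sample wells filling rows B-M, columns 3-22
  (first well B3, last M22); all edge wells free.
* ``high_quantity`` - 20 formulations, 3 concentrations (2, 5, 10 mg/mL),
  5 replicates = 300 sample wells; two vertical replicate bands (rows B-F
  and G-K over all 22 non-edge columns) plus horizontal 5-replicate runs
  in rows L-O (first well B2, last O21).

Reference experimental designs (the lysozyme intra-/inter-plate plates and
the eight approach groupings A-H used to compare kD-calculation layouts)
are encoded with their single-kD well groups in ``metadata["kd_groups"]``.
Monte-Carlo evaluation scores any layout by simulating full plate runs and
refitting kD per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acf_analysis import analyze_plate
from .dls_simulator import (
    AnomalySpec,
    EvaporationParams,
    FormulationTruth,
    InstrumentConfig,
    simulate_plate,
)
from .kd_pipeline import KdFitError, fit_kd_measurements
from .plate_model import (
    LayoutError,
    PlateLayout,
    WellAddress,
    WellAssignment,
    validate_layout,
)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a generated screening design."""

    n_formulations: int
    concentrations_mg_ml: tuple[float, ...]
    replicates: int
    orientation: str = "vertical"
    edge_policy: str = "exclude"
    fill_volume_ul: float = 30.0

    def __post_init__(self) -> None:
        if list(self.concentrations_mg_ml) != sorted(set(self.concentrations_mg_ml)):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class ApiBudget:
    """Exact API mass required by a layout (mg)."""

    total_mg: float
    per_formulation_mg: dict[str, float]
    per_well_mg: tuple[float, ...]


def api_budget(layout: PlateLayout) -> ApiBudget:
    """Sum of per-well API masses: concentration (mg/mL) x fill volume (mL).

    Control and placebo wells contribute zero.
    """
    per_form: dict[str, list[float]] = {}
    per_well: list[float] = []
    for a in layout.sample_wells():
        mass = a.concentration_mg_ml * a.fill_volume_ul / 1000.0
        per_well.append(mass)
        per_form.setdefault(a.formulation_id, []).append(mass)
    return ApiBudget(
        total_mg=math.fsum(per_well),
        per_formulation_mg={k: math.fsum(v) for k, v in per_form.items()},
        per_well_mg=tuple(per_well),
    )


# ------------------------------------------------------ recommended designs
def _vertical_block(
    layout: PlateLayout,
    fid: str,
    concentrations: Sequence[float],
    row0: int,
    col0: int,
    n_reps: int,
    fill: float,
) -> None:
    """One formulation block: concentrations left-to-right, replicates down."""
    for j, conc in enumerate(concentrations):
        for r in range(n_reps):
            layout.add(
                WellAssignment(
                    address=WellAddress(row0 + r, col0 + j),
                    formulation_id=fid,
                    concentration_mg_ml=float(conc),
                    replicate=r + 1,
                    fill_volume_ul=fill,
                )
            )


def recommended_design(
    kind: str,
    *,
    fill_volume_ul: float = 30.0,
    buffer_fill: bool = False,
    plate_id: str | None = None,
) -> PlateLayout:
    """Build one of the two recommended screening layouts.

    ``kind`` is ``"low_risk"`` or ``"high_quantity"``.  ``buffer_fill``
    additionally fills edge rows A and P with buffer (role ``placebo``)
    for thermal insulation against evaporation of neighbouring samples.
    Regeneration with identical arguments is byte-identical.
    """
    if kind == "low_risk":
        concs = (2.0, 4.0, 6.0, 8.0, 10.0)
        layout = PlateLayout(
            plate_id=plate_id or "low-risk",
            metadata={
                "design": "low_risk",
                "concentrations_mg_ml": concs,
                "replicates": 6,
                "orientation": "vertical",
            },
        )
        # 8 formulations in two 6-row bands (B-G, H-M), 5 columns each,
        # centered in columns 3-22; edge rows/columns stay free.
        for i in range(8):
            band, slot = divmod(i, 4)
            _vertical_block(
                layout,
                f"F{i + 1}",
                concs,
                row0=1 + 6 * band,
                col0=2 + 5 * slot,
                n_reps=6,
                fill=fill_volume_ul,
            )
    elif kind == "high_quantity":
        concs = (2.0, 5.0, 10.0)
        layout = PlateLayout(
            plate_id=plate_id or "high-quantity",
            metadata={
                "design": "high_quantity",
                "concentrations_mg_ml": concs,
                "replicates": 5,
                "orientation": "vertical",
            },
        )
        # 60 (formulation, concentration) slots of 5 replicates each:
        # 44 vertical runs in bands B-F and G-K over columns 2-23, then
        # 16 horizontal runs in rows L-O (columns 2-6, 7-11, 12-16, 17-21).
        slots: list[list[WellAddress]] = []
        for band_row in (1, 6):
            for col in range(1, 23):
                slots.append([WellAddress(band_row + r, col) for r in range(5)])
        for row in range(11, 15):
            for col0 in (1, 6, 11, 16):
                slots.append([WellAddress(row, col0 + j) for j in range(5)])
        for s, cells in enumerate(slots):
            fid = f"F{s // 3 + 1}"
            conc = concs[s % 3]
            for r, addr in enumerate(cells):
                layout.add(
                    WellAssignment(
                        address=addr,
                        formulation_id=fid,
                        concentration_mg_ml=conc,
                        replicate=r + 1,
                        fill_volume_ul=fill_volume_ul,
                    )
                )
    else:
        raise ValueError(f"unknown design kind {kind!r}")

    if buffer_fill:
        for row in (0, 15):
            for col in range(24):
                addr = WellAddress(row, col)
                if addr not in layout:
                    layout.add(
                        WellAssignment(
                            address=addr,
                            role="placebo",
                            fill_volume_ul=fill_volume_ul,
                        )
                    )
    return layout


# -------------------------------------------------------- reference layouts
_LYS_FORMS = ("LysSig2243", "LysSig2243+NaCl", "LysSig5161", "LysSig5161+NaCl")


def _fig1_layout() -> PlateLayout:
    """Intra-plate lysozyme design: 8-step horizontal series, 5 replicate rows."""
    concs = (2.0, 3.5, 5.0, 7.0, 8.0, 10.0, 12.0, 14.0)
    layout = PlateLayout(
        plate_id="fig1",
        metadata={"design": "fig1", "concentrations_mg_ml": concs, "n_runs": 3},
    )
    groups: dict[str, list[str]] = {}
    placements = {
        "LysSig2243": (0, 0),
        "LysSig2243+NaCl": (0, 8),
        "LysSig5161": (5, 0),
        "LysSig5161+NaCl": (5, 8),
    }
    for fid, (row0, col0) in placements.items():
        wells: list[str] = []
        for r in range(5):
            for j, conc in enumerate(concs):
                addr = WellAddress(row0 + r, col0 + j)
                layout.add(
                    WellAssignment(
                        address=addr,
                        formulation_id=fid,
                        concentration_mg_ml=conc,
                        replicate=r + 1,
                    )
                )
                wells.append(addr.label)
        groups[fid] = wells
    for col, _label in enumerate(("Ac.B", "Ac.B", "NaCl", "NaCl")):
        layout.add(WellAssignment(address=WellAddress(15, col), role="control"))
    layout.metadata["kd_groups"] = groups
    return layout


def _fig2_layout() -> PlateLayout:
    """Inter-plate lysozyme design: 4 concentrations, 5 replicates, 3 positions.

    Three position bands (upper/middle/bottom) each hold every formulation,
    giving 3 single-kD fits per formulation per run; over the 3 runs of the
    inter-plate study that is 9 kD per lysozyme batch.  Controls sit in
    row P.
    """
    concs = (2.0, 5.0, 10.0, 14.0)
    layout = PlateLayout(
        plate_id="fig2",
        metadata={"design": "fig2", "concentrations_mg_ml": concs, "n_runs": 3, "positions": 3},
    )
    groups: dict[str, list[str]] = {}
    for p, row0 in enumerate((0, 5, 10)):  # position bands A-E, F-J, K-O
        for fi, fid in enumerate(_LYS_FORMS):
            wells = []
            for r in range(5):
                for j, conc in enumerate(concs):
                    addr = WellAddress(row0 + r, 4 * fi + j)
                    layout.add(
                        WellAssignment(
                            address=addr,
                            formulation_id=fid,
                            concentration_mg_ml=conc,
                            replicate=r + 1,
                        )
                    )
                    wells.append(addr.label)
            groups[f"{fid}/pos{p + 1}"] = wells
    for col, _label in enumerate(("Ac.B", "Ac.B", "NaCl", "NaCl")):
        layout.add(WellAssignment(address=WellAddress(15, col), role="control"))
    layout.metadata["kd_groups"] = groups
    layout.metadata["kd_fits_per_batch"] = 3 * layout.metadata["n_runs"]
    return layout


_APPROACH_CONCS = (2.0, 4.0, 6.0, 8.0, 10.0)
#: shared physical plate of the approach comparison: 8 blocks of
#: 6 replicate rows x 5 concentration columns (bands A-F / K-P,
#: column groups 1-5, 6-10, 15-19, 20-24) = 240 wells, 48 replicates
#: per concentration.
_APPROACH_BANDS = (0, 10)
_APPROACH_COLGROUPS = (0, 5, 14, 19)


def _approach_plate(fid: str) -> PlateLayout:
    layout = PlateLayout(
        plate_id=f"approach-{fid}",
        metadata={"concentrations_mg_ml": _APPROACH_CONCS},
    )
    rep = {c: 0 for c in _APPROACH_CONCS}
    for row0 in _APPROACH_BANDS:
        for col0 in _APPROACH_COLGROUPS:
            for r in range(6):
                for j, conc in enumerate(_APPROACH_CONCS):
                    rep[conc] += 1
                    layout.add(
                        WellAssignment(
                            address=WellAddress(row0 + r, col0 + j),
                            formulation_id=fid,
                            concentration_mg_ml=conc,
                            replicate=rep[conc],
                        )
                    )
    return layout


def _wells_by_conc(layout: PlateLayout) -> dict[float, list[WellAddress]]:
    out: dict[float, list[WellAddress]] = {c: [] for c in _APPROACH_CONCS}
    for a in layout.sample_wells():
        out[a.concentration_mg_ml].append(a.address)
    return out


def _edgeness(addr: WellAddress) -> int:
    """Distance to the nearest plate border (0 = edge well)."""
    return min(addr.row, 15 - addr.row, addr.col, 23 - addr.col)


def _split(seq: list, sizes: Sequence[int]) -> list[list]:
    out, i = [], 0
    for s in sizes:
        out.append(seq[i : i + s])
        i += s
    return out


def _approach_groups(layout: PlateLayout, letter: str) -> dict[str, list[str]]:
    """Single-kD well groups for approach A-H on the shared plate.

    A: the 8 physical blocks (30 points each).  B: the two 120-point
    bands.  C/D: four kDs of 64/64/56/56 points built from edge-ordered
    (C, rows first) or column-edge-ordered (D) replicates.  E/F: four
    30-point kDs from the most-edge (E) or most-central (F) 24 replicates
    per concentration.  G: horizontal three-row groups (60 points).
    H: vertical column-group splits (60 points).
    """
    by_conc = _wells_by_conc(layout)
    groups: dict[str, list[str]] = {}

    def add_split(order_key, sizes_conc6, sizes_other, subset=None):
        n_groups = len(sizes_other)
        parts: list[list[str]] = [[] for _ in range(n_groups)]
        for conc, wells in by_conc.items():
            ws = sorted(wells, key=order_key)
            if subset is not None:
                ws = ws[: subset]
            sizes = sizes_conc6 if conc == 6.0 else sizes_other
            for gi, chunk in enumerate(_split(ws, sizes)):
                parts[gi].extend(a.label for a in chunk)
        for gi, wells in enumerate(parts):
            groups[f"kD{gi + 1}"] = wells

    if letter == "A":
        gi = 0
        for row0 in _APPROACH_BANDS:
            for col0 in _APPROACH_COLGROUPS:
                gi += 1
                groups[f"kD{gi}"] = [
                    WellAddress(row0 + r, col0 + j).label
                    for r in range(6)
                    for j in range(len(_APPROACH_CONCS))
                ]
    elif letter == "B":
        for gi, row0 in enumerate(_APPROACH_BANDS):
            groups[f"kD{gi + 1}"] = [
                WellAddress(row0 + r, col0 + j).label
                for col0 in _APPROACH_COLGROUPS
                for r in range(6)
                for j in range(len(_APPROACH_CONCS))
            ]
    elif letter == "C":
        add_split(lambda a: (_edgeness(a), a.row, a.col), (16, 16, 8, 8), (12, 12, 12, 12))
    elif letter == "D":
        add_split(
            lambda a: (min(a.col, 23 - a.col), a.col, a.row),
            (16, 16, 8, 8),
            (12, 12, 12, 12),
        )
    elif letter == "E":
        add_split(lambda a: (_edgeness(a), a.row, a.col), (6, 6, 6, 6), (6, 6, 6, 6), subset=24)
    elif letter == "F":
        add_split(
            lambda a: (-_edgeness(a), a.row, a.col), (6, 6, 6, 6), (6, 6, 6, 6), subset=24
        )
    elif letter == "G":
        row_groups = [(0, 1, 2), (3, 4, 5), (10, 11, 12), (13, 14, 15)]
        for gi, rows in enumerate(row_groups):
            groups[f"kD{gi + 1}"] = [
                a.address.label for a in layout.sample_wells() if a.address.row in rows
            ]
    elif letter == "H":
        for gi, col0 in enumerate(_APPROACH_COLGROUPS):
            cols = set(range(col0, col0 + 5))
            groups[f"kD{gi + 1}"] = [
                a.address.label for a in layout.sample_wells() if a.address.col in cols
            ]
    else:
        raise ValueError(f"unknown approach letter {letter!r}")
    return groups


def build_paper_layouts(name: str) -> PlateLayout:
    """Reference experimental layouts by name.

    ``"fig1"`` and ``"fig2"`` are the lysozyme intra-/inter-plate designs;
    ``"Ac-A"`` .. ``"Ac-H"`` and ``"Ph-A"`` .. ``"Ph-H"`` are the peptide
    approach groupings (acetate / phosphate buffer) sharing one 240-well
    plate, with single-kD well groups in ``metadata["kd_groups"]``.
    """
    key = name.strip()
    low = key.lower()
    if low == "fig1":
        return _fig1_layout()
    if low == "fig2":
        return _fig2_layout()
    m = key.replace("_", "-").split("-")
    if len(m) == 2 and m[0].capitalize() in ("Ac", "Ph") and m[1].upper() in "ABCDEFGH":
        buffer_name = m[0].capitalize()
        letter = m[1].upper()
        fid = "peptide12-ac" if buffer_name == "Ac" else "peptide12-ph"
        layout = _approach_plate(fid)
        layout.plate_id = f"approach-{buffer_name}-{letter}"
        layout.metadata["design"] = f"{buffer_name}-{letter}"
        layout.metadata["kd_groups"] = _approach_groups(layout, letter)
        return layout
    raise ValueError(
        f"unknown layout name {name!r}; expected fig1, fig2, or Ac-/Ph- A..H"
    )


def approach_names(buffer_name: str = "Ac") -> list[str]:
    return [f"{buffer_name}-{letter}" for letter in "ABCDEFGH"]


# --------------------------------------------------------------- evaluation
def monte_carlo_design_eval(
    layout: PlateLayout,
    truths: Mapping[str, FormulationTruth],
    *,
    instrument: InstrumentConfig | None = None,
    evaporation: EvaporationParams | None = None,
    anomalies: AnomalySpec | None = None,
    n_sims: int = 100,
    seed: int = 0,
    dwell_s: float = 75.0,
    screen: bool = True,
    use_groups: bool = True,
) -> pd.DataFrame:
    """Score a layout by repeated simulate -> analyze -> fit-kD cycles.

    Returns one row per kD group (``metadata["kd_groups"]`` when present
    and ``use_groups``; otherwise per formulation) with the mean, SD, CV
    and bias of the fitted kD across ``n_sims`` simulated runs.
    Reproducible for a fixed ``seed``.
    """
    if n_sims < 2:
        raise ValueError("need at least two simulations")
    groups = layout.metadata.get("kd_groups") if use_groups else None
    group_form: dict[str, str] = {}
    if groups:
        lab2form = {a.address.label: a.formulation_id for a in layout.sample_wells()}
        group_form = {g: lab2form[wells[0]] for g, wells in groups.items()}

    seeds = np.random.SeedSequence(seed).generate_state(n_sims)
    estimates: dict[str, list[float]] = {}
    failures = 0
    for i in range(n_sims):
        sim = simulate_plate(
            layout,
            truths,
            instrument,
            evaporation,
            anomalies,
            seed=int(seeds[i] % (2**31)),
            dwell_s=dwell_s,
            run_id=f"sim-{i}",
        )
        ms = analyze_plate(sim, regularize=False)
        try:
            results = fit_kd_measurements(ms, groups=groups, screen=screen)
        except KdFitError as exc:
            raise RuntimeError(f"kD fit failed in simulation {i}: {exc}") from exc
        for name, res in results.items():
            estimates.setdefault(name, []).append(res.kd_ml_g)

    rows = []
    for name, kds in estimates.items():
        fid = group_form.get(name, name)
        kd_true = truths[fid].kd_ml_g if fid in truths else float("nan")
        x = np.asarray(kds)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        rows.append(
            {
                "group": name,
                "formulation_id": fid,
                "kd_true_ml_g": kd_true,
                "n_sims": int(x.size),
                "mean_kd_ml_g": mean,
                "sd_kd_ml_g": sd,
                "cv_pct": 100.0 * sd / abs(mean) if mean != 0 else float("inf"),
                "bias_pct": 100.0 * (mean - kd_true) / abs(kd_true)
                if kd_true not in (0.0,) and np.isfinite(kd_true)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
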