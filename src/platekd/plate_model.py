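"""384-well plate geometry, layouts, and acquisition schedules.

A plate has 16 rows (displayed A-P) and 24 columns (displayed 1-24).
Internally coordinates are 0-based; every file and report uses the
lettered/1-based display form ("B3").  Edge wells are rows A/P and
columns 1/24 (76 wells); the remaining 308 are center wells.  Row bands
(upper/middle/bottom) follow the plate reader's row-major acquisition
direction: wells in lower bands are measured later and evaporate longer.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

N_ROWS = 16
N_COLS = 24
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: allowed well roles
ROLES = ("sample", "control", "placebo", "empty")

#: manufacturer working range of the low-volume 384-well plates, in uL
WORKING_VOLUME_UL = (5.0, 40.0)

#: default row-band boundaries: upper = A-E, middle = F-K, bottom = L-P
DEFAULT_BAND_BOUNDS = (5, 11)

_LABEL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class LayoutError(ValueError):
    """Raised for malformed well labels, duplicate addresses, or invalid assignments."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """Position of a well; ``row`` 0-15 (A-P), ``col`` 0-23 (1-24)."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < N_ROWS):
            raise LayoutError(f"row index {self.row} outside 0..{N_ROWS - 1}")
        if not (0 <= self.col < N_COLS):
            raise LayoutError(f"column index {self.col} outside 0..{N_COLS - 1}")

    @property
    def label(self) -> str:
        return f"{ROW_LETTERS[self.row]}{self.col + 1}"

    @classmethod
    def parse(cls, label: str) -> "WellAddress":
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise LayoutError(
                f"malformed well label {label!r}: expected letter A-P followed by 1-24"
            )
        row = ROW_LETTERS.index(m.group(1).upper())
        col = int(m.group(2)) - 1
        if not (0 <= col < N_COLS):
            raise LayoutError(f"column {m.group(2)} in label {label!r} outside 1..{N_COLS}")
        return cls(row=row, col=col)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_well_address(label: str) -> WellAddress:
    """Parse a display label such as ``"B3"`` into a :class:`WellAddress`."""
    return WellAddress.parse(label)


@dataclass(frozen=True)
class PositionClass:
    """Edge/center classification plus row band of a well."""

    edge: bool
    band: str  # "upper" | "middle" | "bottom"

    @property
    def center(self) -> bool:
        return not self.edge


def classify_position(
    addr: WellAddress, band_bounds: tuple[int, int] = DEFAULT_BAND_BOUNDS
) -> PositionClass:
    """Classify a well as edge/center and into an upper/middle/bottom row band.

    Edge wells are rows A and P and columns 1 and 24.  ``band_bounds``
    gives the first row index of the middle and bottom bands.
    """
    edge = addr.row in (0, N_ROWS - 1) or addr.col in (0, N_COLS - 1)
    mid_start, bottom_start = band_bounds
    if addr.row < mid_start:
        band = "upper"
    elif addr.row < bottom_start:
        band = "middle"
    else:
        band = "bottom"
    return PositionClass(edge=edge, band=band)


@dataclass(frozen=True)
class WellAssignment:
    """Contents and role of a single well.

    ``concentration_mg_ml`` is the nominal sample mass concentration in
    mg/mL (0 for non-sample roles); ``fill_volume_ul`` is the pipetted
    volume in uL, checked against the plate working range.
    """

    address: WellAddress
    role: str = "sample"
    formulation_id: str = ""
    concentration_mg_ml: float = 0.0
    replicate: int = 1
    fill_volume_ul: float = 30.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LayoutError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "sample":
            if not self.formulation_id:
                raise LayoutError(f"sample well {self.address.label} needs a formulation_id")
            if not self.concentration_mg_ml > 0:
                raise LayoutError(
                    f"sample well {self.address.label} needs a positive concentration"
                )
        if self.replicate < 1:
            raise LayoutError(f"replicate index must be >= 1 at {self.address.label}")
        lo, hi = WORKING_VOLUME_UL
        if self.role != "empty" and not (lo <= self.fill_volume_ul <= hi):
            raise LayoutError(
                f"fill volume {self.fill_volume_ul} uL at {self.address.label} outside "
                f"working range {lo}-{hi} uL"
            )


_CSV_COLUMNS = [
    "well",
    "role",
    "formulation_id",
    "concentration_mg_per_ml",
    "replicate",
    "fill_volume_ul",
]


@dataclass
class PlateLayout:
    """A plate identifier plus one :class:`WellAssignment` per used well."""

    plate_id: str
    wells: dict[WellAddress, WellAssignment] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_assignments(
        cls,
        plate_id: str,
        assignments: Iterable[WellAssignment],
        metadata: dict | None = None,
    ) -> "PlateLayout":
        layout = cls(plate_id=plate_id, metadata=dict(metadata or {}))
        for a in assignments:
            layout.add(a)
        return layout

    def add(self, assignment: WellAssignment) -> None:
        if assignment.address in self.wells:
            raise LayoutError(f"duplicate assignment for well {assignment.address.label}")
        self.wells[assignment.address] = assignment

    def __len__(self) -> int:
        return len(self.wells)

    def __contains__(self, addr: WellAddress) -> bool:
        return addr in self.wells

    def __getitem__(self, addr: WellAddress | str) -> WellAssignment:
        if isinstance(addr, str):
            addr = WellAddress.parse(addr)
        return self.wells[addr]

    def assignments(self) -> list[WellAssignment]:
        """All assignments in row-major (acquisition) order."""
        return [self.wells[a] for a in sorted(self.wells)]

    def sample_wells(self) -> list[WellAssignment]:
        return [a for a in self.assignments() if a.role == "sample"]

    def non_empty(self) -> list[WellAssignment]:
        return [a for a in self.assignments() if a.role != "empty"]

    def formulations(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.sample_wells():
            seen.setdefault(a.formulation_id, None)
        return list(seen)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "well": a.address.label,
                "role": a.role,
                "formulation_id": a.formulation_id,
                "concentration_mg_per_ml": a.concentration_mg_ml,
                "replicate": a.replicate,
                "fill_volume_ul": a.fill_volume_ul,
            }
            for a in self.assignments()
        ]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, plate_id: str | None = None) -> "PlateLayout":
        df = pd.read_csv(path, dtype={"well": str, "role": str, "formulation_id": str})
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise LayoutError(f"plate-map CSV missing columns {missing}")
        if plate_id is None:
            plate_id = str(getattr(path, "name", path))
        layout = cls(plate_id=plate_id)
        for rec in df.itertuples(index=False):
            fid = "" if pd.isna(rec.formulation_id) else str(rec.formulation_id)
            layout.add(
                WellAssignment(
                    address=WellAddress.parse(rec.well),
                    role=str(rec.role),
                    formulation_id=fid,
                    concentration_mg_ml=float(rec.concentration_mg_per_ml),
                    replicate=int(rec.replicate),
                    fill_volume_ul=float(rec.fill_volume_ul),
                )
            )
        return layout


# ---------------------------------------------------------------- schedule
@dataclass
class AcquisitionSchedule:
    """Ordered (well, elapsed-time) pairs; one dwell per well, first at t=0."""

    entries: list[tuple[WellAddress, float]]
    per_well_dwell_s: float

    def __post_init__(self) -> None:
        if self.per_well_dwell_s <= 0:
            raise ValueError("per-well dwell must be positive")

    def __iter__(self) -> Iterator[tuple[WellAddress, float]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def duration_s(self) -> float:
        """First-to-last duration, counting a full dwell for every well."""
        return len(self.entries) * self.per_well_dwell_s

    def elapsed(self, addr: WellAddress) -> float:
        for a, t in self.entries:
            if a == addr:
                return t
        raise KeyError(addr.label)


def acquisition_schedule(
    layout: PlateLayout,
    order: str = "row_major",
    dwell_s: float = 75.0,
) -> AcquisitionSchedule:
    """Assign elapsed start times to all non-empty wells of ``layout``.

    ``order`` is ``"row_major"`` (A1..A24, B1..; the plate reader default)
    or ``"column_major"``.  Well *i* starts at ``i * dwell_s``.
    """
    if dwell_s <= 0:
        raise ValueError("dwell must be positive")
    wells = [a.address for a in layout.non_empty()]
    if not wells:
        raise LayoutError(f"layout {layout.plate_id!r} has no non-empty wells")
    if order == "row_major":
        wells.sort(key=lambda a: (a.row, a.col))
    elif order == "column_major":
        wells.sort(key=lambda a: (a.col, a.row))
    else:
        raise ValueError(f"unknown reading order {order!r}")
    entries = [(addr, i * dwell_s) for i, addr in enumerate(wells)]
    return AcquisitionSchedule(entries=entries, per_well_dwell_s=dwell_s)


# ---------------------------------------------------------------- validation
@dataclass(frozen=True)
class Finding:
    """One machine-readable layout warning."""

    code: str
    message: str
    wells: tuple[str, ...] = ()


def validate_layout(
    layout: PlateLayout,
    min_replicates: int = 5,
    min_concentration_steps: int = 3,
) -> list[Finding]:
    """Screen a layout against the design rules for reliable kD analysis.

    Checks: samples in edge wells; fewer than ``min_replicates`` replicates
    per (formulation, concentration); fewer than ``min_concentration_steps``
    concentration steps per formulation; low concentrations positioned below
    high ones (compared by mean row index, since later rows are read later
    and evaporate longer).  Returns an empty list for compliant layouts.
    """
    findings: list[Finding] = []
    samples = layout.sample_wells()

    edge = [a.address.label for a in samples if classify_position(a.address).edge]
    if edge:
        findings.append(
            Finding("edge_wells_used", f"{len(edge)} sample wells on plate edge", tuple(edge))
        )

    by_form: dict[str, list[WellAssignment]] = {}
    for a in samples:
        by_form.setdefault(a.formulation_id, []).append(a)

    for fid, group in by_form.items():
        by_conc: dict[float, list[WellAssignment]] = {}
        for a in group:
            by_conc.setdefault(a.concentration_mg_ml, []).append(a)
        for conc, reps in sorted(by_conc.items()):
            if len(reps) < min_replicates:
                findings.append(
                    Finding(
                        "few_replicates",
                        f"{fid} at {conc} mg/mL has {len(reps)} replicates "
                        f"(< {min_replicates})",
                        tuple(a.address.label for a in reps),
                    )
                )
        if len(by_conc) < min_concentration_steps:
            findings.append(
                Finding(
                    "few_concentration_steps",
                    f"{fid} has {len(by_conc)} concentration steps "
                    f"(< {min_concentration_steps})",
                )
            )
        concs = sorted(by_conc)
        mean_rows = [
            sum(a.address.row for a in by_conc[c]) / len(by_conc[c]) for c in concs
        ]
        for (c_lo, r_lo), (c_hi, r_hi) in zip(
            zip(concs, mean_rows), zip(concs[1:], mean_rows[1:])
        ):
            if r_lo > r_hi + 1e-9:
                findings.append(
                    Finding(
                        "low_conc_below_high",
                        f"{fid}: {c_lo} mg/mL sits below {c_hi} mg/mL "
                        f"(mean rows {r_lo:.1f} vs {r_hi:.1f})",
                    )
                )
                break
    return findings


def all_addresses() -> list[WellAddress]:
    """Every address of the 384-well plate in row-major order."""
    return [WellAddress(r, c) for r in range(N_ROWS) for c in range(N_COLS)]
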