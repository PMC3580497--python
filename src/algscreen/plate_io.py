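"""Readers and writers for plate-reader growth tables, plate layouts, acute
readouts, and SMILES compound libraries.

All formats are plain delimited text. Growth tables have one row per well and
one column per timepoint, with the header row carrying the times (hours by
default). Layouts are ``well,role,compound_id,dose_uM`` CSV. Compound
libraries are either a CSV with ``compound_id`` and ``smiles`` columns or a
plain SMILES file (``SMILES<tab>id`` per line).

Well addresses are row letter + 1-based column number. Both ``A1`` and
``A01`` are accepted on input; ``A1`` is canonical on output.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_ROWS_96 = "ABCDEFGH"
_ROWS_384 = "ABCDEFGHIJKLMNOP"
_WELL_RE = re.compile(r"^([A-Pa-p])0?([1-9]\d?)$")

ROLE_COMPOUND = "compound"
ROLE_CONTROL = "solvent_control"
ROLE_EMPTY = "empty"

DEFAULT_SCREEN_DOSE_UM = 25.0  # single screening dose used throughout


class PlateFormatError(ValueError):
    """A plate file violates the expected layout or header structure."""


class PlateParseError(ValueError):
    """A cell of a plate file could not be parsed."""


class PlateIOWarning(UserWarning):
    """Non-fatal inconsistencies between a layout and a data file."""


def canonical_well(address: str) -> str:
    """Normalize a well address: ``a01`` -> ``A1``.

    Raises ``ValueError`` for anything that is not row letter (A-P) plus a
    1-2 digit column number.
    """
    m = _WELL_RE.match(address.strip())
    if m is None:
        raise ValueError(f"invalid well address: {address!r}")
    return f"{m.group(1).upper()}{int(m.group(2))}"


def plate_addresses(geometry: int) -> list[str]:
    """All well addresses of a 96- (8x12) or 384-well (16x24) plate, row-major."""
    if geometry == 96:
        rows, ncol = _ROWS_96, 12
    elif geometry == 384:
        rows, ncol = _ROWS_384, 24
    else:
        raise ValueError(f"unsupported plate geometry: {geometry} (expected 96 or 384)")
    return [f"{r}{c}" for r in rows for c in range(1, ncol + 1)]


@dataclass(frozen=True)
class WellRole:
    """Role of one well: compound (with id and dose), solvent control, or empty."""

    role: str
    compound_id: str | None = None
    dose_uM: float | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_COMPOUND, ROLE_CONTROL, ROLE_EMPTY):
            raise ValueError(f"unknown well role: {self.role!r}")
        if self.role == ROLE_COMPOUND and not self.compound_id:
            raise ValueError("compound wells require a compound_id")


@dataclass
class PlateLayout:
    """Map from well address to role for one physical plate.

    Invariants enforced on construction: addresses are unique and fit the
    plate geometry (96 or 384), and any plate that carries compounds has at
    least ``min_controls`` solvent-control wells (the screen design places at
    least four DMSO controls on every compound plate).
    """

    plate_id: str
    wells: dict[str, WellRole]
    geometry: int = 96
    min_controls: int = 4

    def __post_init__(self) -> None:
        valid = set(plate_addresses(self.geometry))
        canon: dict[str, WellRole] = {}
        for addr, role in self.wells.items():
            c = canonical_well(addr)
            if c not in valid:
                raise PlateFormatError(
                    f"well {c} outside {self.geometry}-well geometry on plate {self.plate_id}"
                )
            if c in canon:
                raise PlateFormatError(f"duplicate well {c} on plate {self.plate_id}")
            canon[c] = role
        self.wells = canon
        if self.compound_wells() and len(self.control_wells()) < self.min_controls:
            raise PlateFormatError(
                f"plate {self.plate_id} carries compounds but has "
                f"{len(self.control_wells())} solvent controls (< {self.min_controls})"
            )

    def compound_wells(self) -> list[str]:
        return [w for w, r in self.wells.items() if r.role == ROLE_COMPOUND]

    def control_wells(self) -> list[str]:
        return [w for w, r in self.wells.items() if r.role == ROLE_CONTROL]

    def non_empty_wells(self) -> list[str]:
        return [w for w, r in self.wells.items() if r.role != ROLE_EMPTY]


@dataclass
class WellSeries:
    """One well's optical-density time course.

    ``times`` are hours, strictly increasing; ``od`` is dimensionless OD600,
    finite and non-negative, one reading per timepoint.
    """

    plate_id: str
    well: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.well = canonical_well(self.well)
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size or self.times.size < 2:
            raise ValueError(
                f"well {self.well}: need >= 2 matched time/OD points "
                f"(got {self.times.size} times, {self.od.size} readings)"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well}: times not strictly increasing")
        if not np.all(np.isfinite(self.od)) or np.any(self.od < 0):
            raise ValueError(f"well {self.well}: OD values must be finite and >= 0")


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound: identifier, SMILES, source library, screen dose."""

    compound_id: str
    smiles: str
    library: str = ""
    screen_dose_uM: float = DEFAULT_SCREEN_DOSE_UM


@dataclass
class LibraryLoad:
    """Result of reading a compound library: parsed records plus a rejection
    report for rows whose SMILES RDKit could not parse."""

    records: list[CompoundRecord]
    rejected: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AcuteReadout:
    """Acute-assay readout for one well.

    ``fluorescence`` is the chlorophyll-fluorescence endpoint (arbitrary
    units); ``phototaxis_score`` is a pre-categorized image call; ``regrew``
    records regrowth after pinning onto compound-free agar. At least one of
    the three must be present.
    """

    plate_id: str
    well: str
    fluorescence: float | None = None
    phototaxis_score: str | None = None
    phototaxis_score_2: str | None = None
    regrew: bool | None = None

    PHOTOTAXIS_SCORES = frozenset(
        {"toward_light", "away_from_light", "no_movement", "lysed"}
    )

    def __post_init__(self) -> None:
        self.well = canonical_well(self.well)
        if (
            self.fluorescence is None
            and self.phototaxis_score is None
            and self.regrew is None
        ):
            raise ValueError(f"well {self.well}: acute readout carries no measurement")
        if self.fluorescence is not None and not self.fluorescence >= 0:
            raise ValueError(f"well {self.well}: fluorescence must be >= 0")
        for s in (self.phototaxis_score, self.phototaxis_score_2):
            if s is not None and s not in self.PHOTOTAXIS_SCORES:
                raise ValueError(f"well {self.well}: unknown phototaxis score {s!r}")


# ---------------------------------------------------------------------------
# layout


def read_layout(path: str | Path, plate_id: str | None = None, geometry: int = 96) -> PlateLayout:
    """Read a ``well,role,compound_id,dose_uM`` CSV layout file."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"well", "role"}
    if not required.issubset(df.columns):
        raise PlateFormatError(f"{path.name}: layout needs columns {sorted(required)}")
    wells: dict[str, WellRole] = {}
    for _, row in df.iterrows():
        role = row["role"].strip()
        cid = row.get("compound_id", "") or None
        dose = row.get("dose_uM", "")
        wells[row["well"]] = WellRole(
            role=role,
            compound_id=cid,
            dose_uM=float(dose) if dose else None,
        )
    return PlateLayout(plate_id=plate_id or path.stem, wells=wells, geometry=geometry)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {
            "well": w,
            "role": r.role,
            "compound_id": r.compound_id or "",
            "dose_uM": "" if r.dose_uM is None else r.dose_uM,
        }
        for w, r in sorted(layout.wells.items())
    ]
    pd.DataFrame(rows, columns=["well", "role", "compound_id", "dose_uM"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# growth tables


def read_growth_table(
    path: str | Path,
    layout: PlateLayout,
    time_unit: str = "hours",
) -> list[WellSeries]:
    """Read a growth table (``well,t0,t1,...`` with times in the header) into
    one :class:`WellSeries` per non-empty layout well.

    Wells present in the layout but missing from the file are reported via a
    :class:`PlateIOWarning`; wells in the file but not in the layout are
    rejected (dropped, with a warning). ``time_unit`` may be ``"minutes"`` for
    instruments that export minute headers; times are stored in hours.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first_line = fh.readline()
    # parse the header ourselves: pandas mangles duplicate column names,
    # which would hide a repeated timepoint from the monotonicity check
    delim = "\t" if "\t" in first_line else ","
    header = next(csv.reader([first_line], delimiter=delim))
    if not header or header[0].strip().lower() != "well":
        raise PlateFormatError(f"{path.name}: first column must be 'well'")
    try:
        times = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise PlateFormatError(f"{path.name}: non-numeric time header: {exc}") from exc
    if time_unit == "minutes":
        times = times / 60.0
    elif time_unit != "hours":
        raise ValueError(f"unknown time_unit {time_unit!r}")
    if times.size < 2 or not np.all(np.diff(times) > 0):
        raise PlateFormatError(f"{path.name}: header times not strictly increasing")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delim)

    wanted = set(layout.non_empty_wells())
    seen: dict[str, WellSeries] = {}
    extraneous: list[str] = []
    for _, row in df.iterrows():
        well = canonical_well(row.iloc[0])
        if well not in wanted:
            extraneous.append(well)
            continue
        od = np.empty(times.size)
        for j, cell in enumerate(row.iloc[1:]):
            try:
                od[j] = float(cell)
            except ValueError:
                raise PlateParseError(
                    f"{path.name}: non-numeric OD in well {well} at "
                    f"t={times[j]:g} h: {cell!r}"
                ) from None
        seen[well] = WellSeries(plate_id=layout.plate_id, well=well, times=times, od=od)

    missing = sorted(wanted - seen.keys())
    if missing:
        warnings.warn(
            f"{path.name}: layout wells missing from file: {', '.join(missing)}",
            PlateIOWarning,
            stacklevel=2,
        )
    if extraneous:
        warnings.warn(
            f"{path.name}: rejected wells absent from layout: {', '.join(sorted(extraneous))}",
            PlateIOWarning,
            stacklevel=2,
        )
    return [seen[w] for w in sorted(seen)]


def write_growth_table(series: Sequence[WellSeries], path: str | Path) -> None:
    """Write WellSeries back to the tabular format, full float precision.

    All series must share one time grid (one plate's export).
    """
    if not series:
        raise ValueError("no series to write")
    times = series[0].times
    for s in series:
        if s.times.size != times.size or not np.array_equal(s.times, times):
            raise ValueError("all series must share the same time grid")
    cols = ["well"] + [repr(float(t)) for t in times]
    rows = [[s.well] + [repr(float(v)) for v in s.od] for s in series]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# compound libraries


def read_compound_library(
    path: str | Path,
    library: str | None = None,
    default_dose_uM: float = DEFAULT_SCREEN_DOSE_UM,
) -> LibraryLoad:
    """Read a compound library from CSV (``compound_id``/``smiles`` columns,
    optional ``library`` and ``dose_uM``) or a plain SMILES file
    (``SMILES<tab>id`` per line; extension ``.smi``/``.smiles``).

    Rows whose SMILES RDKit cannot parse are dropped and listed in the
    returned rejection report. Duplicate compound ids are an error.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, float]] = []
    if path.suffix.lower() in (".smi", ".smiles"):
        lib = library or path.stem
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{i + 1}"
            rows.append((cid, smiles, lib, default_dose_uM))
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = {c.lower().strip(): c for c in df.columns}
        if "compound_id" not in cols or "smiles" not in cols:
            raise PlateFormatError(
                f"{path.name}: need 'compound_id' and 'smiles' columns"
            )
        for _, row in df.iterrows():
            cid = row[cols["compound_id"]].strip()
            smiles = row[cols["smiles"]].strip()
            lib = (
                row[cols["library"]].strip()
                if "library" in cols
                else (library or path.stem)
            )
            dose = row[cols["dose_um"]] if "dose_um" in cols else ""
            rows.append((cid, smiles, lib, float(dose) if dose else default_dose_uM))

    seen_ids: set[str] = set()
    records: list[CompoundRecord] = []
    rejected: list[str] = []
    for cid, smiles, lib, dose in rows:
        if cid in seen_ids:
            raise ValueError(f"{path.name}: duplicate compound_id {cid!r}")
        seen_ids.add(cid)
        if Chem.MolFromSmiles(smiles) is None:
            rejected.append(cid)
            continue
        records.append(
            CompoundRecord(compound_id=cid, smiles=smiles, library=lib, screen_dose_uM=dose)
        )
    if rejected:
        warnings.warn(
            f"{path.name}: dropped {len(rejected)} record(s) with unparseable "
            f"SMILES: {', '.join(rejected[:10])}",
            PlateIOWarning,
            stacklevel=2,
        )
    return LibraryLoad(records=records, rejected=rejected)


def write_compound_library(records: Iterable[CompoundRecord], path: str | Path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "library": r.library,
            "dose_uM": r.screen_dose_uM,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["compound_id", "smiles", "library", "dose_uM"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# acute readouts


def _parse_bool(cell: str) -> bool | None:
    cell = cell.strip().lower()
    if cell in ("", "na", "nan", "missing"):
        return None
    if cell in ("1", "true", "yes", "y"):
        return True
    if cell in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot parse boolean cell {cell!r}")


def read_acute_table(path: str | Path, plate_id: str | None = None) -> list[AcuteReadout]:
    """Read an acute readout CSV:
    ``well,fluorescence,phototaxis_score_1,phototaxis_score_2,regrew``.

    Empty cells mean the measurement is missing for that well.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "well" not in df.columns:
        raise PlateFormatError(f"{path.name}: acute table needs a 'well' column")
    out: list[AcuteReadout] = []
    for _, row in df.iterrows():
        fluor = row.get("fluorescence", "").strip()
        s1 = row.get("phototaxis_score_1", "").strip() or None
        s2 = row.get("phototaxis_score_2", "").strip() or None
        out.append(
            AcuteReadout(
                plate_id=plate_id or path.stem,
                well=row["well"],
                fluorescence=float(fluor) if fluor else None,
                phototaxis_score=s1,
                phototaxis_score_2=s2,
                regrew=_parse_bool(row.get("regrew", "")),
            )
        )
    return out


def write_acute_table(readouts: Sequence[AcuteReadout], path: str | Path) -> None:
    rows = [
        {
            "well": r.well,
            "fluorescence": "" if r.fluorescence is None else r.fluorescence,
            "phototaxis_score_1": r.phototaxis_score or "",
            "phototaxis_score_2": r.phototaxis_score_2 or "",
            "regrew": "" if r.regrew is None else int(r.regrew),
        }
        for r in readouts
    ]
    pd.DataFrame(
        rows,
        columns=["well", "fluorescence", "phototaxis_score_1", "phototaxis_score_2", "regrew"],
    ).to_csv(path, index=False)
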