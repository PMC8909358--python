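"""Reading, writing and labelling of per-well extracellular-flux rate tables.

Rates are carried per well in the instrument's native units
(OCR: pmol O2/min/well, ECAR: mpH/min/well) and never converted silently.
A :class:`PlateKinetics` bundles the per-well series with the plate layout
and, once assigned, the injection schedule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DuplicateRecordError,
    FormatError,
    LayoutError,
    ScheduleError,
    StateError,
)

OCR_UNITS = "pmol O2/min/well"
ECAR_UNITS = "mpH/min/well"

PHASE_NAMES = ("basal", "oligomycin", "fccp", "rot_aa")

RATE_COLUMNS = ["well", "measurement", "time_min", "OCR", "ECAR"]
LAYOUT_COLUMNS = ["well", "group", "is_background"]


@dataclass(frozen=True)
class PlateLayout:
    """Maps well ids to group labels and background flags."""

    groups: dict[str, str]
    background: frozenset[str]

    def __post_init__(self) -> None:
        missing = self.background - set(self.groups)
        if missing:
            raise LayoutError(f"background wells not in layout: {sorted(missing)}")

    @property
    def wells(self) -> list[str]:
        return list(self.groups)

    def is_background(self, well_id: str) -> bool:
        return well_id in self.background

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        for col in LAYOUT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"layout file is missing required column {col!r}")
        if df["well"].duplicated().any():
            dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
            raise DuplicateRecordError(f"well {dup!r} appears twice in layout")
        flags = df["is_background"].map(_parse_bool)
        groups = dict(zip(df["well"].astype(str), df["group"].astype(str)))
        bg = frozenset(df.loc[flags.values, "well"].astype(str))
        return cls(groups=groups, background=bg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": self.wells,
                "group": [self.groups[w] for w in self.wells],
                "is_background": [w in self.background for w in self.wells],
            }
        )


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise FormatError(f"cannot interpret {v!r} as a boolean is_background flag")


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered assay phases with 1-based inclusive measurement index ranges."""

    phases: tuple[tuple[str, int, int], ...]
    drug_final_concentrations_um: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ScheduleError("schedule has no phases")
        names = [p[0] for p in self.phases]
        order = [n for n in PHASE_NAMES if n in names]
        if names != order:
            raise ScheduleError(
                f"phases must follow the order {PHASE_NAMES}, got {names}"
            )
        expected_first = 1
        for name, first, last in self.phases:
            if first != expected_first:
                raise ScheduleError(
                    f"phase {name!r} starts at {first}, expected {expected_first}: "
                    "index ranges must be contiguous from 1"
                )
            if last < first:
                raise ScheduleError(f"phase {name!r} has empty range {first}-{last}")
            expected_first = last + 1

    @property
    def n_measurements(self) -> int:
        return self.phases[-1][2]

    def phase_of(self, index: int) -> str:
        for name, first, last in self.phases:
            if first <= index <= last:
                return name
        raise ScheduleError(f"measurement index {index} outside schedule 1-{self.n_measurements}")

    def indices(self, phase: str) -> list[int]:
        for name, first, last in self.phases:
            if name == phase:
                return list(range(first, last + 1))
        raise ScheduleError(f"phase {phase!r} not in schedule")

    @classmethod
    def default_mito_stress(cls) -> "InjectionSchedule":
        return cls(
            phases=(
                ("basal", 1, 3),
                ("oligomycin", 4, 8),
                ("fccp", 9, 12),
                ("rot_aa", 13, 16),
            ),
            drug_final_concentrations_um={"oligomycin": 2.0, "fccp": 2.0, "rot_aa": 0.5},
        )

    @classmethod
    def from_dict(cls, cfg: dict) -> "InjectionSchedule":
        phases = tuple(
            (p["name"], int(p["first"]), int(p["last"])) for p in cfg["phases"]
        )
        drugs = {str(k): float(v) for k, v in cfg.get("drug_final_concentrations_um", {}).items()}
        return cls(phases=phases, drug_final_concentrations_um=drugs)

    @classmethod
    def from_yaml(cls, path) -> "InjectionSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "phases": [
                {"name": n, "first": f, "last": l} for n, f, l in self.phases
            ],
            "drug_final_concentrations_um": dict(self.drug_final_concentrations_um),
        }


@dataclass(frozen=True)
class WellKinetics:
    """One well's OCR/ECAR time series, optionally phase-labelled."""

    well_id: str
    index: np.ndarray
    time_min: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray
    phase: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.index)
        if not (len(self.time_min) == len(self.ocr) == len(self.ecar) == n):
            raise FormatError(f"well {self.well_id}: ragged measurement arrays")
        if n and np.any(np.diff(self.index) <= 0):
            raise FormatError(f"well {self.well_id}: measurement indices not strictly increasing")
        if n and np.any(np.diff(self.time_min) < 0):
            raise FormatError(f"well {self.well_id}: times decrease")
        if self.phase is not None and len(self.phase) != n:
            raise FormatError(f"well {self.well_id}: phase labels do not match measurements")

    @property
    def n_measurements(self) -> int:
        return len(self.index)

    def ocr_in_phase(self, phase: str) -> np.ndarray:
        if self.phase is None:
            raise StateError("phases not assigned")
        sel = np.array([p == phase for p in self.phase])
        return self.ocr[sel]

    def ecar_in_phase(self, phase: str) -> np.ndarray:
        if self.phase is None:
            raise StateError("phases not assigned")
        sel = np.array([p == phase for p in self.phase])
        return self.ecar[sel]


@dataclass(frozen=True)
class PlateKinetics:
    """All wells of one plate plus layout, schedule and correction state."""

    wells: dict[str, WellKinetics]
    layout: PlateLayout
    schedule: InjectionSchedule | None = None
    background_corrected: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.wells) - set(self.layout.groups)
        if unknown:
            raise LayoutError(f"wells missing from layout: {sorted(unknown)}")
        index_sets = {tuple(wk.index.tolist()) for wk in self.wells.values()}
        if len(index_sets) > 1:
            raise FormatError("wells do not share a common measurement index set")

    @property
    def measurement_indices(self) -> list[int]:
        first = next(iter(self.wells.values()))
        return first.index.tolist()

    @property
    def sample_wells(self) -> list[str]:
        return [w for w in self.wells if not self.layout.is_background(w)]

    @property
    def background_wells(self) -> list[str]:
        return [w for w in self.wells if self.layout.is_background(w)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for wk in self.wells.values():
            for k in range(wk.n_measurements):
                rows.append(
                    (wk.well_id, int(wk.index[k]), float(wk.time_min[k]),
                     float(wk.ocr[k]), float(wk.ecar[k]))
                )
        return pd.DataFrame(rows, columns=RATE_COLUMNS)


def read_rate_table(path, layout_path) -> PlateKinetics:
    """Parse a rates CSV and its plate layout into a :class:`PlateKinetics`.

    The rates file must carry columns ``well,measurement,time_min,OCR,ECAR``;
    row order is irrelevant. Phases are left unassigned and
    ``background_corrected`` is False.
    """
    rates = pd.read_csv(path)
    layout = PlateLayout.from_frame(pd.read_csv(layout_path))
    return plate_from_frame(rates, layout)


def plate_from_frame(rates: pd.DataFrame, layout: PlateLayout) -> PlateKinetics:
    for col in RATE_COLUMNS:
        if col not in rates.columns:
            raise FormatError(f"rate table is missing required column {col!r}")
    dup = rates.duplicated(subset=["well", "measurement"])
    if dup.any():
        w, m = rates.loc[dup, ["well", "measurement"]].iloc[0]
        raise DuplicateRecordError(f"duplicate record for well {w!r} measurement {m}")
    unknown = set(rates["well"].astype(str)) - set(layout.groups)
    if unknown:
        raise LayoutError(f"rate-table wells absent from layout: {sorted(unknown)}")

    wells: dict[str, WellKinetics] = {}
    rates = rates.sort_values(["well", "measurement"], kind="mergesort")
    for well_id, sub in rates.groupby("well", sort=True):
        wells[str(well_id)] = WellKinetics(
            well_id=str(well_id),
            index=sub["measurement"].to_numpy(dtype=int),
            time_min=sub["time_min"].to_numpy(dtype=float),
            ocr=sub["OCR"].to_numpy(dtype=float),
            ecar=sub["ECAR"].to_numpy(dtype=float),
        )
    return PlateKinetics(wells=wells, layout=layout)


def write_rate_table(pk: PlateKinetics, path) -> None:
    """Write rates in the same CSV dialect read_rate_table consumes.

    Numbers are written with 6 significant digits (declared round-trip
    precision).
    """
    df = pk.to_frame()
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def apply_background_correction(pk: PlateKinetics) -> PlateKinetics:
    """Subtract the per-index mean background OCR/ECAR from every well.

    Background wells themselves are corrected too, so their post-correction
    mean is identically zero at every index.
    """
    if pk.background_corrected:
        raise StateError("plate is already background-corrected")
    bg = pk.background_wells
    if not bg:
        raise ConfigurationError("background correction requested but layout has no background wells")

    ocr_bg = np.mean([pk.wells[w].ocr for w in bg], axis=0)
    ecar_bg = np.mean([pk.wells[w].ecar for w in bg], axis=0)

    corrected = {
        wid: replace(wk, ocr=wk.ocr - ocr_bg, ecar=wk.ecar - ecar_bg)
        for wid, wk in pk.wells.items()
    }
    return replace(pk, wells=corrected, background_corrected=True)


def assign_phases(pk: PlateKinetics, schedule: InjectionSchedule) -> PlateKinetics:
    """Label every measurement with its injection phase (pure relabelling)."""
    indices = pk.measurement_indices
    if indices and (min(indices) < 1 or max(indices) > schedule.n_measurements):
        raise ScheduleError(
            f"schedule covers 1-{schedule.n_measurements} but plate has "
            f"indices {min(indices)}-{max(indices)}"
        )
    labelled = {
        wid: replace(wk, phase=tuple(schedule.phase_of(int(i)) for i in wk.index))
        for wid, wk in pk.wells.items()
    }
    return replace(pk, wells=labelled, schedule=schedule)
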