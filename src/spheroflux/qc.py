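"""Well-level quality control: movement artifacts, rate jumps, exclusions.

A spheroid that moves off the sensor during the mixing step shows up as a
sudden OCR change between two measurements of the SAME phase; changes across
an injection boundary are expected and never tested. Flagged wells are
excluded (not repaired) before parameter extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PipelineError, StateError, ValidationError
from .flux_io import InjectionSchedule, PlateKinetics, WellKinetics
from .morphometry import MorphometryResult, centroid_displacement

#: Relative OCR-change threshold for within-phase jump detection. Adjacent
#: same-phase means in well-behaved assays drift by <= ~20%, so 0.4 leaves
#: genuine kinetics unflagged while catching off-sensor shifts (>= ~50%).
DEFAULT_JUMP_THETA = 0.4
#: Displacement threshold, about one spheroid radius.
DEFAULT_DISPLACEMENT_UM = 200.0
#: Small-rate guard in the jump denominator (pmol/min).
JUMP_EPSILON = 1.0

FLAG_RATE_JUMP = "rate_jump"
FLAG_DISPLACED = "displaced"
FLAG_INCOMPLETE = "incomplete"
FLAG_BORDER = "border_truncated"
FLAG_NEGATIVE = "negative_rate"
FLAG_ECAR_JUMP = "ecar_jump"  # informational only, never excludes

#: Flags that exclude a well under the default policy.
DEFAULT_EXCLUDING_FLAGS = frozenset({FLAG_RATE_JUMP, FLAG_DISPLACED, FLAG_INCOMPLETE})


@dataclass
class QCReport:
    """Per-well QC outcome."""

    well_id: str
    flags: set[str] = field(default_factory=set)
    jump_index: int | None = None
    displacement_um: float | None = None
    excluded: bool = False

    def finalize(self, excluding_flags: frozenset[str] = DEFAULT_EXCLUDING_FLAGS) -> "QCReport":
        self.excluded = bool(self.flags & excluding_flags)
        return self


def _relative_jumps(values: np.ndarray, phases: tuple[str, ...]) -> list[tuple[int, float]]:
    out = []
    for i in range(1, len(values)):
        if phases[i] != phases[i - 1]:
            continue  # injection boundary: change is the assay, not an artifact
        denom = max(abs(values[i - 1]), JUMP_EPSILON)
        out.append((i, abs(values[i] - values[i - 1]) / denom))
    return out


def detect_rate_jumps(
    wk: WellKinetics,
    schedule: InjectionSchedule,
    theta: float = DEFAULT_JUMP_THETA,
) -> QCReport:
    """Flag sudden within-phase OCR variations.

    The jump statistic for consecutive same-phase measurements is
    ``|OCR_i - OCR_{i-1}| / max(|OCR_{i-1}|, 1)``; the first index exceeding
    ``theta`` is recorded. ECAR jumps are reported informationally and never
    drive exclusion.
    """
    if wk.phase is None:
        raise StateError(f"well {wk.well_id}: phases must be assigned before QC")
    report = QCReport(well_id=wk.well_id)

    expected = set(range(1, schedule.n_measurements + 1))
    if set(int(i) for i in wk.index) != expected:
        report.flags.add(FLAG_INCOMPLETE)
        return report.finalize()

    for i, j in _relative_jumps(wk.ocr, wk.phase):
        if j > theta:
            report.flags.add(FLAG_RATE_JUMP)
            report.jump_index = int(wk.index[i])
            break
    for i, j in _relative_jumps(wk.ecar, wk.phase):
        if j > theta:
            report.flags.add(FLAG_ECAR_JUMP)
            break
    return report.finalize()


def detect_displacement(
    pre: MorphometryResult | None,
    post: MorphometryResult | None,
    delta_um: float = DEFAULT_DISPLACEMENT_UM,
    well_id: str = "",
) -> QCReport:
    """Flag wells whose spheroid moved more than ``delta_um`` during the assay."""
    report = QCReport(well_id=well_id)
    if pre is None or post is None:
        report.flags.add(FLAG_INCOMPLETE)
        return report.finalize()
    d = centroid_displacement(pre, post)
    report.displacement_um = d
    if d > delta_um:
        report.flags.add(FLAG_DISPLACED)
    if pre.border_touching or post.border_touching:
        report.flags.add(FLAG_BORDER)
    return report.finalize()


def merge_reports(*reports: QCReport) -> QCReport:
    """Union the flags of several reports for the same well."""
    wells = {r.well_id for r in reports}
    if len(wells) != 1:
        raise ValidationError(f"cannot merge reports for different wells {sorted(wells)}")
    merged = QCReport(well_id=reports[0].well_id)
    for r in reports:
        merged.flags |= r.flags
        if merged.jump_index is None:
            merged.jump_index = r.jump_index
        if merged.displacement_um is None:
            merged.displacement_um = r.displacement_um
    return merged.finalize()


def apply_exclusions(
    pk: PlateKinetics,
    reports: dict[str, QCReport],
    excluding_flags: frozenset[str] = DEFAULT_EXCLUDING_FLAGS,
    report_only: bool = False,
) -> tuple[PlateKinetics, pd.DataFrame]:
    """Drop excluded sample wells and return the surviving plate + table.

    Background wells are never excluded by rate_jump (their near-zero rates
    make the relative statistic meaningless). With ``report_only`` no well is
    removed; the table still records all flags.
    """
    missing = set(pk.wells) - set(reports)
    if missing:
        raise ValidationError(f"no QC report for wells {sorted(missing)}")

    rows = []
    keep: dict[str, WellKinetics] = {}
    for wid, wk in pk.wells.items():
        rep = reports[wid]
        flags = set(rep.flags)
        if pk.layout.is_background(wid):
            flags.discard(FLAG_RATE_JUMP)
        excluded = bool(flags & excluding_flags) and not report_only
        rows.append(
            {
                "well": wid,
                "flags": ";".join(sorted(flags)),
                "jump_index": rep.jump_index,
                "displacement_um": rep.displacement_um,
                "excluded": excluded,
            }
        )
        if not excluded:
            keep[wid] = wk

    table = pd.DataFrame(rows, columns=["well", "flags", "jump_index", "displacement_um", "excluded"])
    surviving_samples = [w for w in keep if not pk.layout.is_background(w)]
    if pk.sample_wells and not surviving_samples:
        raise PipelineError("QC excluded every sample well; check thresholds and data")
    layout = pk.layout
    kept_layout = replace(
        layout,
        groups={w: g for w, g in layout.groups.items() if w in keep},
        background=frozenset(w for w in layout.background if w in keep),
    )
    return replace(pk, wells=keep, layout=kept_layout), table
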