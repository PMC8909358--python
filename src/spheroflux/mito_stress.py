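"""Mito Stress respiration parameters from a phase-labelled OCR series.

Definitions (all rates on the same basis):

* non-mitochondrial respiration: minimum OCR after rotenone/antimycin A
* basal respiration:             last basal OCR - non-mito
* ATP-linked respiration:        last basal OCR - minimum OCR after oligomycin
* proton leak:                   oligomycin minimum - non-mito
* maximal respiration:           FCCP-phase maximum - non-mito
* spare capacity:                maximal - basal (also reported as % of basal)

"Basal" is the LAST pre-injection measurement (conventionally the 3rd), not
the basal-phase mean. Maximal respiration subtracts non-mito (vendor
convention); callers comparing against raw FCCP plateaus can add it back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import IncompleteWellError, NormalizationError, ValidationError
from .flux_io import InjectionSchedule, WellKinetics

BASIS_PER_WELL = "per_well"
BASIS_PER_1000_CELLS = "per_1000_cells"
BASIS_PER_1000_UM2 = "per_1000_um2"

RATE_FIELDS = (
    "non_mito",
    "basal_resp",
    "atp_linked",
    "proton_leak",
    "maximal_resp",
    "spare_capacity",
    "last_basal_ocr",
    "last_basal_ecar",
    "stressed_ocr",
    "stressed_ecar",
)


@dataclass(frozen=True)
class MitoStressParams:
    """Six respiration parameters plus basal/stressed operating points."""

    well_id: str
    non_mito: float
    basal_resp: float
    atp_linked: float
    proton_leak: float
    maximal_resp: float
    spare_capacity: float
    spare_capacity_pct: float  # NaN when basal_resp <= 0
    last_basal_ocr: float
    last_basal_ecar: float
    stressed_ocr: float
    stressed_ecar: float
    basis: str = BASIS_PER_WELL
    quality_flag: str = ""


def extract_params(wk: WellKinetics, schedule: InjectionSchedule) -> MitoStressParams:
    """Per-well Mito Stress parameters from a phase-labelled kinetics series."""
    if wk.phase is None:
        raise IncompleteWellError(f"well {wk.well_id}: phases not assigned")

    basal_ocr = wk.ocr_in_phase("basal")
    oligo_ocr = wk.ocr_in_phase("oligomycin")
    fccp_ocr = wk.ocr_in_phase("fccp")
    rotaa_ocr = wk.ocr_in_phase("rot_aa")
    for name, arr in (("basal", basal_ocr), ("oligomycin", oligo_ocr),
                      ("fccp", fccp_ocr), ("rot_aa", rotaa_ocr)):
        if arr.size == 0:
            raise IncompleteWellError(f"well {wk.well_id}: no measurements in phase {name!r}")

    last_basal = float(basal_ocr[-1])
    last_basal_ecar = float(wk.ecar_in_phase("basal")[-1])
    oligo_min = float(oligo_ocr.min())
    fccp_max = float(fccp_ocr.max())
    non_mito = float(rotaa_ocr.min())

    # Stressed operating point: the FCCP measurement where OCR peaks.
    fccp_ecar = wk.ecar_in_phase("fccp")
    k = int(np.argmax(fccp_ocr))
    stressed_ocr = float(fccp_ocr[k])
    stressed_ecar = float(fccp_ecar[k])

    basal_resp = last_basal - non_mito
    atp_linked = last_basal - oligo_min
    proton_leak = oligo_min - non_mito
    maximal_resp = fccp_max - non_mito
    spare = maximal_resp - basal_resp
    if basal_resp > 0:
        spare_pct = 100.0 * maximal_resp / basal_resp
        flag = ""
    else:
        spare_pct = float("nan")
        flag = "nonpositive_basal"

    return MitoStressParams(
        well_id=wk.well_id,
        non_mito=non_mito,
        basal_resp=basal_resp,
        atp_linked=atp_linked,
        proton_leak=proton_leak,
        maximal_resp=maximal_resp,
        spare_capacity=spare,
        spare_capacity_pct=spare_pct,
        last_basal_ocr=last_basal,
        last_basal_ecar=last_basal_ecar,
        stressed_ocr=stressed_ocr,
        stressed_ecar=stressed_ecar,
        basis=BASIS_PER_WELL,
        quality_flag=flag,
    )


def normalize_params(
    p: MitoStressParams,
    cells: float | None = None,
    area_um2: float | None = None,
) -> MitoStressParams:
    """Express per-well parameters per 1000 cells or per 1000 um^2 of area.

    Exactly one denominator must be given. spare_capacity_pct is a ratio and
    is left unchanged.
    """
    if p.basis != BASIS_PER_WELL:
        raise ValidationError(f"params already normalized (basis {p.basis!r})")
    if (cells is None) == (area_um2 is None):
        raise ValidationError("give exactly one of cells= or area_um2=")
    if cells is not None:
        if cells <= 0:
            raise NormalizationError(f"well {p.well_id}: cells must be positive")
        denom, basis = cells / 1000.0, BASIS_PER_1000_CELLS
    else:
        if area_um2 <= 0:
            raise NormalizationError(f"well {p.well_id}: area must be positive")
        denom, basis = area_um2 / 1000.0, BASIS_PER_1000_UM2
    scaled = {f: getattr(p, f) / denom for f in RATE_FIELDS}
    return replace(p, basis=basis, **scaled)
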