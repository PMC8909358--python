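"""Synthetic spheroid cohorts: cell counts, areas, images and four-phase
OCR/ECAR kinetics with protocol-dependent noise, background wells and
optional movement artifacts.

The generator is fully deterministic given (config, seed) and emits a truth
table alongside the observable data, so recovery of known quantities can be
asserted at every pipeline stage.

Rate kinetics use a geometric approach to a per-phase target level: within a
phase, r_k = target + (r_{k-1} - target) * d, which gives the monotone
within-phase drift seen in real Mito Stress series. The per-phase approach
factors are arbitrary smoothing constants, not biological estimates.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import ellipe

from .calibration import CalibrationPoint
from .errors import ConfigurationError, ValidationError
from .flux_io import (
    InjectionSchedule,
    PlateKinetics,
    PlateLayout,
    WellKinetics,
    write_rate_table,
)
from .morphometry import ImageStack

#: Within-phase geometric approach factor per phase (closer to 1 = slower).
PHASE_APPROACH = {"basal": 0.6, "oligomycin": 0.8, "fccp": 0.35, "rot_aa": 0.7}
#: Basal series starts above its settling level by this factor.
BASAL_OVERSHOOT = 1.25
#: ECAR settles to this fraction of basal after rotenone/antimycin A.
ECAR_ROTAA_FRACTION = 0.8
#: Background-well rate noise (absolute SD, instrument floor).
BACKGROUND_OCR_SD = 0.3
BACKGROUND_ECAR_SD = 0.05
MINUTES_PER_MEASUREMENT = 6.5


@dataclass(frozen=True)
class CellLineProfile:
    """Per-cell bioenergetic parameters of a synthetic cell line."""

    name: str
    per_cell_basal_ocr: float   # pmol O2/min per 1000 cells
    per_cell_basal_ecar: float  # mpH/min per 1000 cells
    oligo_fraction: float       # OCR remaining after oligomycin, as fraction of basal
    fccp_multiplier: float      # maximal / basal OCR ratio
    non_mito_fraction: float    # OCR remaining after rot/AA, as fraction of basal
    stress_ecar_multiplier: float = 1.4

    def __post_init__(self) -> None:
        if not (0.0 < self.non_mito_fraction < self.oligo_fraction < 1.0):
            raise ValidationError(
                "need 0 < non_mito_fraction < oligo_fraction < 1"
            )
        if self.fccp_multiplier < 0 or self.stress_ecar_multiplier < 1:
            raise ValidationError("fccp_multiplier >= 0 and stress_ecar_multiplier >= 1 required")
        if self.per_cell_basal_ocr <= 0 or self.per_cell_basal_ecar <= 0:
            raise ValidationError("per-cell rates must be positive")


#: Qualitative aerobic-vs-glycolytic contrast; synthetic parameters, not
#: measurements of any real cell line.
AEROBIC_PROFILE = CellLineProfile(
    name="synthetic-aerobic",
    per_cell_basal_ocr=4.7,
    per_cell_basal_ecar=1.8,
    oligo_fraction=0.85,
    fccp_multiplier=1.6,
    non_mito_fraction=0.45,
    stress_ecar_multiplier=1.5,
)
GLYCOLYTIC_PROFILE = CellLineProfile(
    name="synthetic-glycolytic-quiescent",
    per_cell_basal_ocr=1.9,
    per_cell_basal_ecar=1.3,
    oligo_fraction=0.7,
    fccp_multiplier=1.3,
    non_mito_fraction=0.5,
    stress_ecar_multiplier=1.25,
)


@dataclass(frozen=True)
class ArtifactSpec:
    """A persistent level shift starting at a measurement index.

    Models a spheroid moved off the sensor: every OCR measurement from
    ``index`` onward is multiplied by (1 - magnitude).
    """

    well_offset: int      # offset into the cohort's sample wells
    index: int            # 1-based measurement index of the shift
    magnitude: float      # fraction of the current rate lost

    def __post_init__(self) -> None:
        if not (0.0 < self.magnitude < 1.0):
            raise ValidationError("artifact magnitude must be in (0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort (seed mandatory)."""

    protocol: str                      # "single" or "multiple"
    seed: int
    n_wells: int = 45
    n_background_wells: int = 4
    seeded_cells_per_well: float = 10_000.0
    growth_factor: float = 1.2
    cell_count_cv: float = 10.0        # percent
    measurement_noise_cv: float = 5.0  # percent
    area_noise_cv: float = 3.0         # percent
    area_per_cell_slope: float = 0.03  # cells per um^2
    area_intercept_cells: float = 0.0
    artifact_wells: tuple[ArtifactSpec, ...] = ()
    group_label: str | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("single", "multiple"):
            raise ConfigurationError("protocol must be 'single' or 'multiple'")
        if self.n_wells < 1:
            raise ConfigurationError("n_wells must be >= 1")
        if min(self.cell_count_cv, self.measurement_noise_cv, self.area_noise_cv) < 0:
            raise ConfigurationError("CVs must be >= 0")
        if self.growth_factor <= 0 or self.seeded_cells_per_well <= 0:
            raise ConfigurationError("growth_factor and seeded_cells_per_well must be positive")
        for a in self.artifact_wells:
            if not 0 <= a.well_offset < self.n_wells:
                raise ConfigurationError(f"artifact well_offset {a.well_offset} out of range")

    @property
    def group(self) -> str:
        return self.group_label or f"{self.protocol}-protocol"

    @classmethod
    def single_default(cls, seed: int, **kw) -> "CohortConfig":
        return cls(protocol="single", seed=seed, cell_count_cv=10.0,
                   measurement_noise_cv=5.0, **kw)

    @classmethod
    def multiple_default(cls, seed: int, **kw) -> "CohortConfig":
        return cls(protocol="multiple", seed=seed, cell_count_cv=50.0,
                   measurement_noise_cv=8.0, growth_factor=1.1,
                   seeded_cells_per_well=4_000.0, **kw)


@dataclass(frozen=True)
class SimulatedCohort:
    plate: PlateKinetics
    truth: pd.DataFrame
    calibration_points: list[CalibrationPoint]
    schedule: InjectionSchedule
    config: CohortConfig
    profile: CellLineProfile
    n_resampled: int


def _well_ids(n_samples: int, n_background: int) -> tuple[list[str], list[str]]:
    rows = "ABCDEFGH"
    ids = [f"{r}{c}" for r in rows for c in range(1, 13)]
    total = n_samples + n_background
    if total > len(ids):
        raise ConfigurationError(f"{total} wells exceed a 96-well plate")
    # background wells at the plate corners (instrument convention), spilling
    # over to the sequence tail when more than 4 are requested
    bg = ["A1", "A12", "H1", "H12"][:n_background]
    pool = [w for w in ids if w not in bg]
    extra = n_background - len(bg)
    if extra > 0:
        bg, pool = bg + pool[-extra:], pool[:-extra]
    return pool[:n_samples], bg


def _lognormal(rng: np.random.Generator, mean: float, cv_pct: float, size: int) -> np.ndarray:
    if cv_pct == 0:
        return np.full(size, mean)
    cv = cv_pct / 100.0
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _phase_targets(basal_level: float, profile: CellLineProfile) -> dict[str, float]:
    return {
        "basal": basal_level,
        "oligomycin": profile.oligo_fraction * basal_level,
        "fccp": profile.fccp_multiplier * basal_level,
        "rot_aa": profile.non_mito_fraction * basal_level,
    }


def _backbone(targets: dict[str, float], start: float, schedule: InjectionSchedule) -> np.ndarray:
    values = np.empty(schedule.n_measurements)
    prev = start
    k = 0
    for name, first, last in schedule.phases:
        t = targets[name]
        d = PHASE_APPROACH[name]
        for _ in range(first, last + 1):
            prev = t + (prev - t) * d
            values[k] = prev
            k += 1
    return values


def simulate_cohort(
    cfg: CohortConfig,
    profile: CellLineProfile = AEROBIC_PROFILE,
    schedule: InjectionSchedule | None = None,
) -> SimulatedCohort:
    """Generate one cohort: truth table, plate kinetics, calibration points."""
    schedule = schedule or InjectionSchedule.default_mito_stress()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_wells

    sample_ids, bg_ids = _well_ids(n, cfg.n_background_wells)
    mean_cells = cfg.seeded_cells_per_well * cfg.growth_factor
    true_cells = _lognormal(rng, mean_cells, cfg.cell_count_cv, n)
    true_area = (true_cells - cfg.area_intercept_cells) / cfg.area_per_cell_slope
    if cfg.area_noise_cv > 0:
        true_area = true_area * (1.0 + rng.normal(0.0, cfg.area_noise_cv / 100.0, n))

    artifact_by_offset = {a.well_offset: a for a in cfg.artifact_wells}
    noise_sd = cfg.measurement_noise_cv / 100.0
    n_meas = schedule.n_measurements
    time_min = np.arange(1, n_meas + 1) * MINUTES_PER_MEASUREMENT

    wells: dict[str, WellKinetics] = {}
    truth_rows = []
    n_resampled = 0

    for offset, wid in enumerate(sample_ids):
        cells = true_cells[offset]
        basal_ocr = cells / 1000.0 * profile.per_cell_basal_ocr
        basal_ecar = cells / 1000.0 * profile.per_cell_basal_ecar

        ocr_targets = _phase_targets(basal_ocr, profile)
        ecar_targets = {
            "basal": basal_ecar,
            "oligomycin": basal_ecar,
            "fccp": profile.stress_ecar_multiplier * basal_ecar,
            "rot_aa": ECAR_ROTAA_FRACTION * basal_ecar,
        }
        ocr = _backbone(ocr_targets, BASAL_OVERSHOOT * basal_ocr, schedule)
        ecar = _backbone(ecar_targets, basal_ecar, schedule)

        if noise_sd > 0:
            for series in (ocr, ecar):
                eps = rng.normal(0.0, noise_sd, n_meas)
                vals = series * (1.0 + eps)
                bad = vals <= 0
                while bad.any():  # extreme draws: resample, keep rates positive
                    n_resampled += int(bad.sum())
                    vals[bad] = series[bad] * (1.0 + rng.normal(0.0, noise_sd, int(bad.sum())))
                    bad = vals <= 0
                series[:] = vals

        art = artifact_by_offset.get(offset)
        if art is not None:
            ocr[art.index - 1:] *= 1.0 - art.magnitude

        wells[wid] = WellKinetics(
            well_id=wid,
            index=np.arange(1, n_meas + 1),
            time_min=time_min,
            ocr=ocr,
            ecar=ecar,
        )
        truth_rows.append(
            {
                "well": wid,
                "group": cfg.group,
                "is_background": False,
                "protocol": cfg.protocol,
                "seeded_cells": cfg.seeded_cells_per_well,
                "true_cells": cells,
                "area_um2": true_area[offset],
                "basal_ocr_level": basal_ocr,
                "basal_ecar_level": basal_ecar,
                "has_artifact": art is not None,
                "artifact_index": art.index if art else -1,
                "artifact_magnitude": art.magnitude if art else 0.0,
            }
        )

    for wid in bg_ids:
        wells[wid] = WellKinetics(
            well_id=wid,
            index=np.arange(1, n_meas + 1),
            time_min=time_min,
            ocr=rng.normal(0.0, BACKGROUND_OCR_SD, n_meas),
            ecar=rng.normal(0.0, BACKGROUND_ECAR_SD, n_meas),
        )
        truth_rows.append(
            {
                "well": wid, "group": "background", "is_background": True,
                "protocol": cfg.protocol, "seeded_cells": 0.0, "true_cells": 0.0,
                "area_um2": 0.0, "basal_ocr_level": 0.0, "basal_ecar_level": 0.0,
                "has_artifact": False, "artifact_index": -1, "artifact_magnitude": 0.0,
            }
        )

    layout = PlateLayout(
        groups={r["well"]: r["group"] for r in truth_rows},
        background=frozenset(bg_ids),
    )
    plate = PlateKinetics(wells=wells, layout=layout)
    calibration_points = _calibration_points(rng, cfg)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(
        plate=plate,
        truth=truth,
        calibration_points=calibration_points,
        schedule=schedule,
        config=cfg,
        profile=profile,
        n_resampled=n_resampled,
    )


def _calibration_points(
    rng: np.random.Generator,
    cfg: CohortConfig,
    densities=(5_000.0, 10_000.0, 15_000.0, 20_000.0),
    pools_per_density: int = 2,
    pool_size: int = 10,
) -> list[CalibrationPoint]:
    """Pooled digestion standard-curve points from the cohort's area law."""
    points = []
    for seeded in densities:
        for _ in range(pools_per_density):
            cells = _lognormal(rng, seeded * cfg.growth_factor, cfg.cell_count_cv, pool_size)
            areas = (cells - cfg.area_intercept_cells) / cfg.area_per_cell_slope
            if cfg.area_noise_cv > 0:
                areas = areas * (1.0 + rng.normal(0.0, cfg.area_noise_cv / 100.0, pool_size))
            points.append(
                CalibrationPoint.from_pool(
                    predictor_total=float(areas.sum()),
                    viable_cells_total=float(cells.sum()),
                    n_spheroids_pooled=pool_size,
                )
            )
    return points


def write_dataset(cohort: SimulatedCohort, outdir) -> None:
    """Write the CSV/YAML dataset consumed by the analysis pipeline."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_rate_table(cohort.plate, out / "rates.csv")
    cohort.plate.layout.to_frame().to_csv(out / "layout.csv", index=False)
    with open(out / "schedule.yaml", "w") as fh:
        yaml.safe_dump(cohort.schedule.to_dict(), fh, sort_keys=False)
    pd.DataFrame(
        {
            "predictor_value": [p.predictor for p in cohort.calibration_points],
            "viable_cells": [p.viable_cells for p in cohort.calibration_points],
            "n_pooled": [p.n_spheroids_pooled for p in cohort.calibration_points],
            "method": "area",
        }
    ).to_csv(out / "calibration.csv", index=False, float_format="%.6g")
    cohort.truth.to_csv(out / "truth.csv", index=False, float_format="%.8g")
    samples = cohort.truth.loc[~cohort.truth["is_background"], ["well", "area_um2"]]
    samples.to_csv(out / "areas.csv", index=False, float_format="%.8g")
    run_cfg = {
        "rates": "rates.csv",
        "layout": "layout.csv",
        "areas": "areas.csv",
        "calibration": "calibration.csv",
        "schedule": "schedule.yaml",
        "normalization": "per_1000_cells",
        "seed": cohort.config.seed,
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    cfg = asdict(cohort.config)
    cfg["artifact_wells"] = [asdict(a) for a in cohort.config.artifact_wells]
    with open(out / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump({"cohort": cfg, "profile": asdict(cohort.profile)}, fh, sort_keys=False)


def _ellipse_circularity(q: float) -> float:
    """Circularity 4*pi*A/P^2 of an ellipse with axis ratio q = b/a <= 1."""
    # A = pi a b, P = 4 a E(e), e^2 = 1 - q^2  (scipy's ellipe takes m = e^2)
    e2 = 1.0 - q * q
    perim = 4.0 * ellipe(e2)  # for a = 1
    return 4.0 * math.pi * (math.pi * q) / perim**2


def _axis_ratio_for_roundness(target: float) -> float:
    if not (0.0 < target <= 1.0):
        raise ValidationError("roundness_target must be in (0, 1]")
    if target >= _ellipse_circularity(1.0) - 1e-12:
        return 1.0
    lo = 1e-3
    if target < _ellipse_circularity(lo):
        raise ValidationError(f"roundness_target {target} below attainable range")
    return float(brentq(lambda q: _ellipse_circularity(q) - target, lo, 1.0))


def simulate_spheroid_image(
    cells: float,
    roundness_target: float,
    pixel_size_um: float,
    seed: int,
    area_per_cell_slope: float = 0.03,
    area_intercept_cells: float = 0.0,
    n_planes: int = 8,
    snr: float = 10.0,
    blur_sigma_px: float = 2.0,
    centroid_offset_px: tuple[float, float] = (0.0, 0.0),
    max_shape_px: int = 2048,
    shape_px: int | None = None,
) -> tuple[ImageStack, dict]:
    """Render a synthetic spheroid z-stack plus its ground truth.

    The object is an ellipse whose area follows the cohort's area-cell law
    and whose axis ratio matches the roundness target; planes carry an
    intensity falloff away from the focal plane, then Gaussian blur and
    additive noise (foreground amplitude / ``snr``) are applied.
    Returns ``(stack, truth)`` with truth keys area_um2, roundness,
    centroid_um (x, y), a_px, b_px.
    """
    if cells <= 0:
        raise ValidationError("cells must be positive")
    if n_planes < 1:
        raise ValidationError("need >= 1 plane")
    rng = np.random.default_rng(seed)

    area_um2 = (cells - area_intercept_cells) / area_per_cell_slope
    area_px = area_um2 / pixel_size_um**2
    q = _axis_ratio_for_roundness(roundness_target)
    a = math.sqrt(area_px / (math.pi * q))  # semi-major axis, px
    b = q * a

    margin = 4.0 * blur_sigma_px + 8.0
    half = a + margin + max(abs(centroid_offset_px[0]), abs(centroid_offset_px[1]))
    # fixed frame (shape_px) lets pre/post-assay renders share coordinates
    shape = shape_px if shape_px is not None else int(math.ceil(2 * half)) | 1
    if shape > max_shape_px:
        raise ValidationError(
            f"spheroid of {cells:.0f} cells needs a {shape} px frame (> {max_shape_px})"
        )
    c0 = shape // 2
    oy, ox = centroid_offset_px
    if abs(ox) + a >= c0 - 1 or abs(oy) + a >= c0 - 1:
        raise ValidationError("centroid offset pushes the spheroid outside the frame")

    yy, xx = np.mgrid[0:shape, 0:shape]
    ellipse = (
        ((xx - c0 - ox) / a) ** 2 + ((yy - c0 - oy) / b) ** 2
    ) <= 1.0
    base = ellipse.astype(float)

    focal = (n_planes - 1) / 2.0
    falloff = np.exp(-(((np.arange(n_planes) - focal) / (n_planes / 3.0)) ** 2))
    falloff /= falloff.max()  # max projection recovers full amplitude

    planes = np.empty((n_planes, shape, shape))
    noise_sd = 1.0 / snr
    for z in range(n_planes):
        plane = gaussian_filter(base * falloff[z], blur_sigma_px)
        planes[z] = plane + rng.normal(0.0, noise_sd, plane.shape)

    truth = {
        "area_um2": math.pi * a * b * pixel_size_um**2,
        "roundness": min(1.0, _ellipse_circularity(q)),
        "centroid_um": ((c0 + ox) * pixel_size_um, (c0 + oy) * pixel_size_um),
        "a_px": a,
        "b_px": b,
    }
    return ImageStack(planes=planes, pixel_size_um=pixel_size_um), truth
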