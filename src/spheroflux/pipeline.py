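"""Config-driven end-to-end run: rates -> QC -> calibration -> Mito Stress
parameters -> phenotype statistics, with every output written as plain CSV
or text so runs are byte-for-byte reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import (
    DEFAULT_SIZE_CLASS_EDGES,
    assign_size_class,
    estimate_cells_from_area,
    fit_calibration,
    read_calibration_table,
)
from .errors import ConfigurationError, PipelineError, SpherofluxError
from .flux_io import (
    InjectionSchedule,
    apply_background_correction,
    assign_phases,
    read_rate_table,
)
from .mito_stress import BASIS_PER_WELL, extract_params, normalize_params
from .phenotyping import (
    bioenergetic_map,
    cv_summary,
    minmax_scale,
    run_hclust,
    run_pca,
)
from .qc import DEFAULT_JUMP_THETA, apply_exclusions, detect_rate_jumps

FLOAT_FMT = "%.8g"

PHENOTYPE_PARAMS = (
    "non_mito",
    "basal_resp",
    "atp_linked",
    "proton_leak",
    "maximal_resp",
    "spare_capacity",
    "spare_capacity_pct",
)


@dataclass(frozen=True)
class RunConfig:
    """Validated paths and knobs for one analysis run."""

    rates: Path
    layout: Path
    areas: Path | None = None
    calibration: Path | None = None
    schedule: InjectionSchedule = field(default_factory=InjectionSchedule.default_mito_stress)
    background_correction: bool = False
    jump_theta: float = DEFAULT_JUMP_THETA
    qc_report_only: bool = False
    normalization: str = "per_1000_cells"  # per_well | per_1000_cells | per_1000_um2
    size_class_edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES
    run_pca_analysis: bool = True
    run_clustering: bool = True
    n_clusters: int = 2
    run_maps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rates", "layout", "areas", "calibration"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.normalization not in ("per_well", "per_1000_cells", "per_1000_um2"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.normalization != "per_well" and self.areas is None:
            raise ConfigurationError(
                f"normalization {self.normalization!r} needs an areas file"
            )
        if self.normalization == "per_1000_cells" and self.calibration is None:
            raise ConfigurationError("per-cell normalization needs a calibration file")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def _p(key):
            v = raw.get(key)
            return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

        sched = raw.get("schedule")
        if isinstance(sched, str):
            schedule = InjectionSchedule.from_yaml(base / sched)
        elif isinstance(sched, dict):
            schedule = InjectionSchedule.from_dict(sched)
        else:
            schedule = InjectionSchedule.default_mito_stress()

        kwargs = dict(
            rates=_p("rates"),
            layout=_p("layout"),
            areas=_p("areas"),
            calibration=_p("calibration"),
            schedule=schedule,
            background_correction=bool(raw.get("background_correction", False)),
            jump_theta=float(raw.get("jump_theta", DEFAULT_JUMP_THETA)),
            qc_report_only=bool(raw.get("qc_report_only", False)),
            normalization=str(raw.get("normalization", "per_1000_cells")),
            size_class_edges=tuple(raw.get("size_class_edges", DEFAULT_SIZE_CLASS_EDGES)),
            run_pca_analysis=bool(raw.get("pca", True)),
            run_clustering=bool(raw.get("clustering", True)),
            n_clusters=int(raw.get("n_clusters", 2)),
            run_maps=bool(raw.get("maps", True)),
            seed=int(raw.get("seed", 0)),
        )
        kwargs.update(overrides)
        if kwargs["rates"] is None or kwargs["layout"] is None:
            raise ConfigurationError("config must set 'rates' and 'layout' paths")
        return cls(**kwargs)


def run_pipeline(cfg: RunConfig, outdir) -> dict[str, pd.DataFrame]:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns the main tables keyed by output name. On a stage failure the
    partial outputs written so far are kept and an INCOMPLETE marker file
    names the failing stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        return _run_stages(cfg, out)
    except SpherofluxError as exc:
        stage = getattr(exc, "stage", stage)
        (out / "INCOMPLETE").write_text(f"pipeline aborted: {exc}\n")
        raise


def _run_stages(cfg: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}

    # -- flux_io ------------------------------------------------------------
    pk = read_rate_table(cfg.rates, cfg.layout)
    n_wells_in = len(pk.wells)
    if cfg.background_correction:
        pk = apply_background_correction(pk)
    pk = assign_phases(pk, cfg.schedule)

    # -- qc -----------------------------------------------------------------
    reports = {
        wid: detect_rate_jumps(wk, cfg.schedule, theta=cfg.jump_theta)
        for wid, wk in pk.wells.items()
    }
    pk, qc_table = apply_exclusions(pk, reports, report_only=cfg.qc_report_only)
    tables["qc"] = qc_table
    _write(qc_table, out / "qc.csv")

    # -- calibration --------------------------------------------------------
    curve = None
    areas: dict[str, float] = {}
    if cfg.areas is not None:
        adf = pd.read_csv(cfg.areas)
        areas = dict(zip(adf["well"].astype(str), adf["area_um2"].astype(float)))
    if cfg.calibration is not None:
        curve = fit_calibration(read_calibration_table(cfg.calibration), method="area")

    # -- mito_stress --------------------------------------------------------
    rows = []
    for wid in pk.sample_wells:
        p = extract_params(pk.wells[wid], cfg.schedule)
        area = areas.get(wid)
        cells = extrapolated = None
        if curve is not None and area is not None:
            cells, extrapolated = estimate_cells_from_area(curve, area)
        if cfg.normalization == "per_1000_cells":
            if cells is None:
                raise PipelineError(f"mito_stress: well {wid} has no area for per-cell normalization")
            p = normalize_params(p, cells=cells)
        elif cfg.normalization == "per_1000_um2":
            if area is None:
                raise PipelineError(f"mito_stress: well {wid} has no area for per-area normalization")
            p = normalize_params(p, area_um2=area)
        row = {
            "well": wid,
            "group": pk.layout.groups[wid],
            "basis": p.basis,
            "area_um2": area,
            "cells_est": cells,
            "extrapolated_flag": extrapolated,
            "size_class": assign_size_class(cells, edges=cfg.size_class_edges)
            if cells is not None else None,
            "non_mito": p.non_mito,
            "basal_resp": p.basal_resp,
            "atp_linked": p.atp_linked,
            "proton_leak": p.proton_leak,
            "maximal_resp": p.maximal_resp,
            "spare_capacity": p.spare_capacity,
            "spare_capacity_pct": p.spare_capacity_pct,
            "last_basal_ocr": p.last_basal_ocr,
            "last_basal_ecar": p.last_basal_ecar,
            "stressed_ocr": p.stressed_ocr,
            "stressed_ecar": p.stressed_ecar,
            "quality_flag": p.quality_flag,
        }
        rows.append(row)
    params = pd.DataFrame(rows).set_index("well")
    tables["params"] = params
    _write(params.reset_index(), out / "params.csv")

    if curve is not None:
        curve_df = pd.DataFrame(
            [{
                "method": curve.method, "slope": curve.slope,
                "intercept": curve.intercept, "r_squared": curve.r_squared,
                "n_points": curve.n_points,
            }]
        )
        _write(curve_df, out / "calibration_fit.csv")

    # -- phenotyping --------------------------------------------------------
    summary = cv_summary(params, value_cols=list(PHENOTYPE_PARAMS), group_cols=("group",))
    tables["cv_summary"] = summary
    _write(summary, out / "cv_summary.csv")

    usable = params.dropna(subset=["basal_resp"])
    matrix = usable[list(PHENOTYPE_PARAMS)].dropna(axis=1, how="any")
    if len(usable) >= 2 and (cfg.run_pca_analysis or cfg.run_clustering):
        pm = minmax_scale(matrix)
        _write(pm.data.reset_index(), out / "scaled_matrix.csv")
        if cfg.run_pca_analysis:
            pca = run_pca(pm)
            _write(pca.scores.reset_index(), out / "pca_scores.csv")
            _write(pca.loadings.reset_index(names="parameter"), out / "pca_loadings.csv")
            pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(len(pca.explained_proportion))],
                    "explained_proportion": pca.explained_proportion,
                }
            ).pipe(_write, out / "pca_explained.csv")
        if cfg.run_clustering and len(usable) >= cfg.n_clusters:
            cl = run_hclust(pm, k=cfg.n_clusters)
            (out / "dendrogram.newick").write_text(cl.to_newick() + "\n")
            _write(
                pd.DataFrame({"well": list(pm.data.index), "cluster": cl.labels}),
                out / "clusters.csv",
            )
    if cfg.run_maps:
        map_df = bioenergetic_map(params, group_cols=("group", "size_class"))
        tables["bioenergetic_map"] = map_df
        _write(map_df, out / "bioenergetic_map.csv")

    n_excluded = int(qc_table["excluded"].sum())
    lines = [
        f"spheroflux {__version__}",
        f"seed: {cfg.seed}",
        f"normalization: {cfg.normalization}",
        f"wells read: {n_wells_in}",
        f"wells excluded by QC: {n_excluded}",
        f"sample wells analyzed: {len(params)}",
        "",
        "per-group CV of Mito Stress parameters (%):",
        summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
    ]
    (out / "summary.txt").write_text("\n".join(lines))
    return tables


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
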