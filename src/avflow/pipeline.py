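"""Reproducible pipeline tying the synthesis, geometry, metric and
statistics stages together.

``run_pipeline`` executes the toggled stages in order — synthesise an AVF
lumen and wall-shear field, recover the anatomical summary from the mesh,
compute the haemodynamic metric maps and their 1 cm segment means, and run
the cohort statistics — writing CSV/PLY/zip artefacts plus a JSON run
manifest with per-file checksums.  The run is deterministic: the same
configuration and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fields import save_field_series, save_mesh
from .geometry import (
    ANASTOMOSIS,
    DISTAL_ARTERY,
    DRAINING_VEIN,
    FEEDING_ARTERY,
    centrelines_to_frame,
    extract_limb_centrelines,
    partition_segments,
    summarise_anatomy,
)
from .metrics import (
    SurfaceFieldSeries,
    compute_metric_maps,
    lumped_pressure_network,
    segment_aggregate,
)
from .stats import (
    ANATOMICAL_VARIABLES,
    combined_auc,
    compare_groups,
    dichotomize_flow,
    group_summary,
    load_table2_fixture,
    roc_table,
)
from .synthetic import (
    AVFDesignParams,
    SyntheticAVF,
    build_end_to_side_avf,
    womersley_surface_series,
)
from .womersley import BLOOD_DENSITY, BLOOD_VISCOSITY, FlowWaveform


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (units: mm, Pa, ml/min, s)."""

    outdir: str = "avf_run"
    seed: int = 0
    run_synth: bool = True
    run_geometry: bool = True
    run_metrics: bool = True
    run_stats: bool = True
    geometry_params: dict = field(default_factory=dict)  # AVFDesignParams overrides
    mean_flow_ml_min: float = 600.0
    period_s: float = 1.0
    pulsatility: float = 0.5
    viscosity_pa_s: float = BLOOD_VISCOSITY
    density_kg_m3: float = BLOOD_DENSITY
    segment_length_mm: float = 10.0
    smoothing_window_mm: float = 10.0
    fit_window_mm: float = 5.0
    cohort_csv: str | None = None  # default: packaged fixture
    roc_variables: tuple[str, ...] = ("fa_curvature", "fa_diameter_mm", "dv_diameter_mm")
    mesh_path: str | None = None  # use an existing mesh instead of synthesis

    def validate(self) -> None:
        if self.mesh_path is not None and not Path(self.mesh_path).exists():
            raise FileNotFoundError(f"configured mesh does not exist: {self.mesh_path}")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(f"configured cohort does not exist: {self.cohort_csv}")
        if self.segment_length_mm <= 0 or self.period_s <= 0:
            raise ValueError("segment length and period must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.roc_variables, list):
            cfg.roc_variables = tuple(cfg.roc_variables)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roc_variables"] = list(self.roc_variables)
        return d


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, seed, file checksums."""

    config: dict
    package_version: str
    seed: int
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256
    stages_completed: list = field(default_factory=list)
    error: str | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def avf_field_series(
    avf: SyntheticAVF,
    waveform: FlowWaveform,
    viscosity: float = BLOOD_VISCOSITY,
    density: float = BLOOD_DENSITY,
) -> SurfaceFieldSeries:
    """Analytic pulsatile wall-shear field over a synthetic AVF surface.

    The inflow waveform is split between the draining vein and the distal
    artery with the lumped Poiseuille network; each limb then carries the
    rigid-tube pulsatile (Womersley) wall shear for its own radius and
    flow, directed along the local centreline tangent.  Anastomosis-patch
    faces take the feeding-artery solution.  This is a smooth idealised
    stand-in for a full 3-D flow solve: it has no secondary or separated
    flow, so oscillatory and transverse metrics reflect only the waveform.
    """
    p = avf.params
    net = lumped_pressure_network(
        {FEEDING_ARTERY: p.artery_length, DRAINING_VEIN: p.vein_length,
         DISTAL_ARTERY: p.distal_length},
        {FEEDING_ARTERY: p.feeding_artery_diameter / 2,
         DRAINING_VEIN: p.draining_vein_diameter / 2,
         DISTAL_ARTERY: p.distal_artery_diameter / 2},
        waveform.mean_flow, viscosity,
    )
    frac_vein = net.flows["draining_vein"] / net.flows["inflow"]
    limb_flow = {
        FEEDING_ARTERY: 1.0,
        DRAINING_VEIN: frac_vein,
        DISTAL_ARTERY: 1.0 - frac_vein,
    }
    radii = {
        FEEDING_ARTERY: p.feeding_artery_diameter / 2,
        DRAINING_VEIN: p.draining_vein_diameter / 2,
        DISTAL_ARTERY: p.distal_artery_diameter / 2,
    }
    mesh = avf.mesh
    traction = np.zeros((len(waveform.sample_times), len(mesh.faces), 3))
    labels = np.where(avf.face_labels == ANASTOMOSIS, FEEDING_ARTERY, avf.face_labels)
    for limb, cl in avf.centrelines.items():
        sel = np.flatnonzero(labels == limb)
        if len(sel) == 0:
            continue
        wf = FlowWaveform(
            period=waveform.period,
            mean_flow=waveform.mean_flow * limb_flow[limb],
            harmonics=[(n, a * limb_flow[limb]) for n, a in waveform.harmonics],
            sample_times=waveform.sample_times,
        )
        sub = mesh.submesh([sel], append=True)
        sub_series = womersley_surface_series(
            sub, cl, wf, viscosity, density, radius=radii[limb]
        )
        traction[:, sel, :] = sub_series.traction
    return SurfaceFieldSeries(
        mesh=mesh, times=waveform.sample_times, traction=traction,
        period=waveform.period,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages and write the run manifest.

    Stage failures record partial completion in the manifest and re-raise.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        seed=config.seed,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest_path = outdir / "manifest.json"

    def record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(outdir))] = _sha256(path)

    avf = None
    series = None
    try:
        if config.run_synth:
            params = AVFDesignParams(**config.geometry_params)
            avf = build_end_to_side_avf(params)
            waveform = FlowWaveform.physiologic(
                mean_flow=config.mean_flow_ml_min, period=config.period_s,
                pulsatility=config.pulsatility,
            )
            mesh_path = outdir / "lumen.ply"
            save_mesh(avf.mesh, mesh_path, avf.face_labels)
            record(mesh_path)
            record(outdir / "lumen.ply.labels.csv")
            series = avf_field_series(avf, waveform, config.viscosity_pa_s,
                                      config.density_kg_m3)
            fpath = outdir / "fields.zip"
            save_field_series(series, fpath)
            record(fpath)
            manifest.stages_completed.append("synth")

        segtable = None
        if config.run_geometry:
            if avf is None:
                raise ValueError("geometry stage needs the synth stage (or a labelled mesh)")
            seeds = {
                label: cl.point_at(cl.length - 2.0)
                for label, cl in avf.centrelines.items()
            }
            recovered = extract_limb_centrelines(
                avf.mesh, avf.anastomosis_faces, seeds, avf.junction,
            )
            summary = summarise_anatomy(
                avf.mesh, recovered, avf.anastomosis_faces,
                smoothing_window=config.smoothing_window_mm,
                fit_window=config.fit_window_mm,
            )
            anat_path = outdir / "anatomy.csv"
            pd.DataFrame([summary.as_dict()]).to_csv(anat_path, index=False)
            record(anat_path)
            cl_path = outdir / "centrelines.csv"
            centrelines_to_frame(recovered).to_csv(cl_path, index=False)
            record(cl_path)
            segtable = partition_segments(
                avf.mesh, recovered, avf.anastomosis_faces, config.segment_length_mm
            )
            seg_path = outdir / "segments.csv"
            segtable.segments.to_csv(seg_path, index=False)
            record(seg_path)
            manifest.stages_completed.append("geometry")

        if config.run_metrics:
            if series is None:
                raise ValueError("metrics stage needs a field series from the synth stage")
            maps = compute_metric_maps(series)
            maps_path = outdir / "metric_maps.csv"
            maps.as_frame().to_csv(maps_path, index=False)
            record(maps_path)
            if segtable is not None:
                seg_means = segment_aggregate(maps, segtable, series.mesh)
                sm_path = outdir / "segment_means.csv"
                seg_means.to_csv(sm_path, index=False)
                record(sm_path)
            manifest.stages_completed.append("metrics")

        if config.run_stats:
            cohort = (
                pd.read_csv(config.cohort_csv)
                if config.cohort_csv
                else load_table2_fixture()
            )
            cohort = dichotomize_flow(cohort)
            cohort["dv_minus_fa_diameter_mm"] = (
                cohort["dv_diameter_mm"] - cohort["fa_diameter_mm"]
            )
            summary_vars = ANATOMICAL_VARIABLES + (
                "dv_minus_fa_diameter_mm", "venous_outflow_ml_min",
            )
            for name, grouping in (("outcome", "outcome"), ("rcf", "rcf"),
                                   ("outflow", "outflow_category")):
                gs = group_summary(cohort, grouping, variables=summary_vars)
                path = outdir / f"group_summary_{name}.csv"
                gs.to_csv(path, index=False)
                record(path)
            roc = roc_table(cohort)
            comb = combined_auc(cohort, config.roc_variables, seed=config.seed)
            roc = pd.concat([
                roc,
                pd.DataFrame([dict(variable="+".join(config.roc_variables),
                                   orientation=comb.orientation, auc=comb.auc,
                                   n_pos=comb.n_pos, n_neg=comb.n_neg,
                                   ties=comb.ties)]),
            ], ignore_index=True)
            roc_path = outdir / "roc_auc.csv"
            roc.to_csv(roc_path, index=False)
            record(roc_path)
            pvals = compare_groups(cohort, "outflow_category")
            p_path = outdir / "group_pvalues.csv"
            pvals.to_csv(p_path, index=False)
            record(p_path)
            manifest.stages_completed.append("stats")
    except Exception as exc:
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        manifest.save(manifest_path)
        raise
    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest.save(manifest_path)
    return manifest
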