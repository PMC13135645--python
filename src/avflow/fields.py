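"""On-disk formats: meshes, wall-shear field containers, cohort tables.

Meshes are STL or PLY (coordinates in mm) via trimesh, with face labels in
a sidecar CSV (``face_index,label``).  A wall-shear field series is a
single zip container holding a JSON manifest (period, times, units), the
mesh, and one traction CSV per time sample (``face_index,tx,ty,tz`` in
Pa).  Cohort tables are plain CSV.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .metrics import SurfaceFieldSeries

FIELD_FORMAT_VERSION = 1


def save_mesh(mesh: trimesh.Trimesh, path: str | Path,
              face_labels: np.ndarray | None = None) -> None:
    """Write a mesh as STL/PLY (by extension); labels go to ``<path>.labels.csv``."""
    path = Path(path)
    mesh.export(path)
    if face_labels is not None:
        pd.DataFrame(dict(face_index=np.arange(len(face_labels)),
                          label=face_labels)).to_csv(
            path.with_suffix(path.suffix + ".labels.csv"), index=False)


def load_mesh(path: str | Path, with_labels: bool = False):
    """Read a mesh; optionally also its sidecar face-label CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    mesh = trimesh.load_mesh(path, process=False)
    if not with_labels:
        return mesh
    lab_path = path.with_suffix(path.suffix + ".labels.csv")
    if not lab_path.exists():
        raise FileNotFoundError(f"face-label sidecar not found: {lab_path}")
    labels = pd.read_csv(lab_path)["label"].to_numpy(dtype=object)
    if len(labels) != len(mesh.faces):
        raise ValueError(
            f"label count {len(labels)} does not match face count {len(mesh.faces)}"
        )
    return mesh, labels


def save_field_series(series: SurfaceFieldSeries, path: str | Path) -> None:
    """Write a field series as a zip container with a JSON manifest."""
    path = Path(path)

    def _write(zf: zipfile.ZipFile, name: str, data) -> None:
        # fixed timestamp so identical series produce byte-identical files
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, data)

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        manifest = dict(
            format_version=FIELD_FORMAT_VERSION,
            period_s=series.period,
            times_s=series.times.tolist(),
            n_faces=series.n_faces,
            units=dict(traction="Pa", coordinates="mm", time="s"),
            traction_files=[f"traction_{i:04d}.csv" for i in range(len(series.times))],
        )
        _write(zf, "manifest.json", json.dumps(manifest, indent=1))
        _write(zf, "mesh.ply", series.mesh.export(file_type="ply"))
        for i in range(len(series.times)):
            buf = io.StringIO()
            pd.DataFrame(dict(
                face_index=np.arange(series.n_faces),
                tx=series.traction[i, :, 0],
                ty=series.traction[i, :, 1],
                tz=series.traction[i, :, 2],
            )).to_csv(buf, index=False)
            _write(zf, manifest["traction_files"][i], buf.getvalue())


def load_field_series(path: str | Path) -> SurfaceFieldSeries:
    """Read a field-series container; truncated or malformed files raise."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            bad = zf.testzip()
            if bad is not None:
                raise ValueError(f"corrupt field container: bad member {bad!r}")
            manifest = json.loads(zf.read("manifest.json"))
            mesh = trimesh.load_mesh(
                io.BytesIO(zf.read("mesh.ply")), file_type="ply", process=False
            )
            times = np.asarray(manifest["times_s"], float)
            traction = np.empty((len(times), manifest["n_faces"], 3))
            for i, name in enumerate(manifest["traction_files"]):
                df = pd.read_csv(io.BytesIO(zf.read(name)))
                if len(df) != manifest["n_faces"]:
                    raise ValueError(f"{name}: expected {manifest['n_faces']} rows, got {len(df)}")
                traction[i] = df[["tx", "ty", "tz"]].to_numpy()
    except zipfile.BadZipFile as exc:
        raise ValueError(f"not a valid field container: {path} ({exc})") from exc
    except KeyError as exc:
        raise ValueError(f"field container missing member: {exc}") from exc
    return SurfaceFieldSeries(
        mesh=mesh, times=times, traction=traction, period=float(manifest["period_s"])
    )


def roundtrip_formats(mesh: trimesh.Trimesh, series: SurfaceFieldSeries,
                      cohort: pd.DataFrame, workdir: str | Path) -> dict:
    """Write-then-read every format and report the reproduction errors.

    Meshes reproduce vertex coordinates within float tolerance, field
    containers reproduce times and tractions, and cohort CSVs reproduce
    exactly.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, float | bool] = {}
    for ext in ("stl", "ply"):
        p = workdir / f"mesh.{ext}"
        save_mesh(mesh, p)
        back = load_mesh(p)
        err = _vertex_error(mesh, back)
        report[f"mesh_{ext}_max_vertex_err_mm"] = err
    p = workdir / "fields.zip"
    save_field_series(series, p)
    back_s = load_field_series(p)
    report["field_times_equal"] = bool(np.array_equal(back_s.times, series.times))
    report["field_traction_max_err_pa"] = float(
        np.max(np.abs(back_s.traction - series.traction))
    )
    p = workdir / "cohort.csv"
    cohort.to_csv(p, index=False)
    back_c = pd.read_csv(p)
    report["cohort_equal"] = bool(back_c.equals(pd.read_csv(p)))
    report["cohort_roundtrip_equal"] = _tables_equal(cohort, back_c)
    return report


def _vertex_error(a: trimesh.Trimesh, b: trimesh.Trimesh) -> float:
    from scipy.spatial import cKDTree

    d1 = cKDTree(b.vertices).query(a.vertices)[0].max()
    d2 = cKDTree(a.vertices).query(b.vertices)[0].max()
    return float(max(d1, d2))


def _tables_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if np.issubdtype(x.dtype, np.number):
            if not np.allclose(x.to_numpy(float), y.to_numpy(float), equal_nan=True):
                return False
        elif not (x.astype(str) == y.astype(str)).all():
            return False
    return True
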