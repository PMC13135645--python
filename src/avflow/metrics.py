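"""Wall-shear-derived haemodynamic metrics and the lumped pressure model.

Per-face metrics computed from a time-resolved wall-shear vector field
tau_w(t) over one cardiac period T:

* TAWSS  = (1/T) int_0^T ||tau_w|| dt                      [Pa]
* OSI    = 0.5 * (1 - ||int tau_w dt|| / int ||tau_w|| dt) in [0, 0.5]
* transWSS = (1/T) int |tau_w . (n x p)| dt, with p the unit mean-shear
  direction                                                [Pa]
* WSSG   = magnitude of the intrinsic surface gradient of the TAWSS field
                                                           [Pa/mm]
* LNH    = v . omega / (||v|| ||omega||) in [-1, 1] on volumetric
  velocity/vorticity snapshots (helical-flow indicator).

Time integrals use trapezoidal quadrature with periodic closure (the last
sample wraps to the first).  Faces where a metric is undefined (e.g. no
mean shear direction for transWSS) are reported missing (NaN), never zero.

The lumped pressure network evaluates the Ohm/Hagen-Poiseuille ordering of
node pressures (feeding artery > distal artery ~ anastomosis > vein) with
Poiseuille resistances 8*mu*L/(pi*R^4) and flags distal-artery flow
reversal (steal) when the anastomotic pressure falls below the distal
arterial pressure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .womersley import ML_MIN_TO_M3_S, MM_TO_M, BLOOD_VISCOSITY, FlowWaveform

logger = logging.getLogger(__name__)


@dataclass
class SurfaceFieldSeries:
    """Per-face wall-shear vectors sampled over one cardiac period.

    ``times`` (s) strictly increase, start at 0 and end before ``period``;
    ``traction`` has shape (n_times, n_faces, 3) in Pa and is tangent to
    the surface (checked against the face normals on construction).
    """

    mesh: trimesh.Trimesh
    times: np.ndarray
    traction: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.traction = np.asarray(self.traction, dtype=float)
        nt, nf, three = self.traction.shape
        if three != 3 or nt != len(self.times):
            raise ValueError("traction must have shape (n_times, n_faces, 3)")
        if nf != len(self.mesh.faces):
            raise ValueError("traction face count does not match the mesh")
        t = self.times
        if t[0] != 0.0 or t[-1] >= self.period or np.any(np.diff(t) <= 0):
            raise ValueError("times must strictly increase from 0 and end before the period")
        n = self.mesh.face_normals
        mag = np.linalg.norm(self.traction, axis=2)
        dot = np.abs(np.einsum("tfk,fk->tf", self.traction, n))
        bad = (mag > 0) & (dot / np.where(mag > 0, mag, 1.0) >= 1e-3)
        if bad.any():
            raise ValueError(
                f"traction not tangent to the surface on {bad.sum()} samples"
            )

    @property
    def n_faces(self) -> int:
        return self.traction.shape[1]

    def _closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and tractions with the periodic closure sample appended."""
        gaps = np.diff(np.r_[self.times, self.period + self.times[0]])
        if np.max(gaps) > self.period / 4:
            raise ValueError(
                f"non-uniform time coverage: largest gap {np.max(gaps):.3g} s "
                f"exceeds T/4 = {self.period / 4:.3g} s"
            )
        t = np.r_[self.times, self.period]
        tr = np.concatenate([self.traction, self.traction[:1]], axis=0)
        return t, tr

    def scaled(self, c: float) -> "SurfaceFieldSeries":
        return SurfaceFieldSeries(self.mesh, self.times, c * self.traction, self.period)


@dataclass
class VolumeSnapshot:
    """Velocity/vorticity point samples at one instant (e.g. peak systole)."""

    points: np.ndarray  # (n, 3) mm
    velocity: np.ndarray  # (n, 3) m/s
    vorticity: np.ndarray  # (n, 3) 1/s
    time_label: str = "peak_systole"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.velocity = np.asarray(self.velocity, float)
        self.vorticity = np.asarray(self.vorticity, float)
        if not (len(self.points) == len(self.velocity) == len(self.vorticity)):
            raise ValueError("points, velocity and vorticity lengths differ")
        for arr in (self.velocity, self.vorticity):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite values in snapshot fields")


@dataclass
class MetricMaps:
    """Per-face metric values plus optional per-point LNH."""

    tawss: np.ndarray
    osi: np.ndarray
    transwss: np.ndarray
    wssg: np.ndarray
    lnh: np.ndarray | None = None
    segment_means: "pandas.DataFrame | None" = None  # noqa: F821

    def as_frame(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(dict(
            face_index=np.arange(len(self.tawss)), tawss=self.tawss,
            osi=self.osi, transwss=self.transwss, wssg=self.wssg,
        ))


# ---------------------------------------------------------------------------
# time-averaged metrics


def tawss(series: SurfaceFieldSeries) -> np.ndarray:
    """Time-averaged wall shear stress magnitude per face (Pa)."""
    if len(series.times) < 3:
        raise ValueError("need at least 3 time samples")
    t, tr = series._closed_cycle()
    mag = np.linalg.norm(tr, axis=2)
    return np.trapezoid(mag, t, axis=0) / series.period


def _mean_vector(series: SurfaceFieldSeries) -> np.ndarray:
    t, tr = series._closed_cycle()
    return np.trapezoid(tr, t[:, None, None], axis=0) / series.period


def osi(series: SurfaceFieldSeries) -> np.ndarray:
    """Oscillatory shear index per face, in [0, 0.5].

    0 for unidirectional shear, 0.5 when the cycle-mean shear vector
    vanishes.  Faces with zero shear throughout are missing (NaN).
    """
    ta = tawss(series)
    mean_mag = np.linalg.norm(_mean_vector(series), axis=1)
    out = np.full(series.n_faces, np.nan)
    ok = ta > 0
    out[ok] = 0.5 * (1.0 - np.clip(mean_mag[ok] / ta[ok], 0.0, 1.0))
    return out


def transwss(series: SurfaceFieldSeries) -> np.ndarray:
    """Transverse wall shear stress per face (Pa).

    Time average of the shear component perpendicular (within the tangent
    plane) to the cycle-mean shear direction p.  Faces without a mean
    direction (pure oscillation) are missing, with the count logged.
    """
    mean_vec = _mean_vector(series)
    mean_mag = np.linalg.norm(mean_vec, axis=1)
    ta = tawss(series)
    undefined = mean_mag <= 1e-12 * np.maximum(ta, 1e-300)
    n_undef = int(undefined.sum())
    if n_undef:
        logger.info("transWSS undefined (no mean shear direction) on %d faces", n_undef)
    p = np.where(undefined[:, None], np.nan, mean_vec / np.where(mean_mag[:, None] == 0, 1.0, mean_mag[:, None]))
    nxp = np.cross(series.mesh.face_normals, p)
    t, tr = series._closed_cycle()
    comp = np.abs(np.einsum("tfk,fk->tf", tr, nxp))
    out = np.trapezoid(comp, t, axis=0) / series.period
    out[undefined] = np.nan
    return out


def wssg(tawss_map: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Surface-gradient magnitude of the TAWSS field per face (Pa/mm).

    For each face, the TAWSS differences to its edge-connected neighbours
    are fitted by least squares to a linear function of the in-tangent-
    plane centroid offsets; the fitted gradient magnitude is reported.
    Faces with fewer than two neighbours are missing.
    """
    tawss_map = np.asarray(tawss_map, float)
    nf = len(mesh.faces)
    if len(tawss_map) != nf:
        raise ValueError("tawss map length does not match the mesh")
    centers = mesh.triangles_center
    normals = mesh.face_normals
    adj = mesh.face_adjacency
    counts = np.zeros(nf, dtype=int)
    nb = np.full((nf, 3), -1, dtype=int)
    for a, b in adj:
        if counts[a] < 3:
            nb[a, counts[a]] = b
        counts[a] += 1
        if counts[b] < 3:
            nb[b, counts[b]] = a
        counts[b] += 1
    out = np.full(nf, np.nan)
    full = counts == 3
    if full.any():
        idx = np.flatnonzero(full)
        d = centers[nb[idx]] - centers[idx, None, :]  # (m, 3, 3)
        n = normals[idx]
        d = d - np.einsum("mkj,mj->mk", d, n)[:, :, None] * n[:, None, :]
        # orthonormal tangent basis per face
        u = d[:, 0, :].copy()
        u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-300)
        v = np.cross(n, u)
        A = np.stack([np.einsum("mkj,mj->mk", d, u),
                      np.einsum("mkj,mj->mk", d, v)], axis=2)  # (m, 3, 2)
        rhs = tawss_map[nb[idx]] - tawss_map[idx, None]
        finite = np.isfinite(rhs).all(axis=1)
        M = np.einsum("mki,mkj->mij", A, A)  # (m, 2, 2)
        r = np.einsum("mki,mk->mi", A, np.nan_to_num(rhs))
        det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        ok = finite & (np.abs(det) > 1e-300)
        gx = (M[:, 1, 1] * r[:, 0] - M[:, 0, 1] * r[:, 1]) / np.where(ok, det, 1.0)
        gy = (M[:, 0, 0] * r[:, 1] - M[:, 1, 0] * r[:, 0]) / np.where(ok, det, 1.0)
        vals = np.hypot(gx, gy)
        out[idx[ok]] = vals[ok]
    # faces with fewer (boundary) or degenerate neighbourhoods: small loop
    for i in np.flatnonzero(~full & (counts >= 2)):
        nbs = nb[i, : min(counts[i], 3)]
        nbs = nbs[nbs >= 0]
        d = centers[nbs] - centers[i]
        n = normals[i]
        d = d - np.outer(d @ n, n)
        rhs = tawss_map[nbs] - tawss_map[i]
        fin = np.isfinite(rhs)
        if fin.sum() < 2:
            continue
        g, *_ = np.linalg.lstsq(d[fin], rhs[fin], rcond=None)
        out[i] = np.linalg.norm(g)
    return out


def lnh(snapshot: VolumeSnapshot) -> np.ndarray:
    """Localised normalised helicity per point, in [-1, 1].

    Cosine of the angle between velocity and vorticity; points where either
    vanishes are missing.
    """
    v, w = snapshot.velocity, snapshot.vorticity
    nv = np.linalg.norm(v, axis=1)
    nw = np.linalg.norm(w, axis=1)
    out = np.full(len(v), np.nan)
    ok = (nv > 0) & (nw > 0)
    out[ok] = np.clip(np.einsum("ij,ij->i", v[ok], w[ok]) / (nv[ok] * nw[ok]), -1.0, 1.0)
    return out


def peak_systole_index(waveform: FlowWaveform) -> int:
    """Index of the maximum reconstructed flow; ties go to the earliest sample."""
    q = waveform.reconstruct()
    return int(np.argmax(q))


# ---------------------------------------------------------------------------
# aggregation


def segment_aggregate(
    metric_maps: MetricMaps | dict[str, np.ndarray],
    segment_table,
    mesh: trimesh.Trimesh,
) -> "pandas.DataFrame":  # noqa: F821
    """Area-weighted mean of each per-face metric within each 1 cm segment.

    Missing faces are excluded from the weighted mean; a segment whose
    faces are all missing yields a missing value with a warning.  Output is
    tidy: limb, seg_index, is_anastomosis, metric, value.
    """
    import pandas as pd

    if isinstance(metric_maps, MetricMaps):
        maps = dict(tawss=metric_maps.tawss, osi=metric_maps.osi,
                    transwss=metric_maps.transwss, wssg=metric_maps.wssg)
    else:
        maps = dict(metric_maps)
    areas = mesh.area_faces
    for name, vals in maps.items():
        if len(vals) != len(areas):
            raise ValueError(f"metric '{name}' length does not match the mesh")
    rows = []
    for row_id, seg in segment_table.segments.iterrows():
        faces = segment_table.faces_of(row_id)
        for name, vals in maps.items():
            if len(faces) == 0:
                rows.append(dict(limb=seg.limb, seg_index=seg.seg_index,
                                 is_anastomosis=bool(seg.is_anastomosis),
                                 metric=name, value=np.nan))
                continue
            v = vals[faces]
            a = areas[faces]
            ok = np.isfinite(v)
            if not ok.any():
                warnings.warn(
                    f"segment {seg.limb}[{seg.seg_index}] has all-missing '{name}'",
                    RuntimeWarning,
                )
                mean = np.nan
            else:
                mean = float(np.average(v[ok], weights=a[ok]))
            rows.append(dict(limb=seg.limb, seg_index=seg.seg_index,
                             is_anastomosis=bool(seg.is_anastomosis),
                             metric=name, value=mean))
    return pd.DataFrame(rows)


def compute_metric_maps(
    series: SurfaceFieldSeries,
    segment_table=None,
    snapshot: VolumeSnapshot | None = None,
) -> MetricMaps:
    """Convenience wrapper computing the full per-face metric suite."""
    ta = tawss(series)
    maps = MetricMaps(
        tawss=ta,
        osi=osi(series),
        transwss=transwss(series),
        wssg=wssg(ta, series.mesh),
        lnh=None if snapshot is None else lnh(snapshot),
    )
    if segment_table is not None:
        maps.segment_means = segment_aggregate(maps, segment_table, series.mesh)
    return maps


# ---------------------------------------------------------------------------
# lumped pressure network


def poiseuille_resistance(length_mm: float, radius_mm: float,
                          viscosity: float = BLOOD_VISCOSITY) -> float:
    """Hydraulic resistance 8*mu*L/(pi*R^4) in Pa s / m^3."""
    L = length_mm * MM_TO_M
    R = radius_mm * MM_TO_M
    return 8.0 * viscosity * L / (np.pi * R**4)


@dataclass
class PressureNetworkResult:
    """Node pressures (Pa, venous outlet as reference 0) and flows (m^3/s)."""

    pressures: dict[str, float]
    flows: dict[str, float]
    distal_reversal: bool


def lumped_pressure_network(
    limb_lengths_mm: dict[str, float],
    limb_radii_mm: dict[str, float],
    inflow_ml_min: float,
    viscosity: float = BLOOD_VISCOSITY,
    anastomosis_resistance_scale: float = 1.0,
    distal_pressure: float = 0.0,
) -> PressureNetworkResult:
    """Solve the three-node Poiseuille network of an end-to-side AVF.

    Topology: inlet --R_fa--> anastomosis node --R_an--> vein inlet
    --R_v--> 0 (venous outlet, the pressure reference), with the distal
    artery branching at the anastomosis node through R_da towards the
    distal arterial bed.  ``distal_pressure`` (Pa) is the pressure the
    collateral circulation maintains in that bed (default 0, an
    unperfused dead end).

    R_an models the suture-line constriction: the Poiseuille resistance of
    a stenosed segment one vein diameter long with half the vein radius,
    multiplied by ``anastomosis_resistance_scale`` — a very large
    anastomotic area corresponds to a small scale.  Shrinking the scale
    lowers the venous outflow-path resistance and with it the anastomotic
    pressure; once that pressure falls below the collateral-maintained
    distal pressure the distal artery back-feeds the fistula, and the
    flow-reversal (steal) flag is raised.
    """
    for d, what in ((limb_lengths_mm, "length"), (limb_radii_mm, "radius")):
        for k, v in d.items():
            if v <= 0:
                raise ValueError(f"{what} of '{k}' must be positive")
    if inflow_ml_min < 0:
        raise ValueError("inflow must be non-negative")
    q = inflow_ml_min * ML_MIN_TO_M3_S
    r_fa = poiseuille_resistance(limb_lengths_mm["feeding_artery"], limb_radii_mm["feeding_artery"], viscosity)
    r_v = poiseuille_resistance(limb_lengths_mm["draining_vein"], limb_radii_mm["draining_vein"], viscosity)
    r_da = poiseuille_resistance(limb_lengths_mm["distal_artery"], limb_radii_mm["distal_artery"], viscosity)
    r_vein_d = limb_radii_mm["draining_vein"]
    r_an = anastomosis_resistance_scale * poiseuille_resistance(
        2.0 * r_vein_d, 0.5 * r_vein_d, viscosity
    )
    if r_an <= 0 or not np.isfinite(r_an + r_v + r_da + r_fa):
        raise ValueError("singular network: non-finite or zero resistances")
    # unknown: P_A (anastomosis node); vein inlet follows from the series path
    # node A: q = P_A/(r_an + r_v) + (P_A - P_distal)/r_da
    g = 1.0 / (r_an + r_v) + 1.0 / r_da
    if not np.isfinite(g) or g <= 0:
        raise ValueError("singular network: no conductive path from the anastomosis")
    p_a = (q + distal_pressure / r_da) / g
    q_vein = p_a / (r_an + r_v)
    p_vin = q_vein * r_v
    p_in = p_a + q * r_fa
    q_da = (p_a - distal_pressure) / r_da
    return PressureNetworkResult(
        pressures=dict(
            feeding_artery_inlet=float(p_in), anastomosis=float(p_a),
            vein_inlet=float(p_vin), distal_artery=float(distal_pressure),
            venous_outlet=0.0,
        ),
        flows=dict(inflow=float(q), distal_artery=float(q_da), draining_vein=float(q_vein)),
        distal_reversal=bool(p_a < distal_pressure),
    )
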