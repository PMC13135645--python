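"""Synthetic AVF lumens, wall-shear fields and cohorts.

End-to-side arteriovenous fistulas are generated parametrically: a
through-running artery (feeding + distal limbs) with a vein limb joined at
a prescribed anastomosis angle, each limb a circular tube following a
planar straight-then-arc centreline.  Meshes come from an implicit
signed-distance union of the limb tubes sampled on a regular grid and
triangulated with marching cubes, which is watertight by construction and
whose resolution is set by ``mesh_edge_target``.

Each limb keeps a straight juxta-anastomotic run entering the junction
(surgically, the mobilised vessel ends are straight where they are sewn),
so the anastomosis angle is well defined for curved vessels and the
window-fit angle estimator sees straight centreline near the junction.

The cohort generator draws per-group truncated-normal anatomical variables
whose default means and spreads are those of the packaged 17-fistula
cohort's High/Low-outflow groups, and assigns venous outflow through a
monotone flow link, so recovery of group differences and ROC AUCs can be
tested at any sample size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .geometry import (
    ANASTOMOSIS,
    DISTAL_ARTERY,
    DRAINING_VEIN,
    FEEDING_ARTERY,
    Centreline,
)
from .womersley import (
    BLOOD_DENSITY,
    BLOOD_VISCOSITY,
    FlowWaveform,
    WallShearSeries,
    womersley_wall_shear,
)

__all__ = [
    "AVFDesignParams",
    "SyntheticAVF",
    "CohortSpec",
    "build_tube",
    "build_end_to_side_avf",
    "womersley_wall_shear",
    "womersley_surface_series",
    "generate_cohort",
]


@dataclass
class AVFDesignParams:
    """Design parameters of a synthetic end-to-side AVF (mm, degrees).

    Diameters and curvatures span the ranges measured in the packaged
    cohort (feeding artery 2.2-7.7 mm, vein 2.8-8.6 mm, curvature
    0.013-0.075 mm^-1, angle 24-95 degrees).
    """

    feeding_artery_diameter: float = 4.7
    draining_vein_diameter: float = 6.5
    distal_artery_diameter: float = 4.0
    artery_curvature: float = 0.025
    vein_curvature: float = 0.03
    anastomosis_angle: float = 62.0
    artery_length: float = 110.0
    vein_length: float = 100.0
    distal_length: float = 60.0
    mesh_edge_target: float = 0.5
    juxta_straight: float | None = None  # straight run entering the junction; default vein_diameter + 8
    mirror: bool = False

    def __post_init__(self) -> None:
        for name in ("feeding_artery_diameter", "draining_vein_diameter", "distal_artery_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.anastomosis_angle < 180.0:
            raise ValueError("anastomosis_angle must lie in (0, 180) degrees")
        for name in ("artery_curvature", "vein_curvature"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for lname, kname in (
            ("artery_length", "artery_curvature"),
            ("vein_length", "vein_curvature"),
            ("distal_length", "artery_curvature"),
        ):
            if getattr(self, lname) < 20.0:
                raise ValueError(f"{lname} must be at least 20 mm")
            if getattr(self, kname) * getattr(self, lname) >= np.pi:
                raise ValueError(
                    f"{kname} * {lname} must stay below pi (self-intersecting arc)"
                )
            if getattr(self, lname) < self.straight_run + 5.0:
                raise ValueError(
                    f"{lname} must exceed the juxta-anastomotic straight run "
                    f"({self.straight_run:.1f} mm) by at least 5 mm"
                )
        if self.mesh_edge_target <= 0:
            raise ValueError("mesh_edge_target must be positive")
        if self.draining_vein_diameter > 2.0 * self.feeding_artery_diameter:
            raise ValueError(
                "geometrically impossible junction: vein diameter exceeds the "
                "local artery chord (twice the feeding artery diameter)"
            )

    @property
    def straight_run(self) -> float:
        """Length (mm) of the straight juxta-anastomotic run of every limb.

        Long enough that the anastomosis patch — which at shallow angles
        extends along the limbs as far as the vein and artery surfaces stay
        merged — ends on straight centreline, keeping the window-fit angle
        estimator on straight vessel.  Roughly: the arclength where the
        tube surfaces separate, plus one vein diameter of patch, plus the
        angle-fit window with margin.
        """
        if self.juxta_straight is not None:
            return self.juxta_straight
        theta = np.radians(min(self.anastomosis_angle, 180.0 - self.anastomosis_angle))
        r_v = self.draining_vein_diameter / 2.0
        r_a = max(self.feeding_artery_diameter, self.distal_artery_diameter) / 2.0
        seam_extent = (r_v + r_a) / max(np.sin(theta), 0.2)
        return seam_extent + self.draining_vein_diameter + 10.0


@dataclass
class SyntheticAVF:
    """A built synthetic fistula: mesh, face labels and ground truth."""

    mesh: trimesh.Trimesh
    face_labels: np.ndarray  # per-face str label (limb or 'anastomosis')
    centrelines: dict[str, Centreline]  # ground truth, s=0 at the junction
    params: AVFDesignParams
    junction: np.ndarray  # (3,) junction point, mm

    @property
    def anastomosis_faces(self) -> np.ndarray:
        return np.flatnonzero(self.face_labels == ANASTOMOSIS)


# ---------------------------------------------------------------------------
# centreline construction helpers


def _straight_then_arc(
    origin: np.ndarray,
    direction: np.ndarray,
    bend_normal: np.ndarray,
    straight: float,
    total_length: float,
    curvature: float,
    ds: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Planar straight-run + constant-curvature-arc polyline with curvature.

    Returns (points, kappa).  ``bend_normal`` is the in-plane unit vector the
    arc turns towards.
    """
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    straight = min(straight, total_length)
    n1 = max(int(np.ceil(straight / ds)), 1)
    s1 = np.linspace(0.0, straight, n1 + 1)
    pts = origin + s1[:, None] * direction
    kappa = np.zeros(len(s1))
    arc_len = total_length - straight
    if arc_len > 1e-9 and curvature > 0:
        radius = 1.0 / curvature
        n0 = np.asarray(bend_normal, float)
        n0 = n0 - (n0 @ direction) * direction
        n0 /= np.linalg.norm(n0)
        n2 = max(int(np.ceil(arc_len / ds)), 2)
        phi = np.linspace(0.0, arc_len * curvature, n2 + 1)[1:]
        start = pts[-1]
        arc = (
            start
            + radius * np.sin(phi)[:, None] * direction
            + radius * (1.0 - np.cos(phi))[:, None] * n0
        )
        pts = np.vstack([pts, arc])
        kappa = np.concatenate([kappa, np.full(len(phi), curvature)])
    elif arc_len > 1e-9:
        n2 = max(int(np.ceil(arc_len / ds)), 1)
        s2 = np.linspace(0.0, arc_len, n2 + 1)[1:]
        pts = np.vstack([pts, pts[-1] + s2[:, None] * direction])
        kappa = np.concatenate([kappa, np.zeros(len(s2))])
    return pts, kappa


def _design_centrelines(params: AVFDesignParams) -> dict[str, Centreline]:
    """Ground-truth limb centrelines, s = 0 at the junction (origin)."""
    origin = np.zeros(3)
    theta = np.radians(params.anastomosis_angle)
    ls = params.straight_run
    # feeding artery runs upstream along -x, bending towards -y
    fa_pts, fa_k = _straight_then_arc(
        origin, [-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], ls, params.artery_length,
        params.artery_curvature,
    )
    # distal artery continues downstream along +x, bending towards -y
    da_pts, da_k = _straight_then_arc(
        origin, [1.0, 0.0, 0.0], [0.0, -1.0, 0.0], ls, params.distal_length,
        params.artery_curvature,
    )
    # vein takes off at the anastomosis angle from the downstream direction,
    # bending further away from the artery axis
    v_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
    v_bend = np.array([-np.sin(theta), np.cos(theta), 0.0])
    dv_pts, dv_k = _straight_then_arc(
        origin, v_dir, v_bend, ls, params.vein_length, params.vein_curvature,
    )
    out = {
        FEEDING_ARTERY: Centreline(fa_pts, FEEDING_ARTERY, fa_k),
        DISTAL_ARTERY: Centreline(da_pts, DISTAL_ARTERY, da_k),
        DRAINING_VEIN: Centreline(dv_pts, DRAINING_VEIN, dv_k),
    }
    if params.mirror:
        for label, cl in out.items():
            pts = cl.points.copy()
            pts[:, 1] *= -1.0
            out[label] = Centreline(pts, label, cl.curvature)
    return out


# ---------------------------------------------------------------------------
# meshing


def build_tube(
    centreline: Centreline,
    diameter_profile,
    mesh_edge_target: float = 0.5,
) -> trimesh.Trimesh:
    """Sweep a circular cross-section along a centreline into a closed tube.

    ``diameter_profile`` may be a scalar (mm), an array matching the
    centreline points, or a callable of arclength.  Cross-sections are
    circles of the requested diameter centred on the centreline, carried
    along a parallel-transport frame; flat end caps close the surface, so
    the mesh is watertight by construction.

    Raises ``ValueError`` when the sweep would self-intersect
    (curvature * radius >= 1 anywhere).
    """
    cl = centreline.resample(min(mesh_edge_target, centreline.length / 4))
    s = cl.arclength
    if callable(diameter_profile):
        diam = np.asarray([float(diameter_profile(si)) for si in s])
    else:
        dp = np.asarray(diameter_profile, dtype=float)
        if dp.ndim == 0:
            diam = np.full(len(s), float(dp))
        else:
            diam = np.interp(s, centreline.arclength, dp)
    if np.any(diam <= 0):
        raise ValueError("diameter profile must be positive everywhere")
    kappa = centreline.curvature
    if kappa is None:
        from .geometry import discrete_curvature

        kappa = discrete_curvature(centreline) if len(centreline.points) >= 5 else np.zeros(len(centreline.points))
    kap = np.interp(s, centreline.arclength, kappa)
    worst = np.max(kap * diam / 2.0)
    if worst >= 1.0:
        raise ValueError(
            f"self-intersecting sweep: curvature*radius reaches {worst:.2f} >= 1"
        )

    n_circ = max(12, int(np.ceil(np.pi * np.max(diam) / mesh_edge_target)))
    # parallel-transport frames
    tangents = cl.tangent
    u = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u[0] = np.cross(tangents[0], ref)
    u[0] /= np.linalg.norm(u[0])
    for i in range(1, len(tangents)):
        v = u[i - 1] - (u[i - 1] @ tangents[i]) * tangents[i]
        u[i] = v / np.linalg.norm(v)
    w = np.cross(tangents, u)

    phi = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    rings = (
        cl.points[:, None, :]
        + (diam / 2.0)[:, None, None]
        * (np.cos(phi)[None, :, None] * u[:, None, :] + np.sin(phi)[None, :, None] * w[:, None, :])
    )
    n_st = len(s)
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n_st - 1):
        a = i * n_circ + np.arange(n_circ)
        b = i * n_circ + (np.arange(n_circ) + 1) % n_circ
        c = a + n_circ
        d = b + n_circ
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    faces = np.vstack(faces)
    # end caps: fan around centre vertices
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, cl.points[0], cl.points[-1]])
    ring0 = np.arange(n_circ)
    cap0 = np.column_stack([np.full(n_circ, c0), (ring0 + 1) % n_circ, ring0])
    ringN = (n_st - 1) * n_circ + np.arange(n_circ)
    capN = np.column_stack([
        np.full(n_circ, c1),
        (n_st - 1) * n_circ + ring0,
        (n_st - 1) * n_circ + (ring0 + 1) % n_circ,
    ])
    faces = np.vstack([faces, cap0, capN])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _sdf_tube(points: np.ndarray, tree: cKDTree, radius: float) -> np.ndarray:
    d, _ = tree.query(points, workers=-1)
    return d - radius


def build_end_to_side_avf(params: AVFDesignParams) -> SyntheticAVF:
    """Build a labelled end-to-side AVF lumen mesh with ground truth.

    The three limb tubes are combined as an implicit signed-distance union
    sampled on a regular grid of spacing ``mesh_edge_target`` and
    triangulated with marching cubes, giving a single watertight outward-
    oriented surface.  Faces are labelled by nearest limb; faces within one
    vein diameter of the junction form the anastomosis patch.
    """
    centrelines = _design_centrelines(params)
    radii = {
        FEEDING_ARTERY: params.feeding_artery_diameter / 2.0,
        DISTAL_ARTERY: params.distal_artery_diameter / 2.0,
        DRAINING_VEIN: params.draining_vein_diameter / 2.0,
    }
    _check_limb_clearance(centrelines, radii, params)

    h = params.mesh_edge_target
    dense = {
        label: cl.resample(min(0.4 * h, 0.25)) for label, cl in centrelines.items()
    }
    trees = {label: cKDTree(cl.points) for label, cl in dense.items()}
    all_pts = np.vstack([cl.points for cl in dense.values()])
    r_max = max(radii.values())
    lo = all_pts.min(axis=0) - (r_max + 3 * h)
    hi = all_pts.max(axis=0) + (r_max + 3 * h)
    nx, ny, nz = (np.ceil((hi - lo) / h).astype(int) + 1)
    xs = lo[0] + h * np.arange(nx)
    ys = lo[1] + h * np.arange(ny)
    zs = lo[2] + h * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    phis = np.stack(
        [_sdf_tube(grid, trees[label], radii[label]) for label in trees], axis=1
    )
    vol = phis.min(axis=1).reshape(nx, ny, nz)
    # junction seam: grid points lying on (within one cell of) at least two
    # limb surfaces at once; the anastomosis patch is defined by distance
    # to this curve
    near_surface = np.abs(phis) < 1.2 * h
    seam_pts = grid[near_surface.sum(axis=1) >= 2]
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("implicit union produced a non-watertight surface")

    centroids = mesh.triangles_center
    dists = np.column_stack(
        [_sdf_tube(centroids, trees[label], radii[label]) for label in trees]
    )
    limb_names = np.array(list(trees))
    labels = limb_names[np.argmin(dists, axis=1)].astype(object)
    junction = np.zeros(3)
    near = np.linalg.norm(centroids - junction, axis=1) <= params.draining_vein_diameter
    if len(seam_pts):
        seam_tree = cKDTree(seam_pts)
        near |= seam_tree.query(centroids)[0] <= params.draining_vein_diameter
    labels[near] = ANASTOMOSIS
    return SyntheticAVF(
        mesh=mesh,
        face_labels=np.asarray(labels, dtype=object),
        centrelines=centrelines,
        params=params,
        junction=junction,
    )


def _check_limb_clearance(centrelines, radii, params) -> None:
    """Reject designs whose limbs touch away from the junction."""
    ls = params.straight_run
    pairs = [
        (FEEDING_ARTERY, DRAINING_VEIN),
        (DISTAL_ARTERY, DRAINING_VEIN),
        (FEEDING_ARTERY, DISTAL_ARTERY),
    ]
    for a, b in pairs:
        ca, cb = centrelines[a], centrelines[b]
        ma = ca.arclength > 1.5 * ls
        mb = cb.arclength > 1.5 * ls
        if not (ma.any() and mb.any()):
            continue
        tree = cKDTree(cb.points[mb])
        dmin = tree.query(ca.points[ma])[0].min()
        if dmin < radii[a] + radii[b] + 1.0:
            raise ValueError(
                f"limbs '{a}' and '{b}' approach within {dmin:.1f} mm away from "
                "the junction; reduce curvature or lengths"
            )


# ---------------------------------------------------------------------------
# wall-shear fields on a tube surface


def womersley_surface_series(
    mesh: trimesh.Trimesh,
    centreline: Centreline,
    waveform: FlowWaveform,
    viscosity: float = BLOOD_VISCOSITY,
    density: float = BLOOD_DENSITY,
    times: np.ndarray | None = None,
    radius: float | None = None,
):
    """Map a Womersley wall-shear series onto a tube surface.

    Each face carries the signed axial shear in the local downstream
    direction (the centreline tangent at the nearest station, projected
    onto the face tangent plane).  ``radius`` defaults to half the mean
    section diameter recorded on the centreline.

    Returns a :class:`avflow.metrics.SurfaceFieldSeries`.
    """
    from .metrics import SurfaceFieldSeries

    if radius is None:
        if centreline.section_diameter is None:
            raise ValueError("radius not given and centreline has no diameters")
        radius = float(np.mean(centreline.section_diameter) / 2.0)
    series = womersley_wall_shear(radius, waveform, viscosity, density, times)
    tree = cKDTree(centreline.points)
    _, idx = tree.query(mesh.triangles_center)
    axial = centreline.tangent[idx]
    normals = mesh.face_normals
    tang = axial - np.sum(axial * normals, axis=1, keepdims=True) * normals
    nrm = np.linalg.norm(tang, axis=1, keepdims=True)
    degenerate = nrm[:, 0] < 1e-9  # faces whose normal is (anti)parallel to the axis
    nrm[degenerate] = 1.0
    tang = tang / nrm
    tang[degenerate] = 0.0
    traction = series.signed[:, None, None] * tang[None, :, :]
    return SurfaceFieldSeries(
        mesh=mesh, times=series.times, traction=traction, period=waveform.period
    )


# ---------------------------------------------------------------------------
# cohorts


def _default_group_params() -> tuple[dict, dict]:
    """High/Low-outflow group means and SDs of the packaged cohort."""
    from .stats import dichotomize_flow, load_table2_fixture

    df = load_table2_fixture()
    df = dichotomize_flow(df)
    means: dict[str, tuple[float, float]] = {}
    sds: dict[str, tuple[float, float]] = {}
    for var in ("fa_diameter_mm", "fa_curvature", "dv_diameter_mm",
                "dv_curvature", "anastomosis_angle_deg"):
        hi = df.loc[df.outflow_category == "High", var]
        lo = df.loc[df.outflow_category == "Low", var]
        means[var] = (float(hi.mean()), float(lo.mean()))
        sds[var] = (float(hi.std(ddof=0)), float(lo.std(ddof=0)))
    return means, sds


DEFAULT_VARIABLE_BOUNDS = {
    "fa_diameter_mm": (0.5, 20.0),
    "fa_curvature": (0.0, 0.2),
    "dv_diameter_mm": (0.5, 20.0),
    "dv_curvature": (0.0, 0.2),
    "anastomosis_angle_deg": (5.0, 175.0),
}


def _default_flow_link(is_high: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Monotone latent-to-outflow map consistent with the >=1000 ml/min rule.

    High-group fistulas draw outflow from a truncated normal above
    1000 ml/min (location 1400, scale 400); Low-group below it (location
    700, scale 250, floored at 50).
    """
    n = len(is_high)
    out = np.empty(n)
    for i in range(n):
        lo, hi = (1000.0, 4000.0) if is_high[i] else (50.0, 1000.0 - 1e-9)
        mu, sd = (1400.0, 400.0) if is_high[i] else (700.0, 250.0)
        out[i] = _truncated_normal(rng, mu, sd, lo, hi)
    return out


def _truncated_normal(rng, mu, sd, lo, hi, max_tries: int = 100) -> float:
    for _ in range(max_tries):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError(
        f"truncated-normal rejection failed after {max_tries} draws "
        f"(mu={mu}, sd={sd}, bounds=({lo}, {hi}))"
    )


@dataclass
class CohortSpec:
    """Specification of a synthetic two-group (High/Low outflow) cohort.

    ``group_means``/``group_sds`` map variable name -> (High, Low) location
    and scale; defaults are the packaged cohort's per-category values.
    Draws are truncated at physical bounds by rejection (at most 100
    attempts per value).  One integer seed drives the whole table.
    """

    n_per_group: int = 50
    group_means: dict[str, tuple[float, float]] | None = None
    group_sds: dict[str, tuple[float, float]] | None = None
    bounds: dict[str, tuple[float, float]] | None = None
    flow_link: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.group_means is None or self.group_sds is None:
            means, sds = _default_group_params()
            if self.group_means is None:
                self.group_means = means
            if self.group_sds is None:
                self.group_sds = sds
        for var, (s_hi, s_lo) in self.group_sds.items():
            if s_hi <= 0 or s_lo <= 0:
                raise ValueError(f"group SDs must be positive ({var})")
        if set(self.group_means) != set(self.group_sds):
            raise ValueError("group_means and group_sds must cover the same variables")


def generate_cohort(spec: CohortSpec) -> "pandas.DataFrame":  # noqa: F821
    """Draw a synthetic cohort table with the packaged-cohort schema.

    Reproducible given ``spec.seed``; variables are truncated-normal per
    group, venous outflow comes from the flow link, and the outflow
    category column restates the >= 1000 ml/min rule.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    is_high = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    data: dict[str, np.ndarray] = {}
    bounds = dict(DEFAULT_VARIABLE_BOUNDS)
    if spec.bounds:
        bounds.update(spec.bounds)
    for var in spec.group_means:
        mu_hi, mu_lo = spec.group_means[var]
        sd_hi, sd_lo = spec.group_sds[var]
        lo, hi = bounds.get(var, (-np.inf, np.inf))
        vals = np.empty(2 * n)
        for i in range(2 * n):
            mu, sd = (mu_hi, sd_hi) if is_high[i] else (mu_lo, sd_lo)
            vals[i] = _truncated_normal(rng, mu, sd, lo, hi)
        data[var] = vals
    link = spec.flow_link or _default_flow_link
    outflow = link(is_high, rng)
    df = pd.DataFrame(data)
    df.insert(0, "patient_id", [f"SYN{i:04d}" for i in range(2 * n)])
    df.insert(1, "fistula_type", np.where(rng.random(2 * n) < 10 / 17, "RCF",
                                          np.where(rng.random(2 * n) < 6 / 7, "BCF", "BBF")))
    df.insert(2, "side", np.where(rng.random(2 * n) < 15 / 17, "left", "right"))
    df.insert(3, "outcome", np.where(rng.random(2 * n) < 13 / 17, "S", "U"))
    df.insert(4, "venous_outflow_ml_min", outflow)
    df.insert(5, "outflow_category", np.where(outflow >= 1000.0, "High", "Low"))
    return df
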