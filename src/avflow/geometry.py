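"""Centreline extraction and anatomical characterisation of vessel lumens.

The anatomical descriptors used throughout the package are the ones a
vascular-access study reads off a segmented arteriovenous-fistula (AVF)
lumen: per-station equivalent diameter, centreline curvature, the
anastomosis angle between the feeding artery and the draining vein, and
windowed means of these quantities over the first 10 cm (feeding artery,
draining vein) or 5 cm (distal artery) of each limb.  Lumens are watertight
triangle surface meshes with coordinates in millimetres.

Conventions
-----------
* Arclength ``s`` is measured in mm from the anastomosis-patch boundary of
  each limb, increasing away from the junction.
* Curvature is reported in mm^-1.
* The anastomosis angle is the angle, in degrees, between the feeding-artery
  centreline direction entering the junction (directed downstream) and the
  draining-vein take-off direction (directed away from the junction).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

FEEDING_ARTERY = "feeding_artery"
DRAINING_VEIN = "draining_vein"
DISTAL_ARTERY = "distal_artery"
ANASTOMOSIS = "anastomosis"

LIMB_LABELS = (FEEDING_ARTERY, DRAINING_VEIN, DISTAL_ARTERY)

#: windows (mm) over which per-limb summaries are averaged
SUMMARY_WINDOWS_MM = {FEEDING_ARTERY: 100.0, DRAINING_VEIN: 100.0, DISTAL_ARTERY: 50.0}


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Centreline:
    """Arclength-parameterised polyline through a vessel lumen.

    Attributes
    ----------
    points : (n, 3) float array, mm
    limb_label : one of :data:`LIMB_LABELS` (or a free label)
    curvature : optional per-point curvature (mm^-1); filled analytically by
        the synthetic builder or numerically by :func:`discrete_curvature`.
    section_diameter : optional per-point equivalent diameter (mm) recorded
        while marching cross-sections during :func:`extract_centreline`.
    """

    points: np.ndarray
    limb_label: str = "vessel"
    curvature: np.ndarray | None = None
    section_diameter: np.ndarray | None = None
    arclength: np.ndarray = field(init=False)
    tangent: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("centreline needs at least two 3-D points")
        self.arclength = _cumulative_arclength(self.points)
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("degenerate (repeated) centreline points")
        self.tangent = np.gradient(self.points, self.arclength, axis=0)
        self.tangent /= np.linalg.norm(self.tangent, axis=1, keepdims=True)
        if self.curvature is not None:
            self.curvature = np.asarray(self.curvature, dtype=float)
            if self.curvature.shape[0] != self.points.shape[0]:
                raise ValueError("curvature length mismatch")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, self.points[:, k])
        return out

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, self.tangent[:, k])
        nrm = np.linalg.norm(out, axis=-1, keepdims=True)
        return out / nrm

    def resample(self, spacing: float = 1.0) -> "Centreline":
        n = max(int(np.ceil(self.length / spacing)) + 1, 2)
        s = np.linspace(0.0, self.length, n)
        kappa = None
        if self.curvature is not None:
            kappa = np.interp(s, self.arclength, self.curvature)
        diam = None
        if self.section_diameter is not None:
            diam = np.interp(s, self.arclength, self.section_diameter)
        return Centreline(self.point_at(s), self.limb_label, kappa, diam)

    def reverse(self) -> "Centreline":
        kappa = None if self.curvature is None else self.curvature[::-1].copy()
        diam = None if self.section_diameter is None else self.section_diameter[::-1].copy()
        return Centreline(self.points[::-1].copy(), self.limb_label, kappa, diam)


@dataclass
class SegmentTable:
    """1 cm arclength partition of the lumen surface.

    ``segments`` has one row per segment: limb, seg_index, s_start, s_end,
    is_anastomosis, is_partial.  ``face_segment`` maps every surface face to
    its segment row index; the anastomosis patch is its own segment so the
    rows partition the surface.
    """

    segments: "pandas.DataFrame"  # noqa: F821 - imported lazily
    face_segment: np.ndarray

    def faces_of(self, row_index: int) -> np.ndarray:
        return np.flatnonzero(self.face_segment == row_index)


@dataclass
class AnatomicalSummary:
    """Windowed anatomical descriptors of one fistula (Table-2 style)."""

    feeding_artery_diameter: float
    draining_vein_diameter: float
    distal_artery_diameter: float
    feeding_artery_curvature: float
    draining_vein_curvature: float
    distal_artery_curvature: float
    anastomosis_angle: float
    vein_minus_artery_diameter: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# plane sections


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _loop_area_centroid(loop: np.ndarray, normal: np.ndarray) -> tuple[float, np.ndarray]:
    """Area and area-centroid of a closed planar polygon given in 3-D."""
    pts = loop
    if np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
        pts = pts[:-1]
    origin = pts.mean(axis=0)
    u, v = _plane_basis(normal)
    x = (pts - origin) @ u
    y = (pts - origin) @ v
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        return 0.0, origin
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    return abs(area), origin + cx * u + cy * v


def _section_loops(mesh: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray):
    """Closed intersection polygons of a plane with the mesh."""
    try:
        path = mesh.section(plane_origin=origin, plane_normal=normal)
    except Exception:
        return []
    if path is None:
        return []
    loops = []
    for pts in path.discrete:
        pts = np.asarray(pts)
        if len(pts) < 3:
            continue
        closed = np.linalg.norm(pts[0] - pts[-1]) < 1e-6
        loops.append((pts, closed))
    return loops


def _nearest_loop(loops, point: np.ndarray, normal: np.ndarray):
    """Pick the loop whose centroid is nearest ``point``; None if none close."""
    best = None
    for pts, closed in loops:
        area, centroid = _loop_area_centroid(pts, normal)
        if area <= 0:
            continue
        d = np.linalg.norm(centroid - point)
        r_max = np.max(np.linalg.norm(pts - centroid, axis=1))
        if d > r_max:  # point not plausibly inside this loop
            continue
        if best is None or d < best[3]:
            best = (pts, closed, area, d, centroid)
    return best


# ---------------------------------------------------------------------------
# centreline extraction


def points_inside(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Approximate interior test: sign of the offset to the nearest face.

    A point is inside when it lies behind the outward normal of its nearest
    face (nearest by face centroid).  Accurate whenever the point is
    farther from the surface than the local face size, which holds for
    seeds placed inside a lumen.
    """
    points = np.atleast_2d(points)
    tree = cKDTree(mesh.triangles_center)
    _, idx = tree.query(points)
    offs = points - mesh.triangles_center[idx]
    return np.einsum("ij,ij->i", offs, mesh.face_normals[idx]) < 0.0


def extract_centreline(
    mesh: trimesh.Trimesh,
    endpoint_seeds: tuple[np.ndarray, np.ndarray],
    step: float = 1.0,
    stop_faces: np.ndarray | None = None,
    stop_margin: float | None = None,
    direction_relax: float = 0.7,
    resample_spacing: float = 1.0,
    limb_label: str = "vessel",
) -> Centreline:
    """March cross-section centroids from one interior seed towards another.

    At every station the mesh is cut with the plane normal to the current
    marching direction; the area centroid of the closed intersection polygon
    containing the current point becomes the next centreline point.  The
    marching direction is exponentially relaxed to damp centroid noise.

    Parameters
    ----------
    endpoint_seeds : pair of interior points (start, target), mm.
    stop_faces : optional face indices (e.g. the anastomosis patch); the
        march stops when the current point comes within the local section
        radius plus ``stop_margin`` of any of their centroids.
    stop_margin : extra clearance beyond the local radius for the
        ``stop_faces`` criterion (default: step).

    Returns a :class:`Centreline` resampled at ``resample_spacing`` with the
    per-station equivalent diameters recorded in ``section_diameter``.
    """
    start = np.asarray(endpoint_seeds[0], dtype=float)
    target = np.asarray(endpoint_seeds[1], dtype=float)
    if not mesh.is_watertight:
        raise ValueError("mesh must be watertight for centreline extraction")
    inside = points_inside(mesh, np.vstack([start, target]))
    if not inside.all():
        which = [name for name, ok in zip(("start", "target"), inside) if not ok]
        raise ValueError(f"seed point(s) outside the lumen: {', '.join(which)}")
    n_comp = mesh.body_count
    if n_comp > 1:
        raise ValueError(f"disconnected lumen: {n_comp} components")

    patch_tree = None
    if stop_faces is not None and len(stop_faces) > 0:
        patch_tree = cKDTree(mesh.triangles_center[np.asarray(stop_faces)])
        if stop_margin is None:
            stop_margin = step

    direction = target - start
    direction /= np.linalg.norm(direction)
    point = start.copy()
    pts: list[np.ndarray] = []
    diams: list[float] = []
    areas: list[float] = []
    max_steps = int(np.linalg.norm(target - start) / step * 3) + 50

    for _ in range(max_steps):
        loops = _section_loops(mesh, point, direction)
        best = _nearest_loop(loops, point, direction)
        if best is None or not best[1]:
            break  # open cut: exited through an end cap
        loop, _, area, _, centroid = best
        if areas and area > 2.0 * np.median(areas[-10:]):
            break  # section ballooning into the junction
        if pts:
            new_dir = centroid - pts[-1]
            nrm = np.linalg.norm(new_dir)
            if nrm > 1e-9:
                direction = direction_relax * direction + (1 - direction_relax) * (new_dir / nrm)
                direction /= np.linalg.norm(direction)
        pts.append(centroid)
        areas.append(area)
        diams.append(2.0 * np.sqrt(area / np.pi))
        if patch_tree is not None:
            if patch_tree.query(centroid)[0] < diams[-1] / 2.0 + stop_margin:
                break
        to_target = target - centroid
        if np.linalg.norm(to_target) < step or to_target @ direction <= 0:
            break
        point = centroid + step * direction

    if len(pts) < 2:
        raise ValueError("centreline extraction failed: fewer than 2 stations")
    line = Centreline(np.asarray(pts), limb_label, section_diameter=np.asarray(diams))

    # refinement pass: re-cut every station with the tangent estimated from
    # the first pass, removing the tilt of the chord-based start-up planes
    ref_pts, ref_diams = [], []
    for p, t in zip(line.points, line.tangent):
        best = _nearest_loop(_section_loops(mesh, p, t), p, t)
        if best is None or not best[1]:
            continue
        _, _, area, _, centroid = best
        ref_pts.append(centroid)
        ref_diams.append(2.0 * np.sqrt(area / np.pi))
    if len(ref_pts) >= 2:
        line = Centreline(np.asarray(ref_pts), limb_label,
                          section_diameter=np.asarray(ref_diams))
    return line.resample(resample_spacing)


# ---------------------------------------------------------------------------
# curvature


def discrete_curvature(
    centreline: Centreline,
    smoothing_window: float = 10.0,
    presmooth: bool = True,
) -> np.ndarray:
    """Per-point curvature kappa = |r' x r''| / |r'|^3 (mm^-1).

    Each coordinate is first smoothed with a boxcar of half-width
    ``smoothing_window/4`` in arclength, then locally fitted with a
    quadratic in arclength over a window of half-width
    ``smoothing_window/2``; the fitted first and second derivatives give
    kappa.  Windows become one-sided at the endpoints.  The estimate is
    exactly invariant under rigid motions of the input.
    """
    if centreline.points.shape[0] < 5:
        raise ValueError("curvature needs at least 5 points")
    s = centreline.arclength
    p = centreline.points
    if presmooth:
        # the averaging window shrinks near the ends so it stays symmetric
        # about each point; a one-sided average would displace endpoints
        # towards the concave side of a curved line and invent curvature
        sm = np.empty_like(p)
        for i in range(len(s)):
            half = min(smoothing_window / 4.0, s[i] - s[0], s[-1] - s[i])
            m = np.abs(s - s[i]) <= half + 1e-12
            sm[i] = p[m].mean(axis=0)
        p = sm
    half = smoothing_window / 2.0
    kappa = np.empty(len(s))
    for i in range(len(s)):
        m = np.abs(s - s[i]) <= half
        if m.sum() < 5:  # widen to the 5 nearest points
            idx = np.argsort(np.abs(s - s[i]))[:5]
            m = np.zeros(len(s), bool)
            m[idx] = True
        ds = s[m] - s[i]
        A = np.column_stack([np.ones_like(ds), ds, ds**2])
        coef, *_ = np.linalg.lstsq(A, p[m], rcond=None)
        r1, r2 = coef[1], 2.0 * coef[2]
        denom = np.linalg.norm(r1) ** 3
        kappa[i] = np.linalg.norm(np.cross(r1, r2)) / denom if denom > 0 else np.nan
    return kappa


# ---------------------------------------------------------------------------
# diameters


def station_diameter(
    mesh: trimesh.Trimesh,
    centreline: Centreline,
    s: float,
    anastomosis_faces: np.ndarray | None = None,
) -> float:
    """Equivalent-circle diameter D = 2*sqrt(A/pi) of the lumen section at s.

    The mesh is cut with the plane normal to the centreline tangent at
    arclength ``s``; the closed intersection polygon containing the
    centreline point supplies the section area A.  Returns NaN (flagged
    missing) for open cuts (plane exiting through an end cap) and for
    stations inside the labelled anastomosis patch.
    """
    if not (0.0 <= s <= centreline.length):
        raise ValueError(f"station s={s} outside centreline range [0, {centreline.length}]")
    point = centreline.point_at(s)
    normal = centreline.tangent_at(s)
    loops = _section_loops(mesh, point, normal)
    best = _nearest_loop(loops, point, normal)
    if best is None or not best[1]:
        return float("nan")
    loop, _, area, _, centroid = best
    if anastomosis_faces is not None and len(anastomosis_faces) > 0:
        patch = mesh.triangles_center[np.asarray(anastomosis_faces)]
        r_loop = np.max(np.linalg.norm(loop - centroid, axis=1))
        if np.min(np.linalg.norm(patch - centroid, axis=1)) < 1.2 * r_loop:
            return float("nan")
    return 2.0 * np.sqrt(area / np.pi)


# ---------------------------------------------------------------------------
# segmentation


def partition_segments(
    mesh: trimesh.Trimesh,
    centrelines: dict[str, Centreline],
    anastomosis_faces: np.ndarray,
    segment_length: float = 10.0,
) -> SegmentTable:
    """Partition the lumen surface into 1 cm arclength segments per limb.

    Every non-anastomosis face is assigned to the limb of its nearest
    centreline station and to the consecutive ``[k*L, (k+1)*L)`` arclength
    bin of that station (L = ``segment_length``), counted from the
    anastomosis-patch boundary outward.  A trailing bin shorter than L is
    kept and flagged partial.  The anastomosis patch is one separate
    segment, so the segments partition the surface.
    """
    import pandas as pd

    anastomosis_faces = np.asarray(anastomosis_faces, dtype=int)
    centroids = mesh.triangles_center
    n_faces = len(centroids)
    is_patch = np.zeros(n_faces, bool)
    is_patch[anastomosis_faces] = True

    all_pts, all_limb, all_s = [], [], []
    for li, (label, cl) in enumerate(centrelines.items()):
        all_pts.append(cl.points)
        all_limb.append(np.full(len(cl.points), li))
        all_s.append(cl.arclength)
    tree = cKDTree(np.vstack(all_pts))
    limb_of_pt = np.concatenate(all_limb)
    s_of_pt = np.concatenate(all_s)
    labels = list(centrelines)

    _, nearest = tree.query(centroids[~is_patch])
    face_limb = limb_of_pt[nearest]
    face_s = s_of_pt[nearest]

    rows = []
    face_segment = np.full(n_faces, -1, dtype=int)
    free_idx = np.flatnonzero(~is_patch)
    for li, label in enumerate(labels):
        length = centrelines[label].length
        n_full = int(np.floor(length / segment_length))
        n_bins = n_full + (1 if length - n_full * segment_length > 1e-9 else 0)
        for k in range(max(n_bins, 1)):
            s0 = k * segment_length
            s1 = min((k + 1) * segment_length, length)
            rows.append(
                dict(limb=label, seg_index=k, s_start=s0, s_end=s1,
                     is_anastomosis=False, is_partial=(s1 - s0) < segment_length - 1e-9)
            )
            row_id = len(rows) - 1
            sel = (face_limb == li) & (face_s >= s0) & ((face_s < s1) | (k == max(n_bins, 1) - 1) & (face_s <= s1))
            face_segment[free_idx[sel]] = row_id
    rows.append(dict(limb=ANASTOMOSIS, seg_index=-1, s_start=np.nan, s_end=np.nan,
                     is_anastomosis=True, is_partial=False))
    face_segment[is_patch] = len(rows) - 1
    segments = pd.DataFrame(rows)
    if (face_segment < 0).any():
        raise RuntimeError("internal error: unassigned faces in partition")
    return SegmentTable(segments=segments, face_segment=face_segment)


# ---------------------------------------------------------------------------
# anastomosis angle


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Principal direction of a point cloud, oriented from first to last."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    if d @ (points[-1] - points[0]) < 0:
        d = -d
    return d


def anastomosis_angle(
    feeding_centreline: Centreline,
    vein_centreline: Centreline,
    fit_window: float = 5.0,
) -> float:
    """Angle (degrees) between the feeding-artery and draining-vein take-off.

    A straight line is fitted to the feeding-artery centreline points within
    ``fit_window`` mm of the junction end (s = 0) and oriented downstream
    (towards the junction); another to the first window of the vein,
    oriented away from the junction.  The angle between the two directed
    lines is reported in (0, 180) degrees; larger values mean a more obtuse
    junction.
    """
    angle_dirs = []
    for cl, toward_junction in ((feeding_centreline, True), (vein_centreline, False)):
        m = cl.arclength <= fit_window
        if m.sum() < 3:
            raise ValueError(
                f"fewer than 3 centreline points within {fit_window} mm of the "
                f"junction on {cl.limb_label}; increase fit_window"
            )
        d = _fit_direction(cl.points[m])  # oriented with increasing s (away)
        angle_dirs.append(-d if toward_junction else d)
    cosang = np.clip(angle_dirs[0] @ angle_dirs[1], -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# summary


def summarise_anatomy(
    mesh: trimesh.Trimesh,
    centrelines: dict[str, Centreline],
    anastomosis_faces: np.ndarray | None = None,
    windows_mm: dict[str, float] | None = None,
    smoothing_window: float = 10.0,
    fit_window: float = 5.0,
    sample_spacing: float = 1.0,
) -> AnatomicalSummary:
    """Windowed mean diameters and curvatures plus the anastomosis angle.

    Diameters are sampled every ``sample_spacing`` mm along each limb and
    averaged over the first 100 mm (feeding artery, draining vein) or 50 mm
    (distal artery) of centreline, truncated to the available limb length;
    stations with a missing diameter are excluded.  Curvature is averaged
    over the same windows.
    """
    windows = dict(SUMMARY_WINDOWS_MM)
    if windows_mm:
        windows.update(windows_mm)
    means_d, means_k = {}, {}
    for label, cl in centrelines.items():
        if cl.length < 10.0:
            raise ValueError(f"limb '{label}' shorter than 10 mm")
        w = min(windows.get(label, 100.0), cl.length)
        stations = np.minimum(np.arange(0.0, w + 1e-9, sample_spacing), cl.length)
        if cl.section_diameter is not None:
            diams = np.interp(stations, cl.arclength, cl.section_diameter)
        else:
            diams = np.array(
                [station_diameter(mesh, cl, s, anastomosis_faces) for s in stations]
            )
        valid = np.isfinite(diams)
        if not valid.any():
            raise ValueError(f"no valid diameter stations on limb '{label}'")
        means_d[label] = float(diams[valid].mean())
        if cl.curvature is not None:
            kappa = np.interp(stations, cl.arclength, cl.curvature)
        else:
            kappa = np.interp(
                stations, cl.arclength, discrete_curvature(cl, smoothing_window)
            )
        means_k[label] = float(np.nanmean(kappa))
    angle = anastomosis_angle(
        centrelines[FEEDING_ARTERY], centrelines[DRAINING_VEIN], fit_window
    )
    return AnatomicalSummary(
        feeding_artery_diameter=means_d[FEEDING_ARTERY],
        draining_vein_diameter=means_d[DRAINING_VEIN],
        distal_artery_diameter=means_d.get(DISTAL_ARTERY, float("nan")),
        feeding_artery_curvature=means_k[FEEDING_ARTERY],
        draining_vein_curvature=means_k[DRAINING_VEIN],
        distal_artery_curvature=means_k.get(DISTAL_ARTERY, float("nan")),
        anastomosis_angle=angle,
        vein_minus_artery_diameter=means_d[DRAINING_VEIN] - means_d[FEEDING_ARTERY],
    )


def extract_limb_centrelines(
    mesh: trimesh.Trimesh,
    anastomosis_faces: np.ndarray,
    limb_seeds: dict[str, np.ndarray],
    junction: np.ndarray,
    step: float = 1.0,
    stop_margin: float = 2.0,
) -> dict[str, Centreline]:
    """Extract one centreline per limb, s = 0 at the anastomosis-patch boundary.

    For each limb the march starts at its outer seed (an interior point near
    the limb's free end) and proceeds towards the junction, stopping at the
    labelled anastomosis patch.  The returned centrelines are reversed so
    arclength increases away from the junction.
    """
    junction = np.asarray(junction, float)
    out = {}
    for label, seed in limb_seeds.items():
        line = extract_centreline(
            mesh,
            (np.asarray(seed, float), junction),
            step=step,
            stop_faces=anastomosis_faces,
            stop_margin=stop_margin,
            limb_label=label,
        )
        out[label] = line.reverse()
    return out


def centrelines_to_frame(centrelines: dict[str, Centreline]) -> "pandas.DataFrame":  # noqa: F821
    """Tidy per-point table: limb, s_mm, x, y, z, kappa_per_mm."""
    import pandas as pd

    frames = []
    for label, cl in centrelines.items():
        kappa = cl.curvature
        if kappa is None:
            kappa = discrete_curvature(cl) if len(cl.points) >= 5 else np.full(len(cl.points), np.nan)
        frames.append(pd.DataFrame(dict(
            limb=label, s_mm=cl.arclength, x=cl.points[:, 0], y=cl.points[:, 1],
            z=cl.points[:, 2], kappa_per_mm=kappa,
        )))
    return pd.concat(frames, ignore_index=True)
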