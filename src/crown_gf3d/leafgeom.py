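"""Per-leaf geometric modelling.

Each segmented leaf is reduced to a hexagonal prism:

1. moving-least-squares (MLS) smoothing removes ghost points caused by
   foliage motion during scanning;
2. the midrib axis L1 is the farthest point pair (petiole tip p_e, apex p_s);
3. slicing perpendicular to L1 yields raw left/right edge points, refined by
   independent least-squares cubics in the leaf-local frame;
4. the lamina normal comes from the covariance of the fitted points, and the
   extent of the points along it -- the *equivalent leaf thickness* -- captures
   how curled/drooped the blade is;
5. six vertices (p_e, two left edge points, p_s, two right edge points) form
   the hexagonal base, extruded by the equivalent thickness to give the
   equivalent leaf volume V_leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Polygon

from .config import PipelineConfig

__all__ = [
    "LeafModel",
    "mls_smooth",
    "find_midrib_endpoints",
    "slice_edge_points",
    "fit_edge_cubic",
    "fit_cubic_normal_equations",
    "leaf_normal",
    "equivalent_thickness",
    "hexagon_vertices",
    "hexagon_area",
    "hexagon_area_components",
    "hexagonal_prism_volume",
    "model_leaf",
]


@dataclass
class LeafModel:
    """Fitted geometry of one leaf instance."""

    fitted_points: np.ndarray
    p_e: np.ndarray | None = None       # petiole tip (lower endpoint of L1)
    p_s: np.ndarray | None = None       # blade apex
    left_edges: np.ndarray | None = None
    right_edges: np.ndarray | None = None
    hexagon: np.ndarray | None = None   # 6 ordered vertices
    normal: np.ndarray | None = None
    thickness: float = 0.0              # equivalent leaf thickness (m)
    volume: float = 0.0                 # V_leaf (m^3)
    length: float = 0.0
    width: float = 0.0
    quality_flag: str = "ok"            # ok | fallback_bbox | rejected
    leaf_id: int = -1
    notes: list[str] = field(default_factory=list)


def _fix_sign(n: np.ndarray) -> np.ndarray:
    for axis in (2, 1, 0):
        if n[axis] > 0:
            return n
        if n[axis] < 0:
            return -n
    return n


# ---------------------------------------------------------------------------
# MLS smoothing
# ---------------------------------------------------------------------------

def mls_smooth(
    leaf_points: np.ndarray, support_radius: float, degree: int = 2
) -> np.ndarray:
    """Project each point onto a locally weighted polynomial surface.

    The polynomial (degree 1 or 2) is fitted in the local tangent frame of
    each point with Gaussian weights of bandwidth ``support_radius / 2``;
    the point moves to the surface along the local normal, so the output has
    the same point count.  Points whose neighbourhood cannot support the
    degree-2 fit fall back to degree 1; below 3 neighbours the point is kept.
    """
    pts = np.asarray(leaf_points, dtype=np.float64).reshape(-1, 3)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if support_radius <= 0:
        raise ValueError("support_radius must be positive")
    n = len(pts)
    if n < 3:
        return pts.copy()
    tree = cKDTree(pts)
    h = support_radius / 2.0
    out = pts.copy()
    neighbor_lists = tree.query_ball_point(pts, r=support_radius, workers=-1)
    for i in range(n):
        nb = pts[neighbor_lists[i]] - pts[i]
        m = len(nb)
        if m < 3:
            continue
        cov = nb.T @ nb / m
        lam, vec = np.linalg.eigh(cov)
        if lam[1] <= 1e-30:
            continue  # collinear neighbourhood
        normal = vec[:, 0]
        e1, e2 = vec[:, 2], vec[:, 1]
        t1, t2, z = nb @ e1, nb @ e2, nb @ normal
        wgt = np.exp(-(t1**2 + t2**2 + z**2) / h**2)
        deg = degree if (degree == 1 or m >= 6) else 1
        if deg == 2:
            A = np.column_stack([np.ones(m), t1, t2, t1**2, t1 * t2, t2**2])
        else:
            A = np.column_stack([np.ones(m), t1, t2])
        Aw = A * wgt[:, None]
        try:
            coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ z, rcond=None)
        except np.linalg.LinAlgError:
            continue
        out[i] = pts[i] + coef[0] * normal  # surface height at the local origin
    return out


# ---------------------------------------------------------------------------
# Midrib and edges
# ---------------------------------------------------------------------------

def _farthest_pair_exact(pts: np.ndarray) -> tuple[int, int]:
    n = len(pts)
    best = (-1.0, 0, 0)
    chunk = 512
    for lo in range(0, n, chunk):
        block = pts[lo:lo + chunk]
        d2 = np.sum((block[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        flat = int(np.argmax(d2))
        i, j = divmod(flat, n)
        d = d2[i, j]
        if d > best[0]:
            best = (d, lo + i, j)
    return best[1], best[2]


def find_midrib_endpoints(fitted_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Farthest point pair, ordered as (petiole p_e = lower z, apex p_s).

    Exact pairwise scan for M <= 5000; the farthest pair of the convex hull
    vertices for larger clouds.  Ties are broken by lexicographic coordinate
    order.
    """
    pts = np.asarray(fitted_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for midrib endpoints")
    if len(pts) <= 5000:
        i, j = _farthest_pair_exact(pts)
    else:
        try:
            hull = ConvexHull(pts)
            verts = hull.vertices
        except Exception:
            verts = np.arange(len(pts))
        hi, hj = _farthest_pair_exact(pts[verts])
        i, j = int(verts[hi]), int(verts[hj])
    a, b = pts[i], pts[j]
    # order: p_e is the lower-z endpoint; ties lexicographic on (x, y, z)
    ka, kb = (a[2], a[0], a[1]), (b[2], b[0], b[1])
    if kb < ka:
        a, b = b, a
    return a.copy(), b.copy()


def slice_edge_points(
    fitted_points: np.ndarray,
    p_e: np.ndarray,
    p_s: np.ndarray,
    n_slices: int,
    normal: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Raw left/right edge points from uniform slicing along the midrib.

    Points are binned by their scalar projection on L1 into ``n_slices - 1``
    uniform bands; within each band the extreme points along the in-plane
    transverse direction e2 = normal x e1 give one left and one right edge
    point.  Returns (left, right, skipped_band_indices); the edge lists run
    from the petiole end towards the apex.
    """
    pts = np.asarray(fitted_points, dtype=np.float64).reshape(-1, 3)
    if n_slices < 4:
        raise ValueError("n_slices must be >= 4")
    axis = np.asarray(p_s, dtype=np.float64) - np.asarray(p_e, dtype=np.float64)
    T = np.linalg.norm(axis)
    if T <= 0:
        raise ValueError("degenerate midrib axis (zero length)")
    e1 = axis / T
    if normal is None:
        normal = leaf_normal(pts)
    e2 = np.cross(np.asarray(normal, dtype=np.float64), e1)
    nrm = np.linalg.norm(e2)
    if nrm <= 1e-12:
        raise ValueError("leaf normal parallel to midrib axis")
    e2 = e2 / nrm
    t = (pts - p_e) @ e1
    v = (pts - p_e) @ e2
    nb = n_slices - 1
    band = np.clip(np.floor(t / T * nb).astype(int), 0, nb - 1)
    if len(np.unique(band)) <= 1:
        raise ValueError("all points fall in a single slice band: degenerate axis")
    left, right, skipped = [], [], []
    for k in range(nb):
        members = np.flatnonzero(band == k)
        if len(members) == 0:
            skipped.append(k)
            continue
        left.append(pts[members[np.argmax(v[members])]])
        right.append(pts[members[np.argmin(v[members])]])
    return np.asarray(left), np.asarray(right), skipped


def fit_cubic_normal_equations(u: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares cubic y(u) solved through the 4x4 normal equations."""
    V = np.vander(np.asarray(u, dtype=np.float64), 4, increasing=True)
    G = V.T @ V
    return np.linalg.solve(G, V.T @ np.asarray(y, dtype=np.float64))


def fit_edge_cubic(
    edge_points: np.ndarray,
    p_e: np.ndarray,
    p_s: np.ndarray,
    normal: np.ndarray,
) -> tuple[np.ndarray, bool]:
    """Refine one side's edge points with two independent cubics.

    In the leaf-local frame (u along L1, v transverse in-plane, w along the
    normal) the cubics v(u) and w(u) are fitted by the normal equations;
    refined points keep their u and take the fitted v and w.  With fewer
    than 4 edge points the raw edges are returned unchanged (flag False).
    """
    pts = np.asarray(edge_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        return pts.copy(), False
    axis = np.asarray(p_s, dtype=np.float64) - np.asarray(p_e, dtype=np.float64)
    e1 = axis / np.linalg.norm(axis)
    e3 = np.asarray(normal, dtype=np.float64)
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2)
    e3p = np.cross(e1, e2)  # orthonormalised normal component
    rel = pts - p_e
    u, v, w = rel @ e1, rel @ e2, rel @ e3p
    scale = max(np.ptp(u), 1e-12)  # fit in a scaled abscissa for conditioning
    us = (u - u.min()) / scale
    cv = fit_cubic_normal_equations(us, v)
    cw = fit_cubic_normal_equations(us, w)
    V = np.vander(us, 4, increasing=True)
    v_fit, w_fit = V @ cv, V @ cw
    refined = p_e + np.outer(u, e1) + np.outer(v_fit, e2) + np.outer(w_fit, e3p)
    return refined, True


# ---------------------------------------------------------------------------
# Normal, thickness, hexagon
# ---------------------------------------------------------------------------

def leaf_normal(fitted_points: np.ndarray) -> np.ndarray:
    """Unit lamina normal: smallest covariance eigenvector (z >= 0 sign)."""
    pts = np.asarray(fitted_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a leaf normal")
    c = pts - pts.mean(axis=0)
    lam, vec = np.linalg.eigh(c.T @ c / len(pts))
    if lam[1] <= 1e-30 * max(lam[2], 1.0):
        raise ValueError("degenerate geometry: points are collinear")
    return _fix_sign(vec[:, 0] / np.linalg.norm(vec[:, 0]))


def equivalent_thickness(fitted_points: np.ndarray, normal: np.ndarray) -> float:
    """Extent of the points along the lamina normal (dist^normal, metres)."""
    pts = np.asarray(fitted_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set")
    proj = pts @ np.asarray(normal, dtype=np.float64)
    return float(proj.max() - proj.min())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def hexagon_vertices(
    p_e: np.ndarray,
    p_s: np.ndarray,
    left_edges: np.ndarray,
    right_edges: np.ndarray,
) -> np.ndarray:
    """Six ordered prism-base vertices.

    With n-1 edge points per side (1-based, petiole to apex), the two
    symmetric picks per side are at positions round((n-1)/4) and
    round(3(n-1)/4) (round-half-up).  Order: p_e, lower-left, upper-left,
    p_s, upper-right, lower-right -- a simple polygon in the leaf plane.
    """
    left = np.asarray(left_edges, dtype=np.float64).reshape(-1, 3)
    right = np.asarray(right_edges, dtype=np.float64).reshape(-1, 3)
    n1 = min(len(left), len(right))
    if n1 < 2:
        raise ValueError("need at least 2 edge points per side")
    i1 = _round_half_up(n1 / 4.0)
    i2 = _round_half_up(3.0 * n1 / 4.0)
    if not (1 <= i1 < i2 <= n1):
        raise ValueError(
            f"hexagon edge indices coincide or fall outside range (n-1={n1})"
        )
    return np.vstack([
        np.asarray(p_e, dtype=np.float64),
        left[i1 - 1], left[i2 - 1],
        np.asarray(p_s, dtype=np.float64),
        right[i2 - 1], right[i1 - 1],
    ])


def _hexagon_plane_coords(hexagon: np.ndarray) -> np.ndarray:
    """Project the 6 vertices to their best-fit plane; return 2D coordinates."""
    hexv = np.asarray(hexagon, dtype=np.float64).reshape(6, 3)
    c = hexv - hexv.mean(axis=0)
    _, vec = np.linalg.eigh(c.T @ c)
    e1, e2 = vec[:, 2], vec[:, 1]
    return np.column_stack([c @ e1, c @ e2])


def _shoelace(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def hexagon_area(hexagon: np.ndarray) -> float:
    """Planar area of the hexagonal base (shoelace on the best-fit plane).

    Raises if the projected polygon self-intersects (rejected leaf model).
    """
    xy = _hexagon_plane_coords(hexagon)
    poly = Polygon(xy)
    if not poly.is_valid:
        raise ValueError("hexagon base self-intersects after projection")
    return _shoelace(xy)


def hexagon_area_components(hexagon: np.ndarray) -> tuple[float, float, float]:
    """The named decomposition: upper triangle, middle trapezoid, lower triangle.

    Vertices are ordered (p_e, L1, L2, p_s, R2, R1); the chords L1-R1 and
    L2-R2 split the base into a lower triangle at the petiole, a middle
    trapezoid, and an upper triangle at the apex.  For a simple hexagon the
    three areas sum to the shoelace area exactly.
    """
    xy = _hexagon_plane_coords(hexagon)
    pe, l1, l2, ps, r2, r1 = xy
    lower = _shoelace(np.vstack([pe, l1, r1]))
    middle = _shoelace(np.vstack([l1, l2, r2, r1]))
    upper = _shoelace(np.vstack([l2, ps, r2]))
    return upper, middle, lower


def hexagonal_prism_volume(hexagon: np.ndarray, thickness: float) -> float:
    """Equivalent leaf volume: hexagon base area x equivalent thickness."""
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    return hexagon_area(hexagon) * thickness


# ---------------------------------------------------------------------------
# Per-leaf pipeline
# ---------------------------------------------------------------------------

def _bbox_volume(pts: np.ndarray) -> float:
    """Volume of the covariance-aligned bounding box."""
    c = pts - pts.mean(axis=0)
    if len(pts) < 2:
        return 0.0
    _, vec = np.linalg.eigh(c.T @ c / len(pts))
    local = c @ vec
    extents = np.ptp(local, axis=0)
    return float(np.prod(extents))


def model_leaf(
    leaf_points: np.ndarray,
    config: PipelineConfig | None = None,
    leaf_id: int = -1,
) -> LeafModel:
    """Run the full per-leaf chain and return the fitted :class:`LeafModel`.

    Leaves with fewer than ``min_leaf_points`` points, or whose hexagon
    construction fails, fall back to the covariance-aligned bounding-box
    volume (flag ``fallback_bbox``); fewer than 3 points is ``rejected``
    with zero volume.
    """
    cfg = config or PipelineConfig()
    pts = np.asarray(leaf_points, dtype=np.float64).reshape(-1, 3)
    model = LeafModel(fitted_points=pts.copy(), leaf_id=leaf_id)
    if len(pts) < 3:
        model.quality_flag = "rejected"
        model.volume = 0.0
        return model

    fitted = mls_smooth(pts, cfg.mls_support_radius_, cfg.mls_degree)
    model.fitted_points = fitted
    try:
        normal = leaf_normal(fitted)
        model.normal = normal
        model.thickness = equivalent_thickness(fitted, normal)
    except ValueError as exc:
        model.notes.append(str(exc))
        model.quality_flag = "rejected"
        model.volume = 0.0
        return model

    if len(pts) < cfg.min_leaf_points:
        model.quality_flag = "fallback_bbox"
        model.volume = _bbox_volume(fitted)
        model.notes.append(f"fewer than {cfg.min_leaf_points} points")
        return model

    try:
        p_e, p_s = find_midrib_endpoints(fitted)
        model.p_e, model.p_s = p_e, p_s
        model.length = float(np.linalg.norm(p_s - p_e))
        left_raw, right_raw, skipped = slice_edge_points(
            fitted, p_e, p_s, cfg.n_slices, normal=normal
        )
        if skipped:
            model.notes.append(f"empty slice bands: {skipped}")
        left, ok_l = fit_edge_cubic(left_raw, p_e, p_s, normal)
        right, ok_r = fit_edge_cubic(right_raw, p_e, p_s, normal)
        if not (ok_l and ok_r):
            model.notes.append("edge cubic skipped (too few edge points)")
        model.left_edges, model.right_edges = left, right
        e1 = (p_s - p_e) / np.linalg.norm(p_s - p_e)
        e2 = np.cross(normal, e1)
        e2 /= np.linalg.norm(e2)
        v_all = (fitted - p_e) @ e2
        model.width = float(v_all.max() - v_all.min())
        hexv = hexagon_vertices(p_e, p_s, left, right)
        model.hexagon = hexv
        model.volume = hexagonal_prism_volume(hexv, model.thickness)
        model.quality_flag = "ok"
    except ValueError as exc:
        model.notes.append(str(exc))
        model.quality_flag = "fallback_bbox"
        model.volume = _bbox_volume(fitted)
    return model
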