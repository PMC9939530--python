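"""Branch cylinder fitting and crown volume.

Wood volume is the sum of per-segment cylinder volumes: wood points are
split into connected components on a kNN graph, components are cut into
short runs along their principal axes (re-splitting runs that remain
disconnected, so branches that merely pass through the same slab are not
mixed), and a least-squares cylinder is fitted to each run.

Crown volume is the 3D alpha-shape volume of the vegetative points above
the crown base (the height of the lowest branch); alpha = inf recovers the
convex hull, which is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .io import PointCloud
from .segmentation import mean_nn_spacing


@dataclass
class CylinderModel:
    axis_start: np.ndarray
    axis_end: np.ndarray
    radius: float
    rms_residual: float
    converged: bool = True

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.axis_end - self.axis_start))

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length


@dataclass
class CrownModel:
    crown_points: np.ndarray
    alpha: float
    volume: float
    crown_base_height: float


# ---------------------------------------------------------------------------
# Branch segmentation
# ---------------------------------------------------------------------------

def _local_directions(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-point principal direction and linearity from the kNN patch."""
    n = len(coords)
    kq = min(k + 1, n)
    _, idx = cKDTree(coords).query(coords, k=kq)
    nb = coords[np.atleast_2d(idx)]
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("mij,mil->mjl", nb, nb) / nb.shape[1]
    lam, vec = np.linalg.eigh(cov)
    dirs = vec[:, :, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = (lam[:, 2] - lam[:, 1]) / lam[:, 2]
    lin[~np.isfinite(lin)] = 0.0
    return dirs, lin


def _wood_adjacency(coords: np.ndarray, k: int, max_edge: float) -> csr_matrix:
    """Proximity graph with direction-coherence gating on linear points.

    Slender twigs (locally linear) only link to neighbours whose principal
    directions agree, so branches meeting at a junction fall apart into
    per-twig chains instead of one cylinder-defeating bundle; surface-like
    points of thick branches keep plain proximity links.
    """
    n = len(coords)
    kq = min(k + 1, n)
    dist, idx = cKDTree(coords).query(coords, k=kq)
    # slenderness is judged on a wider patch (k=30): at k~10 the linearity of
    # sparse surface patches fluctuates and the gating would shatter them
    dirs, lin = _local_directions(coords, min(30, n - 1))
    rows = np.repeat(np.arange(n), kq - 1)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    good = vals <= max_edge
    lin_i, lin_j = lin[rows], lin[cols]
    both_linear = (lin_i > 0.7) & (lin_j > 0.7)
    aligned = np.abs(np.einsum("ej,ej->e", dirs[rows], dirs[cols])) >= math.cos(
        math.radians(35.0)
    )
    both_surface = (lin_i <= 0.7) & (lin_j <= 0.7)
    good &= (both_linear & aligned) | both_surface
    g = csr_matrix((np.ones(good.sum()), (rows[good], cols[good])), shape=(n, n))
    return g.maximum(g.T)


def _subgraph_components(adj: csr_matrix, members: np.ndarray) -> list[np.ndarray]:
    sub = adj[members][:, members]
    _, comp = connected_components(sub, directed=False)
    return [members[np.flatnonzero(comp == c)] for c in np.unique(comp)]


def _cut_group(
    coords: np.ndarray, adj: csr_matrix, group: np.ndarray,
    segment_length: float, depth: int = 0,
) -> list[np.ndarray]:
    pts = coords[group]
    if len(pts) < 2:
        return [group]
    c = pts - pts.mean(axis=0)
    _, vec = np.linalg.eigh(c.T @ c / len(pts))
    t = c @ vec[:, 2]
    extent = float(t.max() - t.min())
    if extent <= segment_length or depth >= 12:
        return [group]
    n_runs = int(math.ceil(extent / segment_length))
    edges = np.linspace(t.min(), t.max(), n_runs + 1)
    run_id = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_runs - 1)
    out: list[np.ndarray] = []
    for rid in range(n_runs):
        members = group[run_id == rid]
        if len(members) == 0:
            continue
        # branches that merely cross the same slab stay separate segments
        for sub_members in _subgraph_components(adj, members):
            sub_pts = coords[sub_members]
            sc = sub_pts - sub_pts.mean(axis=0)
            if len(sub_pts) >= 2:
                _, svec = np.linalg.eigh(sc.T @ sc / len(sub_pts))
                sub_extent = float(np.ptp(sc @ svec[:, 2]))
            else:
                sub_extent = 0.0
            if sub_extent > segment_length * 1.05:
                out.extend(_cut_group(coords, adj, sub_members,
                                      segment_length, depth + 1))
            else:
                out.append(sub_members)
    return out


def segment_branch_points(
    wood_cloud: PointCloud, segment_length: float = 0.05, knn_k: int = 10
) -> list[np.ndarray]:
    """Deterministic grouping of wood points into cylinder-sized segments."""
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    coords = wood_cloud.coords
    if len(coords) == 0:
        return []
    if len(coords) == 1:
        return [np.array([0], dtype=np.intp)]
    max_edge = 5.0 * mean_nn_spacing(coords)
    adj = _wood_adjacency(coords, knn_k, max_edge)
    segments: list[np.ndarray] = []
    for group in _subgraph_components(adj, np.arange(len(coords), dtype=np.intp)):
        segments.extend(_cut_group(coords, adj, group, segment_length))
    # fold small fragments (junction cores or surface patches cut off by the
    # direction gating) back into the adjacent larger segment
    big = [s for s in segments if len(s) >= 20]
    small = [s for s in segments if len(s) < 20]
    if big and small:
        owner = np.empty(len(coords), dtype=np.intp)
        for si, s in enumerate(big):
            owner[s] = si
        big_idx = np.concatenate(big)
        tree = cKDTree(coords[big_idx])
        merged = [list(s) for s in big]
        leftover = []
        for s in small:
            d, j = tree.query(coords[s])
            if d.min() <= max_edge:
                merged[owner[big_idx[j[np.argmin(d)]]]].extend(s.tolist())
            else:
                leftover.append(s)
        segments = [np.asarray(sorted(m), dtype=np.intp) for m in merged] + leftover
    segments.sort(key=lambda g: int(g.min()))
    return segments


# ---------------------------------------------------------------------------
# Cylinder fitting
# ---------------------------------------------------------------------------

def _axis_distances(pts: np.ndarray, point: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = pts - point
    along = rel @ direction
    return np.linalg.norm(rel - np.outer(along, direction), axis=1)


def fit_cylinder(segment_points: np.ndarray) -> CylinderModel:
    """Least-squares cylinder (axis + radius) for one branch segment.

    The axis starts at the principal component of the points; the radius,
    axis offset and direction are refined by nonlinear least squares on the
    point-to-axis distances.  Non-convergence falls back to the PCA axis
    with the median distance as radius (flagged).
    """
    pts = np.asarray(segment_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 6:
        raise ValueError("need at least 6 points to fit a cylinder")
    centroid = pts.mean(axis=0)
    c = pts - centroid
    lam, vec = np.linalg.eigh(c.T @ c / len(pts))
    if lam[1] <= 1e-24 * max(lam[2], 1.0):
        raise ValueError("cannot fit a cylinder to collinear points")
    d0 = vec[:, 2]
    # basis orthogonal to the initial axis for the 2-dof axis offset
    b1, b2 = vec[:, 1], vec[:, 0]
    theta0 = math.acos(np.clip(d0[2], -1.0, 1.0))
    phi0 = math.atan2(d0[1], d0[0])
    r0 = float(np.median(_axis_distances(pts, centroid, d0)))
    r0 = max(r0, 1e-9)

    def residuals(x):
        o1, o2, theta, phi, r = x
        point = centroid + o1 * b1 + o2 * b2
        direction = np.array([
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ])
        return _axis_distances(pts, point, direction) - r

    x0 = np.array([0.0, 0.0, theta0, phi0, r0])
    sol = least_squares(residuals, x0, max_nfev=100 * len(x0), method="lm")
    # a near-linear segment under-constrains the radius: a huge, far-away
    # cylinder fits a noisy line as well as a thin one, so reject fits whose
    # radius exceeds the transverse spread of the points themselves
    r_cap = 1.5 * float(np.max(_axis_distances(pts, centroid, d0))) + 1e-12
    converged = bool(sol.success) and 0 < sol.x[4] <= r_cap
    if converged:
        o1, o2, theta, phi, r = sol.x
        point = centroid + o1 * b1 + o2 * b2
        direction = np.array([
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ])
        r = float(abs(r))
        rms = float(np.sqrt(np.mean(sol.fun**2)))
    else:
        point, direction, r = centroid, d0, r0
        rms = float(np.sqrt(np.mean((_axis_distances(pts, point, direction) - r) ** 2)))
    along = (pts - point) @ direction
    start = point + along.min() * direction
    end = point + along.max() * direction
    return CylinderModel(axis_start=start, axis_end=end, radius=max(r, 1e-12),
                         rms_residual=rms, converged=converged)


def wood_volume(cylinders: list[CylinderModel]) -> float:
    """Total branch volume sum_u V_branch_u (0 for an empty list)."""
    return float(sum(c.volume for c in cylinders))


# ---------------------------------------------------------------------------
# Crown volume
# ---------------------------------------------------------------------------

def _tet_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]] - a
    c = pts[simplices[:, 2]] - a
    d = pts[simplices[:, 3]] - a
    return np.abs(np.einsum("ij,ij->i", b, np.cross(c, d))) / 6.0


def _tet_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra (inf for degenerate ones)."""
    a = pts[simplices[:, 0]]
    ba = pts[simplices[:, 1]] - a
    ca = pts[simplices[:, 2]] - a
    da = pts[simplices[:, 3]] - a
    M = np.stack([ba, ca, da], axis=1)            # (n, 3, 3)
    rhs = 0.5 * np.stack(
        [np.sum(ba**2, 1), np.sum(ca**2, 1), np.sum(da**2, 1)], axis=1
    )
    det = np.linalg.det(M)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-30
    if ok.any():
        centres = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centres, axis=1)
    return radii


def alpha_shape_volume(points: np.ndarray, alpha: float) -> float:
    """Volume of the 3D alpha shape (sum of kept Delaunay tetrahedra).

    Tetrahedra with circumradius <= alpha are kept; alpha = inf keeps all
    of them and therefore returns the convex-hull volume exactly.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a volume")
    if math.isinf(alpha):
        return float(ConvexHull(pts).volume)
    tri = Delaunay(pts)
    keep = _tet_circumradii(pts, tri.simplices) <= alpha
    return float(_tet_volumes(pts, tri.simplices)[keep].sum())


def estimate_crown_base_height(
    wood_coords: np.ndarray, fallback: float | None = None
) -> float:
    """Height of the lowest branch: lowest wood point clearly off the trunk.

    The trunk axis is taken as the vertical line through the median (x, y)
    of the lowest 20% of wood points and the trunk radius as their median
    radial distance; the crown base is the minimum z among wood points more
    than twice that radius from the axis.
    """
    pts = np.asarray(wood_coords, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        if fallback is None:
            raise ValueError("no wood points and no fallback crown base")
        return fallback
    z = pts[:, 2]
    zcut = np.quantile(z, 0.2)
    base = pts[z <= zcut]
    axis_xy = np.median(base[:, :2], axis=0)
    # high quantile so measurement noise on the trunk surface stays inside
    r_trunk = float(np.quantile(np.linalg.norm(base[:, :2] - axis_xy, axis=1), 0.98))
    radial = np.linalg.norm(pts[:, :2] - axis_xy, axis=1)
    off_trunk = radial > 2.0 * max(r_trunk, 1e-6)
    if not off_trunk.any():
        return float(z.min())
    return float(z[off_trunk].min())


def crown_volume(
    cloud: PointCloud,
    crown_base_height: float,
    alpha: float = math.inf,
) -> CrownModel:
    """Crown model from the vegetative points above the crown base."""
    pts = cloud.coords[cloud.coords[:, 2] >= crown_base_height]
    if len(pts) < 4:
        raise ValueError("fewer than 4 points above the crown base")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 3:
        raise ValueError("crown points are degenerate (coplanar)")
    vol = alpha_shape_volume(pts, alpha)
    return CrownModel(crown_points=pts, alpha=alpha, volume=vol,
                      crown_base_height=crown_base_height)
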