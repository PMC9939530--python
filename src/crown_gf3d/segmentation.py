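"""Individual leaf segmentation.

A true leaf-centre point has a spherical neighbourhood that (i) lies close to
a plane through the point (the "great circle" of the neighbourhood sphere),
(ii) has locally consistent surface normals, and (iii) covers that great
circle isotropically.  Isotropy is scored by dividing the great-circle disk
into 40 equal-area cells (5 annuli x 8 sectors) and computing the index of
dispersion sigma' = variance/mean of the per-cell counts: sigma' ~ 1 for
uniform coverage, large when the neighbourhood only fills part of the disk
(e.g. at a leaf rim).

Detected centres seed a multi-source geodesic region growing over the kNN
graph (the point-cloud analogue of a 3D watershed); points no seed reaches
are clustered with DBSCAN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.cluster import DBSCAN

from .io import LEAF, PointCloud

_EPS_DEGENERATE = 1e-30


@dataclass(frozen=True)
class Plane:
    """Plane {x : A x + B y + C z = D} with unit normal (A, B, C)."""

    A: float
    B: float
    C: float
    D: float

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C])

    def __post_init__(self) -> None:
        norm = math.sqrt(self.A**2 + self.B**2 + self.C**2)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"plane normal must be unit length, |n| = {norm}")


@dataclass
class CentreDetectionParams:
    radius: float = 0.009375        # 0.75 * (average half leaf width)
    threshold1: float | None = None  # mean plane-distance bound (m); default 0.2*radius
    threshold2: float = math.radians(15.0)
    threshold3: float = 2.0
    min_neighbors: int = 40
    sigma_sqrt: bool = False

    @property
    def threshold1_(self) -> float:
        return self.threshold1 if self.threshold1 is not None else 0.2 * self.radius

    def validate(self) -> None:
        values = {
            "radius": self.radius,
            "threshold1": self.threshold1_,
            "threshold2": self.threshold2,
            "threshold3": self.threshold3,
        }
        for name, value in values.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.min_neighbors < 3:
            raise ValueError("min_neighbors must be >= 3")


@dataclass
class SegmentationParams:
    knn_k: int = 10
    geodesic_cap: float = 0.09      # 2 * average leaf length
    edge_cap_factor: float = 3.0    # max graph edge, in mean nn spacings
    dbscan_eps: float | None = None  # default 4 * mean nearest-neighbour spacing
    dbscan_min_pts: int = 10
    min_leaf_points: int = 40


def _fix_sign(n: np.ndarray) -> np.ndarray:
    """Resolve the +-n ambiguity: z >= 0, ties broken by y >= 0 then x >= 0."""
    for axis in (2, 1, 0):
        if n[axis] > 0:
            return n
        if n[axis] < 0:
            return -n
    return n


def _smallest_eigvec(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh(M)
    return lam, vec[:, 0]


def fit_great_circle_plane(
    cloud: PointCloud, index: int, neighbors: np.ndarray
) -> tuple[Plane, float]:
    """Least-squares plane through p_i and its mean point-to-plane distance.

    The plane is constrained to pass through the query point, so the normal
    is the smallest eigenvector of sum_j w_j w_j^T with w_j = p_j - p_i and
    D = n . p_i.  The centre test (condition i) is mean_distance < threshold1.
    """
    p_i = cloud.coords[index]
    w = cloud.coords[np.asarray(neighbors, dtype=np.intp)] - p_i
    if len(w) < 3:
        raise ValueError("need at least 3 neighbours to fit a plane")
    M = w.T @ w
    lam, n = _smallest_eigvec(M)
    if lam[1] <= _EPS_DEGENERATE * max(lam[2], 1.0):
        raise ValueError("degenerate geometry: neighbours are collinear")
    n = _fix_sign(n / np.linalg.norm(n))
    D = float(n @ p_i)
    mean_distance = float(np.mean(np.abs(w @ n)))
    return Plane(*n, D), mean_distance


def estimate_centre_normal(p_i: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Robust surface normal at p_i from its neighbourhood.

    Off-plane offsets are down-weighted with Gaussian weights
    omega_j = exp(-(w_j . n)^2 / h^2), h = median |w_j . n0| from the
    unweighted fit, and the normal re-estimated as the smallest eigenvector
    of sum_j omega_j w_j w_j^T until the direction moves < 1e-4 rad
    (max 20 iterations).  Sign convention: z >= 0 (ties: y, then x).
    """
    w = np.asarray(neighbors, dtype=np.float64) - np.asarray(p_i, dtype=np.float64)
    if len(w) < 3:
        raise ValueError("need at least 3 neighbours")
    M = w.T @ w
    lam, n = _smallest_eigvec(M)
    if lam[1] <= _EPS_DEGENERATE * max(lam[2], 1.0):
        raise ValueError("degenerate geometry: neighbours are collinear")
    n = n / np.linalg.norm(n)
    h = float(np.median(np.abs(w @ n)))
    if h <= 0:  # exactly planar: weights are irrelevant at zero residual
        return _fix_sign(n)
    for _ in range(20):
        r = w @ n
        omega = np.exp(-((r / h) ** 2))
        Mw = (w * omega[:, None]).T @ w
        _, n_new = _smallest_eigvec(Mw)
        n_new = n_new / np.linalg.norm(n_new)
        if n_new @ n < 0:
            n_new = -n_new
        angle = math.acos(min(1.0, abs(float(n_new @ n))))
        n = n_new
        if angle < 1e-4:
            break
    return _fix_sign(n)


def normal_consistency(n_i: np.ndarray, neighbor_normals: np.ndarray) -> float:
    """Mean angle between n_i and its neighbours' normals (orientation-free).

    The absolute dot product makes the test independent of the +-n sign
    choice of each normal.  Centre test (condition ii): result < threshold2.
    """
    nb = np.atleast_2d(np.asarray(neighbor_normals, dtype=np.float64))
    if nb.size == 0:
        raise ValueError("empty neighbour normal set")
    dots = np.clip(np.abs(nb @ np.asarray(n_i, dtype=np.float64)), 0.0, 1.0)
    return float(np.mean(np.arccos(dots)))


def project_points_to_plane(points: np.ndarray, plane: Plane) -> np.ndarray:
    """Orthogonal projection p' = p - (n.p - D) n onto the plane."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = plane.normal
    resid = pts @ n - plane.D
    return pts - resid[:, None] * n


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane orthonormal basis for a given unit normal."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = ref - (ref @ normal) * normal
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _sigma_from_counts(counts: np.ndarray, sqrt: bool = False) -> float:
    mu = counts.mean()
    if mu == 0:
        return math.inf
    sigma = float(np.sum((counts - mu) ** 2) / counts.size / mu)
    return math.sqrt(sigma) if sqrt else sigma


def angular_uniformity(
    projected_points: np.ndarray,
    centre: np.ndarray,
    plane: Plane,
    R: float,
    sigma_sqrt: bool = False,
) -> float:
    """Dispersion index sigma' of the 40-cell angular occupancy.

    The great-circle disk of radius R about the centre is split into 8
    sectors of 45 deg crossed with 5 equal-area annuli (boundary radii
    R*sqrt(d/5)); sigma' = [sum_d (num_d - mu)^2 / 40] / mu over the 40 cell
    counts.  Points beyond R are discarded; mu = 0 yields +inf.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    pts = np.atleast_2d(np.asarray(projected_points, dtype=np.float64))
    counts = np.zeros(40)
    if pts.size:
        e1, e2 = _plane_basis(plane.normal)
        rel = pts - np.asarray(centre, dtype=np.float64)
        u, v = rel @ e1, rel @ e2
        r = np.hypot(u, v)
        keep = r <= R
        u, v, r = u[keep], v[keep], r[keep]
        ring = np.clip(np.floor(5.0 * (r / R) ** 2).astype(int), 0, 4)
        phi = np.mod(np.arctan2(v, u), 2.0 * math.pi)
        sector = np.clip((phi / (math.pi / 4.0)).astype(int), 0, 7)
        counts += np.bincount(ring * 8 + sector, minlength=40)
    return _sigma_from_counts(counts, sqrt=sigma_sqrt)


# ---------------------------------------------------------------------------
# Batched centre detection
# ---------------------------------------------------------------------------

def _batched_normals_and_tests(
    coords: np.ndarray,
    neighbor_lists: list[np.ndarray],
    params: CentreDetectionParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-point robust normal, plane normal, mean plane distance, validity."""
    n_pts = len(coords)
    normals = np.zeros((n_pts, 3))
    plane_normals = np.zeros((n_pts, 3))
    mean_dist = np.full(n_pts, np.inf)
    valid = np.zeros(n_pts, dtype=bool)

    counts = np.array([len(nb) for nb in neighbor_lists])
    enough = counts >= max(params.min_neighbors, 3)
    if not enough.any():
        return normals, plane_normals, mean_dist, valid

    order = np.flatnonzero(enough)
    chunk = 4000
    for lo in range(0, len(order), chunk):
        sel = order[lo:lo + chunk]
        kmax = int(counts[sel].max())
        m = len(sel)
        w = np.zeros((m, kmax, 3))
        mask = np.zeros((m, kmax), dtype=bool)
        for row, i in enumerate(sel):
            nb = neighbor_lists[i]
            w[row, : len(nb)] = coords[nb] - coords[i]
            mask[row, : len(nb)] = True
        # unweighted plane through p_i (padding rows are zero => no effect on M)
        M = np.einsum("mkj,mkl->mjl", w, w)
        lam, vec = np.linalg.eigh(M)
        n0 = vec[:, :, 0]
        ok = lam[:, 1] > _EPS_DEGENERATE * np.maximum(lam[:, 2], 1.0)
        resid0 = np.einsum("mkj,mj->mk", w, n0)
        mean_dist[sel] = np.where(mask, np.abs(resid0), 0.0).sum(axis=1) / mask.sum(axis=1)
        # IRLS refinement with Gaussian down-weighting of off-plane offsets
        h = np.nanmedian(np.abs(np.where(mask, resid0, np.nan)), axis=1)
        h = np.maximum(h, 1e-12)
        n = n0.copy()
        active = ok.copy()
        for _ in range(20):
            if not active.any():
                break
            r = np.einsum("mkj,mj->mk", w, n)
            omega = np.exp(-((r / h[:, None]) ** 2)) * mask
            Mw = np.einsum("mk,mkj,mkl->mjl", omega, w, w)
            lam_w, vec_w = np.linalg.eigh(Mw)
            n_new = vec_w[:, :, 0]
            flip = np.einsum("mj,mj->m", n_new, n) < 0
            n_new[flip] = -n_new[flip]
            cosang = np.clip(np.abs(np.einsum("mj,mj->m", n_new, n)), 0.0, 1.0)
            moved = np.arccos(cosang) >= 1e-4
            n = np.where(active[:, None], n_new, n)
            active = active & moved
        # sign convention z >= 0 (ties y, then x)
        for arr in (n, n0):
            key = arr[:, 2].copy()
            tie = key == 0
            key[tie] = arr[tie, 1]
            tie &= key == 0
            key[tie] = arr[tie, 0]
            arr[key < 0] *= -1
        normals[sel] = n
        plane_normals[sel] = n0
        valid[sel] = ok
    return normals, plane_normals, mean_dist, valid


def detect_leaf_centres(
    leaf_cloud: PointCloud, params: CentreDetectionParams
) -> np.ndarray:
    """Indices of leaf-surface centre points.

    A point is a candidate iff it passes the three great-circle tests
    (plane distance, normal consistency, angular uniformity).  Candidates
    form dense bands on the interior of each lamina, so suppression links
    candidates lying within radius/2 of each other into connected chains and
    keeps the single strongest (lowest sigma') candidate per chain; the
    result is sorted ascending.
    """
    params.validate()
    n_pts = len(leaf_cloud)
    if n_pts == 0:
        return np.empty(0, dtype=np.intp)
    coords = leaf_cloud.coords
    R = params.radius
    neighbor_lists = leaf_cloud.kdtree.query_ball_point(coords, r=R, workers=-1)
    neighbor_lists = [
        np.asarray([j for j in nb if j != i], dtype=np.intp)
        for i, nb in enumerate(neighbor_lists)
    ]
    normals, plane_normals, mean_dist, valid = _batched_normals_and_tests(
        coords, neighbor_lists, params
    )
    cand = valid & (mean_dist < params.threshold1_)
    if not cand.any():
        return np.empty(0, dtype=np.intp)

    # condition (ii): mean angle to neighbour normals
    for i in np.flatnonzero(cand):
        nb = neighbor_lists[i]
        nb = nb[valid[nb]]
        if len(nb) == 0:
            cand[i] = False
            continue
        if normal_consistency(normals[i], normals[nb]) >= params.threshold2:
            cand[i] = False
    if not cand.any():
        return np.empty(0, dtype=np.intp)

    # condition (iii): angular uniformity of the projected neighbourhood
    sigma = np.full(n_pts, np.inf)
    for i in np.flatnonzero(cand):
        n = plane_normals[i]
        plane = Plane(*n, float(n @ coords[i]))
        proj = project_points_to_plane(coords[neighbor_lists[i]], plane)
        sigma[i] = angular_uniformity(proj, coords[i], plane, R,
                                      sigma_sqrt=params.sigma_sqrt)
        if sigma[i] > params.threshold3:
            cand[i] = False
    cand_idx = np.flatnonzero(cand)
    if len(cand_idx) == 0:
        return np.empty(0, dtype=np.intp)

    # chained suppression: connected components under the radius/2 linkage,
    # keep the lowest-sigma' member (ties: lowest index) of each component
    sub = PointCloud(coords=coords[cand_idx])
    pairs = sub.kdtree.query_pairs(r=R / 2.0, output_type="ndarray")
    m = len(cand_idx)
    if len(pairs):
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
        n_comp, comp = connected_components(adj, directed=False)
    else:
        n_comp, comp = m, np.arange(m)
    keep = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        best = members[np.lexsort((cand_idx[members], sigma[cand_idx[members]]))[0]]
        keep.append(cand_idx[best])
    return np.asarray(sorted(keep), dtype=np.intp)


def _knn_graph(coords: np.ndarray, k: int, max_edge: float | None = None) -> csr_matrix:
    """Symmetric kNN graph with Euclidean edge weights."""
    from scipy.spatial import cKDTree

    n = len(coords)
    kq = min(k + 1, n)
    dist, idx = cKDTree(coords).query(coords, k=kq)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    rows = np.repeat(np.arange(n), kq - 1)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    good = np.isfinite(vals)
    if max_edge is not None:
        good &= vals <= max_edge
    g = csr_matrix((vals[good], (rows[good], cols[good])), shape=(n, n))
    return g.maximum(g.T)


def mean_nn_spacing(coords: np.ndarray) -> float:
    """Mean distance to the nearest neighbour (0 for < 2 points)."""
    from scipy.spatial import cKDTree

    if len(coords) < 2:
        return 0.0
    d, _ = cKDTree(coords).query(coords, k=2)
    return float(d[:, 1].mean())


def segment_leaves(
    leaf_cloud: PointCloud,
    centres: np.ndarray,
    params: SegmentationParams,
) -> PointCloud:
    """Assign a leaf instance id to every point (-1 = noise).

    Seeded region growing: multi-source shortest-path expansion from the
    centre seeds over the kNN graph, each point claimed by its geodesically
    nearest seed within the cap.  Points no seed reaches are clustered with
    DBSCAN; clusters of >= min_leaf_points become additional instances,
    smaller clusters and DBSCAN noise get id -1.
    """
    n = len(leaf_cloud)
    leaf_id = np.full(n, -1, dtype=np.int32)
    if n == 0:
        return PointCloud(coords=leaf_cloud.coords.copy(),
                          class_label=np.full(0, LEAF, dtype=np.int32),
                          leaf_id=leaf_id)
    centres = np.asarray(sorted(np.asarray(centres, dtype=np.intp)))
    next_id = 0
    unreached = np.ones(n, dtype=bool)
    if len(centres):
        # capping edge lengths keeps sparse off-surface chains (e.g. stray
        # twig points) from being pulled into a lamina's geodesic basin
        max_edge = params.edge_cap_factor * mean_nn_spacing(leaf_cloud.coords)
        graph = _knn_graph(leaf_cloud.coords, k=params.knn_k, max_edge=max_edge)
        dist, _, sources = dijkstra(
            graph, directed=False, indices=centres,
            limit=params.geodesic_cap, min_only=True, return_predecessors=True,
        )
        reached = np.isfinite(dist)
        seed_rank = {int(c): i for i, c in enumerate(centres)}
        leaf_id[reached] = np.array(
            [seed_rank[int(s)] for s in sources[reached]], dtype=np.int32
        )
        unreached = ~reached
        next_id = len(centres)
    if unreached.any():
        pts = leaf_cloud.coords[unreached]
        eps = params.dbscan_eps
        if eps is None:
            # a 2-spacing ball on a surface holds ~3-5 points, below
            # dbscan_min_pts; 4 spacings hold ~20 and cluster reliably
            eps = 4.0 * mean_nn_spacing(leaf_cloud.coords)
        if eps > 0 and len(pts) >= 2:
            labels = DBSCAN(eps=eps, min_samples=params.dbscan_min_pts).fit_predict(pts)
            ids = np.full(len(pts), -1, dtype=np.int32)
            for lab in np.unique(labels):
                if lab < 0:
                    continue
                members = labels == lab
                if members.sum() >= params.min_leaf_points:
                    ids[members] = next_id
                    next_id += 1
            leaf_id[unreached] = ids
    return PointCloud(
        coords=leaf_cloud.coords.copy(),
        class_label=np.full(n, LEAF, dtype=np.int32),
        leaf_id=leaf_id,
        source_path=leaf_cloud.source_path,
    )
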