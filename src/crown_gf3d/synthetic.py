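"""Synthetic TLS-like trees with analytic ground truth.

The generator emulates a terrestrial-laser scan of a small sapling: a
slender trunk, a recursive network of tapering twig cylinders inside a
spheroidal crown envelope, and parametric leaves attached along the
terminal twigs.  Every emitted point carries a ground-truth wood/leaf label
and leaf instance id, and the generator also reports analytic reference
volumes so the whole pipeline can be validated without field data.

A leaf lamina is sampled on the parametric surface (u, v) in [0,1]^2:

* planform: elliptic (semi-axes length/2, width/2) or fan-shaped (annular
  sector, ginkgo-like);
* out-of-plane bowing ``curl_amplitude * (2u - 1)^2`` along the local
  normal (u runs along the midrib);
* the distal half (u > 1/2) rotated downward by ``droop_angle`` about the
  mid-width axis;
* i.i.d. Gaussian coordinate noise of sd ``noise_sd``.

The reference (``true``) per-leaf volume applies the *same* hexagon-prism
definitions as the modelling stage to a dense noiseless sampling of the
surface, so pipeline-vs-truth comparisons isolate segmentation and fitting
error rather than model mismatch.  Occlusion is not simulated; sparse-data
robustness is exercised by lowering the sampling density instead.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import ConvexHull

from . import leafgeom
from .io import LEAF, WOOD, PointCloud


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLeafSpec:
    length: float = 0.045
    width: float = 0.025
    curl_amplitude: float = 0.003
    droop_angle: float = math.radians(12.0)
    attachment_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zenith: float = math.radians(60.0)   # midrib direction from vertical
    azimuth: float = 0.0
    shape: str = "elliptic"              # elliptic | fan

    def validate(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("leaf length and width must be positive")
        if self.curl_amplitude < 0:
            raise ValueError("curl_amplitude must be >= 0")
        if not 0 <= self.droop_angle < math.pi / 2:
            raise ValueError("droop_angle must be in [0, pi/2)")
        if self.shape not in ("elliptic", "fan"):
            raise ValueError(f"unknown leaf shape {self.shape!r}")


@dataclass
class BranchRecursion:
    depth: int = 3
    children: int = 3
    angle_range: tuple[float, float] = (math.radians(35.0), math.radians(55.0))
    initial_length: float = 0.18
    length_taper: float = 0.65
    radius_taper: float = 0.7


@dataclass
class CrownEnvelope:
    kind: str = "spheroid"               # spheroid | cone | cylinder
    semi_axes: tuple[float, float, float] = (0.4, 0.4, 0.3)
    centre_height: float = 0.7           # z of the envelope centre (m)

    def contains(self, p: np.ndarray) -> bool:
        a, b, c = self.semi_axes
        dx, dy, dz = p[0], p[1], p[2] - self.centre_height
        if self.kind == "spheroid":
            return (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
        if self.kind == "cylinder":
            return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0 and abs(dz) <= c
        if self.kind == "cone":  # apex up
            if not -c <= dz <= c:
                return False
            shrink = (c - dz) / (2.0 * c)
            return (dx / a) ** 2 + (dy / b) ** 2 <= shrink**2
        raise ValueError(f"unknown envelope kind {self.kind!r}")


@dataclass
class SyntheticTreeSpec:
    """Default values are the package's scaled study conditions: a ~1 m
    sapling with slender twigs and a few dozen leaves, dense enough that
    every leaf carries well over 40 points."""

    n_leaves: int = 50
    leaf_length_range: tuple[float, float] = (0.03, 0.042)
    leaf_width_range: tuple[float, float] = (0.018, 0.026)
    curl_range: tuple[float, float] = (0.001, 0.005)
    droop_range: tuple[float, float] = (math.radians(5.0), math.radians(20.0))
    leaf_shape: str = "elliptic"
    branch: BranchRecursion = field(default_factory=BranchRecursion)
    trunk_height: float = 0.5
    trunk_radius: float = 0.0008
    envelope: CrownEnvelope = field(default_factory=CrownEnvelope)
    sampling_density: float = 5.0e5      # points per m^2 of surface
    noise_sd: float = 0.0005
    seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")
        if self.sampling_density <= 0:
            raise ValueError("sampling_density must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trunk_height <= 0 or self.trunk_radius <= 0:
            raise ValueError("trunk dimensions must be positive")
        if self.leaf_length_range[1] > min(self.envelope.semi_axes):
            raise ValueError(
                "infeasible geometry: leaves larger than the crown envelope"
            )

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTreeSpec":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "branch" in d and isinstance(d["branch"], dict):
            d["branch"] = BranchRecursion(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["branch"].items()
            })
        if "envelope" in d and isinstance(d["envelope"], dict):
            d["envelope"] = CrownEnvelope(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["envelope"].items()
            })
        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tuple(val)
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class LeafTruth:
    """Analytic reference geometry of one generated leaf."""

    thickness: float
    volume: float
    hexagon: np.ndarray
    normal: np.ndarray
    planform_area: float


@dataclass
class GroundTruth:
    class_label: np.ndarray
    leaf_id: np.ndarray
    leaf_volumes: np.ndarray             # per-leaf hexagon-prism volumes
    leaf_thicknesses: np.ndarray
    wood_volume: float                   # sum of generating cylinder volumes
    crown_volume: float                  # hull of the noiseless vegetative geometry
    crown_base_height: float
    gf_vol: float

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "class_label": self.class_label.tolist(),
            "leaf_id": self.leaf_id.tolist(),
            "leaf_volumes_m3": self.leaf_volumes.tolist(),
            "leaf_thicknesses_m": self.leaf_thicknesses.tolist(),
            "wood_volume_m3": self.wood_volume,
            "crown_volume_m3": self.crown_volume,
            "crown_base_height_m": self.crown_base_height,
            "gf_vol": self.gf_vol,
        }
        text = json.dumps(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Leaf surface
# ---------------------------------------------------------------------------

def _leaf_rotation(zenith: float, azimuth: float) -> np.ndarray:
    """Rotation taking the local midrib (+x) to zenith/azimuth direction."""
    a = zenith - math.pi / 2.0
    ry = np.array([
        [math.cos(a), 0.0, math.sin(a)],
        [0.0, 1.0, 0.0],
        [-math.sin(a), 0.0, math.cos(a)],
    ])
    rz = np.array([
        [math.cos(azimuth), -math.sin(azimuth), 0.0],
        [math.sin(azimuth), math.cos(azimuth), 0.0],
        [0.0, 0.0, 1.0],
    ])
    return rz @ ry


def _lamina_to_world(xy: np.ndarray, spec: SyntheticLeafSpec) -> np.ndarray:
    """Apply curl, droop, orientation and attachment to planform samples."""
    L = spec.length
    x, y = xy[:, 0], xy[:, 1]
    u = np.clip(x / L, 0.0, 1.0)
    z = spec.curl_amplitude * (2.0 * u - 1.0) ** 2
    pts = np.column_stack([x, y, z])
    if spec.droop_angle > 0:
        distal = x > L / 2.0
        th = spec.droop_angle
        dx = pts[distal, 0] - L / 2.0
        dz = pts[distal, 2]
        pts[distal, 0] = L / 2.0 + dx * math.cos(th) + dz * math.sin(th)
        pts[distal, 2] = -dx * math.sin(th) + dz * math.cos(th)
    R = _leaf_rotation(spec.zenith, spec.azimuth)
    return pts @ R.T + np.asarray(spec.attachment_point, dtype=np.float64)


def _planform_area(spec: SyntheticLeafSpec) -> float:
    if spec.shape == "elliptic":
        return math.pi * (spec.length / 2.0) * (spec.width / 2.0)
    phi = math.asin(min(spec.width / (2.0 * spec.length), 1.0))
    return phi * spec.length**2


def _sample_planform(spec: SyntheticLeafSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random samples of the planform in the local (x, y) frame."""
    if spec.shape == "elliptic":
        r = np.sqrt(rng.uniform(0.0, 1.0, n))
        beta = rng.uniform(0.0, 2.0 * math.pi, n)
        x = spec.length / 2.0 + (spec.length / 2.0) * r * np.cos(beta)
        y = (spec.width / 2.0) * r * np.sin(beta)
    else:  # fan: annular sector with apex at the petiole
        phi = math.asin(min(spec.width / (2.0 * spec.length), 1.0))
        rho = spec.length * np.sqrt(rng.uniform(0.0, 1.0, n))
        alpha = rng.uniform(-phi, phi, n)
        x = rho * np.cos(alpha)
        y = rho * np.sin(alpha)
    return np.column_stack([x, y])


def _dense_planform_grid(spec: SyntheticLeafSpec) -> np.ndarray:
    """Deterministic, sampling-independent cover of the planform.

    Area-uniform interior grid plus the boundary ring and the midrib line,
    so the thickness extremes (u = 0, 1/2, 1) are hit exactly.
    """
    n_r, n_b = 24, 64
    if spec.shape == "elliptic":
        r = np.sqrt((np.arange(n_r) + 0.5) / n_r)
        beta = (np.arange(n_b) + 0.5) * 2.0 * math.pi / n_b
        rr, bb = np.meshgrid(r, beta, indexing="ij")
        x = spec.length / 2.0 + (spec.length / 2.0) * rr * np.cos(bb)
        y = (spec.width / 2.0) * rr * np.sin(bb)
        ring_b = np.linspace(0.0, 2.0 * math.pi, n_b, endpoint=False)
        ring_x = spec.length / 2.0 + (spec.length / 2.0) * np.cos(ring_b)
        ring_y = (spec.width / 2.0) * np.sin(ring_b)
    else:
        phi = math.asin(min(spec.width / (2.0 * spec.length), 1.0))
        rho = spec.length * np.sqrt((np.arange(n_r) + 0.5) / n_r)
        alpha = np.linspace(-phi, phi, 17)
        rr, aa = np.meshgrid(rho, alpha, indexing="ij")
        x = rr * np.cos(aa)
        y = rr * np.sin(aa)
        ring_a = np.linspace(-phi, phi, 33)
        ring_x = np.concatenate([spec.length * np.cos(ring_a), [0.0]])
        ring_y = np.concatenate([spec.length * np.sin(ring_a), [0.0]])
    mid_x = np.linspace(0.0, spec.length, 41)  # includes u = 0, 1/2, 1
    mid_y = np.zeros_like(mid_x)
    if spec.shape == "fan":  # midrib only spans the sector radially
        pass
    return np.column_stack([
        np.concatenate([x.ravel(), ring_x, mid_x]),
        np.concatenate([y.ravel(), ring_y, mid_y]),
    ])


def _leaf_truth(spec: SyntheticLeafSpec) -> LeafTruth:
    """Reference hexagon-prism model from the dense noiseless surface."""
    grid = _lamina_to_world(_dense_planform_grid(spec), spec)
    normal = leafgeom.leaf_normal(grid)
    thickness = leafgeom.equivalent_thickness(grid, normal)
    p_e, p_s = leafgeom.find_midrib_endpoints(grid)
    left_raw, right_raw, _ = leafgeom.slice_edge_points(grid, p_e, p_s, 21, normal=normal)
    left, _ = leafgeom.fit_edge_cubic(left_raw, p_e, p_s, normal)
    right, _ = leafgeom.fit_edge_cubic(right_raw, p_e, p_s, normal)
    hexv = leafgeom.hexagon_vertices(p_e, p_s, left, right)
    volume = leafgeom.hexagonal_prism_volume(hexv, thickness)
    return LeafTruth(thickness=thickness, volume=volume, hexagon=hexv,
                     normal=normal, planform_area=_planform_area(spec))


def generate_leaf(
    spec: SyntheticLeafSpec,
    density: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> tuple[PointCloud, LeafTruth]:
    """Sample one leaf surface; returns (noisy cloud, analytic truth)."""
    spec.validate()
    if density <= 0:
        raise ValueError("density must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(density * _planform_area(spec)))
    if n < 3:
        raise ValueError(
            f"sampling density {density} yields only {n} points on this leaf"
        )
    pts = _lamina_to_world(_sample_planform(spec, n, rng), spec)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    cloud = PointCloud(
        coords=pts,
        class_label=np.full(n, LEAF, dtype=np.int32),
        leaf_id=np.zeros(n, dtype=np.int32),
    )
    return cloud, _leaf_truth(spec)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * (axis @ v) * (1.0 - math.cos(angle))
    )


def _grow_branches(
    spec: SyntheticTreeSpec, rng: np.random.Generator
) -> tuple[list[tuple[np.ndarray, np.ndarray, float]], list[int]]:
    """Recursive cylinder placement; returns (segments, terminal indices)."""
    br = spec.branch
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    terminals: list[int] = []
    trunk_top = np.array([0.0, 0.0, spec.trunk_height])
    segments.append((np.zeros(3), trunk_top, spec.trunk_radius))

    def grow(start: np.ndarray, direction: np.ndarray, length: float,
             radius: float, depth: int) -> None:
        end = start + direction * length
        # shrink branches that would leave the crown envelope
        scale = 1.0
        while scale > 0.35 and not spec.envelope.contains(start + direction * length * scale):
            scale *= 0.8
        end = start + direction * length * scale
        idx = len(segments)
        segments.append((start.copy(), end, radius))
        if depth >= br.depth:
            terminals.append(idx)
            return
        for _ in range(br.children):
            ang = rng.uniform(*br.angle_range)
            az = rng.uniform(0.0, 2.0 * math.pi)
            perp = np.cross(direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.array([1.0, 0.0, 0.0])
            perp = _rotate_about(perp / np.linalg.norm(perp), direction, az)
            child_dir = _rotate_about(direction, perp, ang)
            child_dir = child_dir / np.linalg.norm(child_dir)
            grow(end, child_dir, length * br.length_taper,
                 radius * br.radius_taper, depth + 1)

    for _ in range(br.children):
        ang = rng.uniform(*br.angle_range)
        az = rng.uniform(0.0, 2.0 * math.pi)
        d = np.array([math.sin(ang) * math.cos(az),
                      math.sin(ang) * math.sin(az),
                      math.cos(ang)])
        grow(trunk_top, d, br.initial_length,
             spec.trunk_radius * br.radius_taper, 1)
    return segments, terminals


def _sample_cylinder(
    start: np.ndarray, end: np.ndarray, radius: float,
    n: int, rng: np.random.Generator,
) -> np.ndarray:
    axis = end - start
    length = np.linalg.norm(axis)
    d = axis / length
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    b1 = np.cross(d, ref)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(d, b1)
    t = rng.uniform(0.0, length, n)
    psi = rng.uniform(0.0, 2.0 * math.pi, n)
    return (start + np.outer(t, d)
            + radius * (np.outer(np.cos(psi), b1) + np.outer(np.sin(psi), b2)))


def _cylinder_grid(start: np.ndarray, end: np.ndarray, radius: float) -> np.ndarray:
    """Small deterministic surface grid (for the truth crown hull)."""
    axis = end - start
    length = np.linalg.norm(axis)
    d = axis / length
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    b1 = np.cross(d, ref)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(d, b1)
    t = np.linspace(0.0, length, 9)
    psi = np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False)
    tt, pp = np.meshgrid(t, psi, indexing="ij")
    return (start + np.outer(tt.ravel(), d)
            + radius * (np.outer(np.cos(pp.ravel()), b1)
                        + np.outer(np.sin(pp.ravel()), b2)))


def generate_tree(spec: SyntheticTreeSpec) -> tuple[PointCloud, GroundTruth]:
    """Generate a labelled TLS-like sapling cloud and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    segments, terminals = _grow_branches(spec, rng)

    # leaves cycle over terminal twigs, spaced along each twig
    leaf_specs: list[SyntheticLeafSpec] = []
    if spec.n_leaves > 0:
        if not terminals:
            raise ValueError("no terminal branch segments to attach leaves to")
        per_twig = int(math.ceil(spec.n_leaves / len(terminals)))
        slots = [(t, s) for s in range(per_twig) for t in terminals]
        for i in range(spec.n_leaves):
            t_idx, slot = slots[i]
            start, end, _ = segments[t_idx]
            frac = (slot + 1.0) / (per_twig + 1.0)
            attach = start + (end - start) * frac
            # midribs point radially outward (with jitter) so neighbouring
            # laminae fan apart instead of interpenetrating
            radial = math.hypot(attach[0], attach[1])
            if radial > 1e-6:
                az_out = math.atan2(attach[1], attach[0])
            else:
                az_out = rng.uniform(0.0, 2.0 * math.pi)
            zen = rng.uniform(math.radians(45.0), math.radians(75.0))
            # alternate leaves left/right of the twig (distichous phyllotaxis)
            side = 0.6 if slot % 2 == 0 else -0.6
            az = az_out + side + rng.uniform(-0.3, 0.3)
            midrib = np.array([math.sin(zen) * math.cos(az),
                               math.sin(zen) * math.sin(az),
                               math.cos(zen)])
            # short petiole stand-off keeps the lamina clear of its twig
            attach = attach + 0.01 * midrib
            leaf_specs.append(SyntheticLeafSpec(
                length=rng.uniform(*spec.leaf_length_range),
                width=rng.uniform(*spec.leaf_width_range),
                curl_amplitude=rng.uniform(*spec.curl_range),
                droop_angle=rng.uniform(*spec.droop_range),
                attachment_point=tuple(attach),
                zenith=zen,
                azimuth=az,
                shape=spec.leaf_shape,
            ))

    coords_parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    leaf_ids: list[np.ndarray] = []
    truth_hull_parts: list[np.ndarray] = []

    wood_volume = 0.0
    for start, end, radius in segments:
        length = float(np.linalg.norm(end - start))
        wood_volume += math.pi * radius**2 * length
        n = int(round(spec.sampling_density * 2.0 * math.pi * radius * length))
        if n > 0:
            pts = _sample_cylinder(start, end, radius, n, rng)
            coords_parts.append(pts)
            labels.append(np.full(n, WOOD, dtype=np.int32))
            leaf_ids.append(np.full(n, -1, dtype=np.int32))
        truth_hull_parts.append(_cylinder_grid(start, end, radius))

    leaf_volumes = np.zeros(len(leaf_specs))
    leaf_thicknesses = np.zeros(len(leaf_specs))
    for lid, lspec in enumerate(leaf_specs):
        cloud_i, truth_i = generate_leaf(lspec, spec.sampling_density, 0.0, rng)
        coords_parts.append(cloud_i.coords)
        labels.append(np.full(len(cloud_i), LEAF, dtype=np.int32))
        leaf_ids.append(np.full(len(cloud_i), lid, dtype=np.int32))
        leaf_volumes[lid] = truth_i.volume
        leaf_thicknesses[lid] = truth_i.thickness
        truth_hull_parts.append(_lamina_to_world(_dense_planform_grid(lspec), lspec))

    coords = np.vstack(coords_parts) if coords_parts else np.empty((0, 3))
    class_label = np.concatenate(labels) if labels else np.empty(0, dtype=np.int32)
    leaf_id = np.concatenate(leaf_ids) if leaf_ids else np.empty(0, dtype=np.int32)
    if spec.noise_sd > 0 and len(coords):
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    crown_base = spec.trunk_height  # branches (and leaves) start at the trunk top
    hull_pts = np.vstack(truth_hull_parts)
    hull_pts = hull_pts[hull_pts[:, 2] >= crown_base]
    if len(hull_pts) >= 4:
        crown_vol = float(ConvexHull(hull_pts).volume)
    else:
        crown_vol = 0.0
    elements = float(leaf_volumes.sum()) + wood_volume
    gf_vol = 1.0 - elements / crown_vol if crown_vol > 0 else float("nan")

    cloud = PointCloud(coords=coords, class_label=class_label, leaf_id=leaf_id)
    truth = GroundTruth(
        class_label=class_label.copy(),
        leaf_id=leaf_id.copy(),
        leaf_volumes=leaf_volumes,
        leaf_thicknesses=leaf_thicknesses,
        wood_volume=wood_volume,
        crown_volume=crown_vol,
        crown_base_height=crown_base,
        gf_vol=gf_vol,
    )
    return cloud, truth
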