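"""Volume-based gap fraction and comparison estimators.

The crown is treated as a porous medium: leaves and branch segments are the
solid matrix, the space between them the pores.  The volume-based gap
fraction is then the void fraction

    GF_vol = 1 - (sum_t V_leaf_t + sum_u V_branch_u) / V_canopy

with per-leaf hexagonal-prism volumes, per-segment cylinder volumes and the
alpha-shape crown volume.  Three conventional estimators are provided for
comparison: the hemispherical-photo sky-pixel fraction per zenith ring
(GF_img), the voxel-occupancy gap fraction, and the Beer-Lambert
transmission P(theta) = exp(-G(theta) * Omega * LAI / cos theta).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import structure
from .config import PipelineConfig
from .io import LEAF, WOOD, PointCloud, read_point_cloud
from .leafgeom import LeafModel, model_leaf
from .segmentation import (
    CentreDetectionParams,
    SegmentationParams,
    detect_leaf_centres,
    segment_leaves,
)
from .woodleaf import classify_wood_leaf

logger = logging.getLogger("crown_gf3d")


@dataclass
class BeerLambertParams:
    G: float = 0.5        # extinction coefficient
    Omega: float = 1.0    # clumping index
    LAI: float = 0.0
    theta: float = 0.0    # zenith angle (rad)

    def validate(self) -> None:
        if self.G <= 0:
            raise ValueError("G must be positive")
        if not 0 < self.Omega <= 1:
            raise ValueError("Omega must be in (0, 1]")
        if self.LAI < 0:
            raise ValueError("LAI must be >= 0")
        if not 0 <= self.theta < math.pi / 2:
            raise ValueError("theta must be in [0, pi/2)")


@dataclass
class GapFractionReport:
    gf_vol: float
    total_leaf_volume: float
    total_wood_volume: float
    crown_volume: float
    crown_base_height: float
    n_leaves: int
    n_cylinders: int
    gf_img_per_ring: list[dict] = field(default_factory=list)
    gf_voxel: float | None = None
    gf_light: list[dict] = field(default_factory=list)
    n_points: int = 0
    n_leaf_points: int = 0
    n_wood_points: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gf_vol": self.gf_vol,
            "total_leaf_volume_m3": self.total_leaf_volume,
            "total_wood_volume_m3": self.total_wood_volume,
            "crown_volume_m3": self.crown_volume,
            "crown_base_height_m": self.crown_base_height,
            "n_leaves": self.n_leaves,
            "n_cylinders": self.n_cylinders,
            "gf_img_per_ring": self.gf_img_per_ring,
            "gf_voxel": self.gf_voxel,
            "gf_light": self.gf_light,
            "n_points": self.n_points,
            "n_leaf_points": self.n_leaf_points,
            "n_wood_points": self.n_wood_points,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_gf_vol(
    total_leaf_volume: float,
    total_wood_volume: float,
    crown_volume: float,
    warnings: list[str] | None = None,
) -> float:
    """GF_vol = 1 - (sum V_leaf + sum V_branch) / V_canopy.

    A result outside [0, 1] (overlapping prisms exceeding the crown, or a
    hull smaller than its elements) is returned as computed, with a warning
    recorded, so pathological geometry stays visible.
    """
    if crown_volume <= 0:
        raise ValueError("crown volume must be positive")
    if total_leaf_volume < 0 or total_wood_volume < 0:
        raise ValueError("component volumes must be >= 0")
    gf = 1.0 - (total_leaf_volume + total_wood_volume) / crown_volume
    if not 0.0 <= gf <= 1.0 and warnings is not None:
        warnings.append(f"GF_vol outside [0, 1]: {gf:.6f}")
    return gf


def beer_lambert_gf(params: BeerLambertParams) -> float:
    """Canopy transmission P(theta) = exp(-G(theta) Omega LAI / cos theta)."""
    params.validate()
    return math.exp(-params.G * params.Omega * params.LAI / math.cos(params.theta))


# ---------------------------------------------------------------------------
# Hemispherical-photo baseline
# ---------------------------------------------------------------------------

def _hemisphere_pixel_zenith(image_size: int, equal_area: bool) -> np.ndarray:
    """Per-pixel zenith angle (rad) of the synthetic hemispherical image.

    NaN outside the projected hemisphere disk.
    """
    half = image_size / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    rho = np.hypot(xx + 0.5 - half, yy + 0.5 - half) / half  # 0..1 disk
    theta = np.full(rho.shape, np.nan)
    inside = rho <= 1.0
    if equal_area:  # rho = sqrt(2) sin(theta/2), normalised to 1 at 90 deg
        theta[inside] = 2.0 * np.arcsin(np.clip(rho[inside] / math.sqrt(2.0), 0, 1))
    else:  # equal-angle: rho proportional to theta
        theta[inside] = rho[inside] * (math.pi / 2.0)
    return theta


def hemispherical_gf(
    cloud: PointCloud,
    observer: np.ndarray,
    image_size: int = 1024,
    ring_edges_deg: list[tuple[float, float]] | None = None,
    point_footprint_deg: float = 0.15,
    equal_area: bool = True,
) -> list[dict]:
    """Sky fraction per zenith ring of a synthetic hemispherical photo.

    Points above the observer are mapped by zenith/azimuth to Lambert
    azimuthal image coordinates (equal-area by default, equal-angle
    optionally) and splatted as disks of the given angular radius; per ring,
    GF_img = sky pixels / total ring pixels.  The conventional 57.3 deg
    reporting ring corresponds to edges (52.3, 62.3).
    """
    if image_size < 256:
        raise ValueError("image_size must be >= 256")
    if ring_edges_deg is None:
        ring_edges_deg = [(52.3, 62.3)]
    observer = np.asarray(observer, dtype=np.float64)
    half = image_size / 2.0
    covered = np.zeros((image_size, image_size), dtype=bool)

    rel = cloud.coords - observer
    above = rel[:, 2] > 0
    rel = rel[above]
    if len(rel):
        r_xy = np.hypot(rel[:, 0], rel[:, 1])
        theta = np.arctan2(r_xy, rel[:, 2])
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        if equal_area:
            rho = math.sqrt(2.0) * np.sin(theta / 2.0)
            drho_dtheta = math.sqrt(2.0) * np.cos(theta / 2.0) / 2.0
        else:
            rho = theta / (math.pi / 2.0)
            drho_dtheta = np.full_like(theta, 1.0 / (math.pi / 2.0))
        px = half + rho * np.cos(phi) * half
        py = half + rho * np.sin(phi) * half
        pix_rad = np.maximum(
            1, np.rint(math.radians(point_footprint_deg) * drho_dtheta * half).astype(int)
        )
        for rad in np.unique(pix_rad):
            sel = pix_rad == rad
            ix = np.clip(px[sel].astype(int), 0, image_size - 1)
            iy = np.clip(py[sel].astype(int), 0, image_size - 1)
            stamp = np.zeros_like(covered)
            stamp[iy, ix] = True
            if rad > 0:
                from scipy.ndimage import binary_dilation

                r = int(rad)
                yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
                disk = xx**2 + yy**2 <= r**2
                stamp = binary_dilation(stamp, structure=disk)
            covered |= stamp

    theta_img = _hemisphere_pixel_zenith(image_size, equal_area)
    out = []
    for lo, hi in ring_edges_deg:
        ring = (theta_img >= math.radians(lo)) & (theta_img < math.radians(hi))
        total = int(ring.sum())
        if total == 0:
            raise ValueError(f"no pixels in zenith ring [{lo}, {hi}] deg")
        sky = int((ring & ~covered).sum())
        out.append({"zenith_deg": [lo, hi], "gf_img": sky / total})
    return out


def voxel_gap_fraction(
    cloud: PointCloud,
    voxel_size: float,
    crown_volume: float,
    warnings: list[str] | None = None,
) -> float:
    """Voxel-scale gap fraction (crown volume minus occupied voxel volume).

    The axis-aligned grid is anchored at the cloud's minimum corner; a voxel
    is occupied if it contains at least one point.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if crown_volume <= 0:
        raise ValueError("crown volume must be positive")
    if len(cloud) == 0:
        return 1.0
    # small epsilon so points an ulp below a voxel boundary land inside it
    ijk = np.floor((cloud.coords - cloud.coords.min(axis=0)) / voxel_size + 1e-9).astype(np.int64)
    n_occ = len(np.unique(ijk, axis=0))
    v_occ = n_occ * voxel_size**3
    gf = (crown_volume - v_occ) / crown_volume
    if gf < 0:
        if warnings is not None:
            warnings.append(
                f"occupied voxel volume {v_occ:.6g} exceeds crown volume; clamped to 0"
            )
        gf = 0.0
    return gf


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    cloud_or_path: PointCloud | str | Path,
    config: PipelineConfig | None = None,
    baselines: tuple[str, ...] = (),
    hp_observer: np.ndarray | None = None,
    beer_lambert: BeerLambertParams | None = None,
    return_models: bool = False,
):
    """Run classify -> segment -> model-leaves -> cylinders -> crown -> GF_vol.

    ``baselines`` may include "hp", "voxel" and "beer"; their results are
    attached to the report.  Deterministic for a given cloud and config.
    Returns the :class:`GapFractionReport` (plus intermediate models when
    ``return_models`` is set).
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if isinstance(cloud_or_path, (str, Path)):
        cloud = read_point_cloud(cloud_or_path)
    else:
        cloud = cloud_or_path
    if cfg.unit_scale != 1.0:
        cloud = PointCloud(coords=cloud.coords * cfg.unit_scale,
                           class_label=cloud.class_label, leaf_id=cloud.leaf_id)
    warnings: list[str] = []
    logger.info("pipeline start: %d points", len(cloud))

    # stage 1: wood/leaf classification
    try:
        if cfg.use_existing_labels and cloud.class_label is not None:
            labelled = cloud
        else:
            labelled = classify_wood_leaf(
                cloud, method=cfg.classify_method,
                params={"k": cfg.eigen_k, "t_lin": cfg.linearity_threshold},
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
    leaf_mask = labelled.class_label == LEAF
    wood_mask = labelled.class_label == WOOD
    leaf_cloud = labelled.subset(leaf_mask)
    wood_cloud = labelled.subset(wood_mask)
    logger.info("classified: %d leaf / %d wood points", len(leaf_cloud), len(wood_cloud))

    # stage 2: leaf-centre detection + instance segmentation
    try:
        centre_params = CentreDetectionParams(
            radius=cfg.centre_radius_, threshold1=cfg.threshold1_,
            threshold2=cfg.threshold2, threshold3=cfg.threshold3,
            min_neighbors=cfg.min_neighbors, sigma_sqrt=cfg.sigma_sqrt,
        )
        centres = detect_leaf_centres(leaf_cloud, centre_params)
        seg_params = SegmentationParams(
            knn_k=cfg.knn_graph_k, geodesic_cap=cfg.geodesic_cap_,
            dbscan_eps=cfg.dbscan_eps, dbscan_min_pts=cfg.dbscan_min_pts,
            min_leaf_points=cfg.min_leaf_points,
        )
        segmented = segment_leaves(leaf_cloud, centres, seg_params)
    except Exception as exc:
        raise RuntimeError(f"stage 'leaves' failed: {exc}") from exc
    instance_ids = np.unique(segmented.leaf_id[segmented.leaf_id >= 0])
    logger.info("segmented %d leaf instances from %d seeds",
                len(instance_ids), len(centres))

    # stage 3: per-leaf hexagon prisms
    leaf_models: list[LeafModel] = []
    total_leaf_volume = 0.0
    try:
        for lid in instance_ids:
            pts = segmented.coords[segmented.leaf_id == lid]
            m = model_leaf(pts, cfg, leaf_id=int(lid))
            leaf_models.append(m)
            total_leaf_volume += m.volume
    except Exception as exc:
        raise RuntimeError(f"stage 'model-leaves' failed: {exc}") from exc
    n_ok = sum(1 for m in leaf_models if m.quality_flag == "ok")
    logger.info("modelled %d leaves (%d hexagon, %d fallback/rejected)",
                len(leaf_models), n_ok, len(leaf_models) - n_ok)

    # stage 4: branch cylinders
    cylinders = []
    try:
        for seg in structure.segment_branch_points(
            wood_cloud, segment_length=cfg.segment_length, knn_k=cfg.knn_graph_k
        ):
            if len(seg) < 6:
                continue
            try:
                cylinders.append(structure.fit_cylinder(wood_cloud.coords[seg]))
            except ValueError:
                continue
    except Exception as exc:
        raise RuntimeError(f"stage 'cylinders' failed: {exc}") from exc
    total_wood_volume = structure.wood_volume(cylinders)
    logger.info("fitted %d branch cylinders, wood volume %.3g m^3",
                len(cylinders), total_wood_volume)

    # stage 5: crown volume and GF_vol
    try:
        base = cfg.crown_base_height
        if base is None:
            base = structure.estimate_crown_base_height(
                wood_cloud.coords, fallback=float(cloud.coords[:, 2].min()) if len(cloud) else 0.0
            )
        vegetative = labelled.subset(leaf_mask | wood_mask)
        crown = structure.crown_volume(vegetative, base, alpha=cfg.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'crown' failed: {exc}") from exc
    gf_vol = compute_gf_vol(total_leaf_volume, total_wood_volume, crown.volume, warnings)
    logger.info("crown volume %.3g m^3, GF_vol %.4f", crown.volume, gf_vol)

    report = GapFractionReport(
        gf_vol=gf_vol,
        total_leaf_volume=total_leaf_volume,
        total_wood_volume=total_wood_volume,
        crown_volume=crown.volume,
        crown_base_height=crown.crown_base_height,
        n_leaves=len(leaf_models),
        n_cylinders=len(cylinders),
        n_points=len(cloud),
        n_leaf_points=int(leaf_mask.sum()),
        n_wood_points=int(wood_mask.sum()),
        warnings=warnings,
    )

    if "hp" in baselines:
        obs = hp_observer
        if obs is None:
            obs = np.array([*np.median(cloud.coords[:, :2], axis=0),
                            float(cloud.coords[:, 2].min())])
        report.gf_img_per_ring = hemispherical_gf(
            labelled, obs, image_size=cfg.hp_image_size,
            ring_edges_deg=[tuple(cfg.hp_ring_edges_deg)],
            point_footprint_deg=cfg.hp_point_footprint_deg,
            equal_area=cfg.hp_equal_area,
        )
    if "voxel" in baselines:
        report.gf_voxel = voxel_gap_fraction(
            crown_cloud_from(crown), cfg.voxel_size, crown.volume, warnings
        )
    if "beer" in baselines and beer_lambert is not None:
        report.gf_light = [{
            "theta_deg": math.degrees(beer_lambert.theta),
            "p_theta": beer_lambert_gf(beer_lambert),
        }]
    if return_models:
        return report, {"leaf_models": leaf_models, "cylinders": cylinders,
                        "crown": crown, "segmented": segmented}
    return report


def crown_cloud_from(crown: structure.CrownModel) -> PointCloud:
    return PointCloud(coords=crown.crown_points)
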