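"""Pipeline configuration.

Every constant the method leaves open (neighbourhood sizes, detection
thresholds, slice counts, voxel size, ...) lives here so it is visible,
serialisable and overridable.  Units are metres and radians throughout;
inputs in other units must be rescaled via ``unit_scale``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable parameters of the GF_vol pipeline.

    Species priors (``leaf_length`` / ``leaf_width``) mirror the use of
    per-species field measurements: the leaf-centre detection radius and the
    geodesic growing cap are derived from them rather than estimated from the
    data being processed.
    """

    # species priors (metres)
    leaf_length: float = 0.036
    leaf_width: float = 0.022

    # wood/leaf classification
    eigen_k: int = 20               # kNN neighbourhood for covariance features
    linearity_threshold: float = 0.8  # wood iff linearity > this (threshold method)
    classify_method: str = "threshold"

    # leaf-centre detection; radius defaults to 0.75 * (leaf_width / 2)
    centre_radius: float | None = None
    threshold1: float | None = None   # mean point-to-plane distance bound (m); default 0.2*radius
    threshold2: float = math.radians(15.0)  # mean normal-angle bound (rad)
    threshold3: float = 2.0           # bound on the dispersion statistic sigma'
    min_neighbors: int = 40
    sigma_sqrt: bool = False          # report sqrt of the dispersion index instead

    # instance segmentation
    knn_graph_k: int = 10
    dbscan_min_pts: int = 10
    dbscan_eps: float | None = None   # default 4 * mean nearest-neighbour spacing
    min_leaf_points: int = 40

    # leaf modelling
    mls_support_radius: float | None = None  # default leaf_width / 4
    mls_degree: int = 2
    n_slices: int = 21                # yields n-1 = 20 edge points per side

    # branches and crown
    segment_length: float = 0.05
    alpha: float = math.inf           # inf => convex hull
    crown_base_height: float | None = None  # None => auto (lowest branch rule)

    # baselines
    voxel_size: float = 0.1
    hp_image_size: int = 1024
    hp_point_footprint_deg: float = 0.15
    hp_equal_area: bool = True
    hp_ring_edges_deg: tuple[float, float] = (52.3, 62.3)  # 57.3 deg convention

    # misc
    unit_scale: float = 1.0
    seed: int = 0
    use_existing_labels: bool = False  # reuse class_label already on the cloud
    schema_version: int = CONFIG_SCHEMA_VERSION

    # -- derived defaults --------------------------------------------------
    @property
    def centre_radius_(self) -> float:
        if self.centre_radius is not None:
            return self.centre_radius
        return 0.75 * (self.leaf_width / 2.0)

    @property
    def threshold1_(self) -> float:
        return self.threshold1 if self.threshold1 is not None else 0.2 * self.centre_radius_

    @property
    def mls_support_radius_(self) -> float:
        if self.mls_support_radius is not None:
            return self.mls_support_radius
        return self.leaf_width / 4.0

    @property
    def geodesic_cap_(self) -> float:
        return 2.0 * self.leaf_length

    def validate(self) -> None:
        positive = [
            ("leaf_length", self.leaf_length),
            ("leaf_width", self.leaf_width),
            ("centre_radius", self.centre_radius_),
            ("threshold1", self.threshold1_),
            ("threshold2", self.threshold2),
            ("threshold3", self.threshold3),
            ("mls_support_radius", self.mls_support_radius_),
            ("segment_length", self.segment_length),
            ("voxel_size", self.voxel_size),
            ("unit_scale", self.unit_scale),
            ("alpha", self.alpha),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"config field {name} must be positive, got {value}")
        if self.eigen_k < 3:
            raise ValueError("eigen_k must be >= 3")
        if self.n_slices < 4:
            raise ValueError("n_slices must be >= 4")
        if self.mls_degree not in (1, 2):
            raise ValueError("mls_degree must be 1 or 2")
        if self.classify_method not in ("threshold", "gaussian", "svm"):
            raise ValueError(f"unknown classify_method {self.classify_method!r}")
        if self.hp_image_size < 256:
            raise ValueError("hp_image_size must be >= 256")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hp_ring_edges_deg"] = list(self.hp_ring_edges_deg)
        d["alpha"] = "inf" if math.isinf(self.alpha) else self.alpha
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "alpha" in d and d["alpha"] in ("inf", ".inf", None):
            d["alpha"] = math.inf
        if "hp_ring_edges_deg" in d and d["hp_ring_edges_deg"] is not None:
            d["hp_ring_edges_deg"] = tuple(d["hp_ring_edges_deg"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        return cls.from_dict(data)
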