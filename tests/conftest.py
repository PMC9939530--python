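"""Shared fixtures: small geometric fixtures and cached synthetic-tree runs."""

from __future__ import annotations

import math

import numpy as np
import pytest

import crown_gf3d as cg


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so stochastic
    # assertions cannot depend on test execution order
    return np.random.default_rng(12345)


def make_cylinder_points(
    radius: float, length: float, n: int, noise_sd: float = 0.0, seed: int = 0,
    axis: np.ndarray | None = None,
) -> np.ndarray:
    """Points on a cylinder surface along +z (or ``axis``)."""
    r = np.random.default_rng(seed)
    t = r.uniform(0.0, length, n)
    psi = r.uniform(0.0, 2.0 * math.pi, n)
    pts = np.column_stack([radius * np.cos(psi), radius * np.sin(psi), t])
    if axis is not None:
        axis = axis / np.linalg.norm(axis)
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        b1 = np.cross(axis, ref)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(axis, b1)
        pts = pts[:, 0:1] * b1 + pts[:, 1:2] * b2 + pts[:, 2:3] * axis
    if noise_sd > 0:
        pts = pts + r.normal(0.0, noise_sd, pts.shape)
    return pts


@pytest.fixture(scope="session")
def flat_leaf_cloud():
    """Dense noiseless roundish flat leaf with its known lamina centroid."""
    spec = cg.SyntheticLeafSpec(
        length=0.03, width=0.03, curl_amplitude=0.0, droop_angle=0.0,
        zenith=math.radians(90.0), azimuth=0.0,
    )
    cloud, truth = cg.generate_leaf(spec, 8.0e5, 0.0, seed=5)
    centroid = np.asarray(spec.attachment_point) + np.array([spec.length / 2, 0, 0])
    return cloud, truth, centroid, spec


@pytest.fixture(scope="session")
def default_trees():
    """Default-condition synthetic trees for seeds 1..5 with their truth."""
    out = {}
    for seed in (1, 2, 3, 4, 5):
        out[seed] = cg.generate_tree(cg.SyntheticTreeSpec(seed=seed))
    return out


@pytest.fixture(scope="session")
def pipeline_runs(default_trees):
    """Full-pipeline reports for the five default trees (cached once)."""
    return {
        seed: cg.run_pipeline(cloud)
        for seed, (cloud, _) in default_trees.items()
    }
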