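"""Point-cloud container and file I/O.

The pipeline works on single-tree (or plot) point clouds in metres.  A cloud
optionally carries a per-point wood/leaf class label and a per-point leaf
instance id, which are preserved bit-exactly through PLY round-trips so that
the CLI stages can be chained through files.

Label encoding in PLY files (per-vertex integer properties):

* ``class_label``: 0 = leaf, 1 = wood, 2 = unassigned
* ``leaf_id``: int32 instance id, -1 = unassigned / noise
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

# class label codes
LEAF = 0
WOOD = 1
UNASSIGNED = 2

_CLASS_NAMES = {LEAF: "leaf", WOOD: "wood", UNASSIGNED: "unassigned"}


@dataclass
class PointCloud:
    """N x 3 coordinates in metres with optional per-point attributes.

    Invariants (checked by :meth:`validate`): coordinates are finite;
    ``class_label`` / ``leaf_id``, when present, have length N; a non-negative
    ``leaf_id`` may only occur on points whose ``class_label`` is leaf.
    """

    coords: np.ndarray
    class_label: np.ndarray | None = None
    leaf_id: np.ndarray | None = None
    source_path: str | None = None
    _kdtree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.class_label is not None:
            self.class_label = np.asarray(self.class_label, dtype=np.int32)
        if self.leaf_id is not None:
            self.leaf_id = np.asarray(self.leaf_id, dtype=np.int32)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point cloud contains non-finite coordinates")
        n = len(self.coords)
        for name in ("class_label", "leaf_id"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != point count {n}")
        if self.leaf_id is not None:
            assigned = self.leaf_id >= 0
            if self.class_label is None:
                if np.any(assigned):
                    raise ValueError("leaf_id assigned but class_label missing")
            elif np.any(assigned & (self.class_label != LEAF)):
                raise ValueError("leaf_id >= 0 on a point not labelled leaf")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def kdtree(self) -> cKDTree:
        """KD-tree over the coordinates, built lazily and cached."""
        if self._kdtree is None:
            self._kdtree = cKDTree(self.coords)
        return self._kdtree

    def subset(self, mask_or_idx: np.ndarray) -> "PointCloud":
        """New cloud restricted to a boolean mask or index array."""
        return PointCloud(
            coords=self.coords[mask_or_idx],
            class_label=None if self.class_label is None else self.class_label[mask_or_idx],
            leaf_id=None if self.leaf_id is None else self.leaf_id[mask_or_idx],
            source_path=self.source_path,
        )


def radius_neighbors(cloud: PointCloud, index: int, radius: float) -> np.ndarray:
    """Indices j != index with ||p_j - p_i|| <= radius, ascending.

    These are the N1 spherical-neighbourhood points used throughout the
    leaf-centre tests; the query point itself is excluded because the offset
    vectors w_j = p_j - p_i vanish for j = i.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= index < len(cloud):
        raise IndexError(f"point index {index} out of range for N={len(cloud)}")
    idx = cloud.kdtree.query_ball_point(cloud.coords[index], r=radius)
    idx = np.asarray(sorted(i for i in idx if i != index), dtype=np.intp)
    return idx


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".ply":
        return "ply"
    if ext in (".xyz", ".txt", ".asc"):
        return "xyz"
    if ext in (".las", ".laz"):
        return "las"
    raise ValueError(f"cannot infer point-cloud format from extension {ext!r}")


def read_point_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a PLY or ASCII-XYZ point cloud.

    ``class_label`` / ``leaf_id`` per-vertex properties are loaded when
    present.  Coordinates are returned unchanged (no recentring).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"point cloud file not found: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format == "ply":
        cloud = _read_ply(path)
    elif format == "xyz":
        cloud = _read_xyz(path)
    elif format == "las":
        raise ValueError(
            "LAS/LAZ input is not supported by this build; convert to PLY or "
            "ASCII XYZ first"
        )
    else:
        raise ValueError(f"unknown point-cloud format {format!r}")
    cloud.source_path = str(path)
    return cloud


def write_point_cloud(
    cloud: PointCloud, path: str | Path, format: str = "auto", binary: bool = True
) -> None:
    """Write a cloud so that :func:`read_point_cloud` round-trips it.

    Coordinates survive to at least 1e-6 m (exact for binary PLY); labels are
    exact.  XYZ output stores coordinates only.
    """
    cloud.validate()
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "ply":
        _write_ply(cloud, path, binary=binary)
    elif format == "xyz":
        np.savetxt(path, cloud.coords, fmt="%.8f")
    else:
        raise ValueError(f"unsupported output format {format!r}")


def _read_xyz(path: Path) -> PointCloud:
    try:
        data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"cannot parse {path} as ASCII XYZ: {exc}") from exc
    if data.size == 0:
        return PointCloud(coords=np.empty((0, 3)))
    if data.shape[1] < 3:
        raise ValueError(f"{path}: expected >= 3 columns, got {data.shape[1]}")
    return PointCloud(coords=data[:, :3])


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path} is not a PLY file")
        fmt = None
        properties: list[tuple[str, str]] = []  # (dtype code, name)
        n_vertices = 0
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unexpected end of PLY header")
            tokens = line.decode("ascii", errors="replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError(f"{path}: list properties on vertices unsupported")
                if tokens[1] not in _PLY_DTYPES:
                    raise ValueError(f"{path}: unknown PLY type {tokens[1]!r}")
                properties.append((_PLY_DTYPES[tokens[1]], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        names = [name for _, name in properties]
        if not {"x", "y", "z"} <= set(names):
            raise ValueError(f"{path}: vertex element lacks x/y/z properties")
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertices):
                rows.append(fh.readline().split())
            raw = np.array(rows, dtype=np.float64) if rows else np.empty((0, len(names)))
            rec = {name: raw[:, i] for i, (_, name) in enumerate(properties)}
        else:
            dtype = np.dtype([(name, "<" + code) for code, name in properties])
            buf = fh.read(dtype.itemsize * n_vertices)
            if len(buf) < dtype.itemsize * n_vertices:
                raise ValueError(f"{path}: truncated PLY body")
            arr = np.frombuffer(buf, dtype=dtype, count=n_vertices)
            rec = {name: arr[name] for name in names}
    coords = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)
    class_label = rec.get("class_label")
    leaf_id = rec.get("leaf_id")
    return PointCloud(
        coords=coords,
        class_label=None if class_label is None else class_label.astype(np.int32),
        leaf_id=None if leaf_id is None else leaf_id.astype(np.int32),
    )


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    props: list[tuple[str, str, np.ndarray]] = [
        ("double", "x", cloud.coords[:, 0]),
        ("double", "y", cloud.coords[:, 1]),
        ("double", "z", cloud.coords[:, 2]),
    ]
    if cloud.class_label is not None:
        props.append(("int32", "class_label", cloud.class_label))
    if cloud.leaf_id is not None:
        props.append(("int32", "leaf_id", cloud.leaf_id))
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append("comment crown-gf3d point cloud")
    header.append(f"element vertex {n}")
    header.extend(f"property {t} {name}" for t, name, _ in props)
    header.append("end_header")
    try:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            if binary:
                dtype = np.dtype([(name, "<" + _PLY_DTYPES[t]) for t, name, _ in props])
                out = np.empty(n, dtype=dtype)
                for t, name, col in props:
                    out[name] = col
                fh.write(out.tobytes())
            else:
                cols = [col for _, _, col in props]
                fmts = ["%.10g" if t == "double" else "%d" for t, _, _ in props]
                for i in range(n):
                    fh.write(
                        (" ".join(f % c[i] for f, c in zip(fmts, cols)) + "\n").encode("ascii")
                    )
    except OSError as exc:
        raise IOError(f"cannot write point cloud to {path}: {exc}") from exc
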