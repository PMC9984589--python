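"""Label volumes, surface meshes and landmark sets: containers and file I/O.

World coordinates are RAS millimetres throughout, taken from the NIfTI
affine.  Voxel indexing is 0-based and voxel *centers* map through the
affine, i.e. world = affine @ (i, j, k, 1).  Binary masks are stored as
uint8; on read, any value > 0.5 is foreground so that float masks written
by other tools are tolerated.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.measure import marching_cubes

log = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "SurfaceMesh",
    "LandmarkSet",
    "read_label_volume",
    "write_label_volume",
    "read_landmarks",
    "write_landmarks",
    "read_stl",
    "write_stl",
    "mask_to_surface",
    "volume_mm3",
]


@dataclass
class LabelVolume:
    """A binary segmentation mask plus its voxel-index -> world-mm affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.voxels.shape}")
        self.voxels = (self.voxels > 0.5).astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "LabelVolume", atol: float = 1e-6) -> bool:
        return self.voxels.shape == other.voxels.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (centers) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.affine.copy())


@dataclass
class SurfaceMesh:
    """Triangulated surface in world mm: (N, 3) vertices, (M, 3) face indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        return v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]

    def face_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def drop_degenerate(self, area_tol: float = 1e-12) -> "SurfaceMesh":
        """Remove zero-area triangles (keeps the vertex array intact)."""
        keep = self.face_areas() > area_tol
        return SurfaceMesh(self.vertices, self.faces[keep])

    def enclosed_volume(self) -> float:
        """Enclosed volume in mm^3 via the divergence theorem (watertight mesh)."""
        a, b, c = self.triangle_corners()
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


@dataclass
class LandmarkSet:
    """Ordered, uniquely named 3D points in world mm."""

    names: list[str]
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise ValueError("names and points length mismatch")
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise ValueError(f"duplicate landmark names: {sorted(dupes)}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self.names.index(name)]

    def subset(self, names: list[str]) -> "LandmarkSet":
        return LandmarkSet(list(names), np.array([self[n] for n in names]))


# ---------------------------------------------------------------------------
# NIfTI label volumes


def read_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if dtype.fields is not None:  # RGB / structured voxel types
        raise ValueError(f"unsupported voxel data type {dtype}: expected a scalar mask")
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise ValueError(f"expected a 3D label volume, got shape {shape}")
    data = np.asarray(img.get_fdata())
    return LabelVolume((data > 0.5).astype(np.uint8), np.asarray(img.affine, dtype=float))


def write_label_volume(vol: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.uint8), vol.affine), str(path))


def volume_mm3(vol: LabelVolume) -> float:
    """Foreground voxel count times the voxel volume |det A|; 0 if empty."""
    return float(vol.n_foreground * abs(np.linalg.det(vol.affine[:3, :3])))


def mask_to_surface(vol: LabelVolume) -> SurfaceMesh:
    """Closed 0.5-level isosurface of the mask in world mm.

    The mask is zero-padded by one voxel so that foreground touching the
    array border still yields a watertight surface; marching-cubes vertex
    coordinates (voxel index units of the padded array) are shifted back and
    pushed through the volume affine.
    """
    if vol.n_foreground == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(vol.voxels.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding offset -> original voxel index coords
    world = verts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return SurfaceMesh(world, faces).drop_degenerate()


# ---------------------------------------------------------------------------
# Landmarks CSV  (header: name,x,y,z ; world mm)


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path, dtype={"name": str})
    expected = ["name", "x", "y", "z"]
    if list(df.columns)[:4] != expected:
        raise ValueError(f"landmark CSV must have header {','.join(expected)}, got {list(df.columns)}")
    if df.empty:
        log.warning("landmark file %s contains no points", path)
        return LandmarkSet([], np.empty((0, 3)))
    coords = np.empty((len(df), 3))
    for j, col in enumerate(("x", "y", "z")):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # +1 header, +1 one-based
            raise ValueError(f"non-numeric coordinate in column '{col}' at line {row}")
        coords[:, j] = vals.to_numpy()
    return LandmarkSet(df["name"].tolist(), coords)


def write_landmarks(lms: LandmarkSet, path) -> None:
    df = pd.DataFrame(
        {"name": lms.names, "x": lms.points[:, 0], "y": lms.points[:, 1], "z": lms.points[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Binary STL


def write_stl(mesh: SurfaceMesh, path) -> None:
    a, b, c = mesh.triangle_corners()
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norms, out=np.zeros_like(n), where=norms > 0)
    rec = np.zeros(len(mesh.faces), dtype=_STL_DTYPE)
    rec["normal"] = n.astype(np.float32)
    rec["v0"] = a.astype(np.float32)
    rec["v1"] = b.astype(np.float32)
    rec["v2"] = c.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", len(rec)))
        fh.write(rec.tobytes())


def read_stl(path) -> SurfaceMesh:
    with open(path, "rb") as fh:
        header = fh.read(80)
        if header[:5] == b"solid" and b"\0" not in header:
            raise ValueError("ASCII STL is not supported; write binary STL")
        (count,) = struct.unpack("<I", fh.read(4))
        rec = np.frombuffer(fh.read(count * _STL_DTYPE.itemsize), dtype=_STL_DTYPE)
    if len(rec) != count:
        raise ValueError("truncated STL file")
    tri = np.stack([rec["v0"], rec["v1"], rec["v2"]], axis=1).astype(float)  # (M,3,3)
    flat = tri.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceMesh(verts, faces).drop_degenerate()


_STL_DTYPE = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("v0", "<f4", (3,)),
        ("v1", "<f4", (3,)),
        ("v2", "<f4", (3,)),
        ("attr", "<u2"),
    ]
)
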