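"""Synthetic segmentation phantoms with known ground truth.

Real repeatability studies of muscle segmentation rest on clinical MRI data
that cannot be shared; this module replaces the human operator with a fully
specified generative model so that every downstream stage (registration,
sub-volume cutting, metrics, statistics) can be exercised and verified
end-to-end.

The phantom is a tube-like muscle rasterized on an anisotropic voxel grid
emulating coronal T1-weighted acquisitions (0.817 mm in-plane pixels, 4 mm
slices by default).  Its centerline runs along the slice-normal axis, so a
"slice" of the phantom is one 2D contour the operator would have drawn and
the terminal slices are the muscle extremities that are hard to identify on
MRI.  Three muscle kinds are available: a straight tube, a spindle (tapered)
tube, and a bowed tube whose belly swings laterally away from the straight
origin–insertion line (iliopsoas-like wrap).

Repeated segmentations are simulated by displacing each slice's contour
with a smooth random field: the signed Euclidean distance transform of the
slice is thresholded at a Gaussian-correlated noise field instead of zero,
which displaces the boundary radially with a controllable SD.  The SD
interpolates linearly from `belly_sigma_mm` at the axis center to
`extremity_sigma_mm` at the ends, encoding the hypothesis that muscle
extremities are harder to delineate, and terminal slices can be dropped
entirely with a given probability (a missed end contour).

One global seed expands into per-repeat, per-slice substreams through
`numpy.random.SeedSequence` spawn keys, so repeats are independent yet the
whole study is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .registration import AffineTransform
from .subvolumes import MuscleAxis, make_axis
from .volio import (
    LabelVolume,
    LandmarkSet,
    SurfaceMesh,
    read_label_volume,
    read_landmarks,
    read_stl,
    write_label_volume,
    write_landmarks,
    write_stl,
)

log = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "NoiseModel", "PhantomStudy", "make_phantom",
           "simulate_repeats", "write_study", "read_study", "LANDMARK_NAMES"]

MUSCLE_KINDS = ("straight_tube", "tapered_tube", "wrapped_tube")

#: 12 bony landmarks of the hip region; offsets are mm in the muscle frame,
#: anchored at the origin ("O") or insertion ("I") attachment.
_LANDMARK_OFFSETS: list[tuple[str, str, tuple[float, float, float]]] = [
    ("ASIS_R",               "O", (40.0, 35.0, 8.0)),
    ("ASIS_L",               "O", (-40.0, 32.0, 12.0)),
    ("PSIS_R",               "O", (28.0, -38.0, 6.0)),
    ("PSIS_L",               "O", (-30.0, -36.0, 10.0)),
    ("iliac_crest_R",        "O", (45.0, 8.0, 0.0)),    # axial offset set to 0.15 L
    ("iliac_crest_L",        "O", (-45.0, 6.0, 0.0)),   # axial offset set to 0.15 L
    ("sacrum",               "O", (0.0, -42.0, 18.0)),
    ("pubic_symphysis",      "O", (0.0, 30.0, -15.0)),
    ("greater_trochanter",   "I", (28.0, 6.0, -8.0)),
    ("lesser_trochanter",    "I", (-14.0, -12.0, -18.0)),
    ("femoral_epicondyle_M", "I", (-22.0, -3.0, 52.0)),
    ("femoral_epicondyle_L", "I", (22.0, 3.0, 50.0)),
]

LANDMARK_NAMES = [name for name, _, _ in _LANDMARK_OFFSETS]


@dataclass
class PhantomSpec:
    """Geometry and grid of one synthetic muscle phantom.

    Defaults emulate the clinical acquisitions the generator stands in for:
    0.817 mm in-plane pixels and 4 mm slice thickness on a grid auto-sized
    to the muscle plus a 5-voxel margin (pass `grid` for a fixed matrix,
    e.g. (512, 512, 40)).  Muscle dimensions default to a hip-muscle scale:
    120 mm attachment-to-attachment length, 18 mm belly radius.
    """

    muscle_kind: str = "straight_tube"
    length_mm: float = 120.0
    max_radius_mm: float = 18.0
    taper: float = 0.0
    wrap_offset_mm: float = 0.0
    pixel_mm: float = 0.817
    slice_mm: float = 4.0
    grid: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.muscle_kind not in MUSCLE_KINDS:
            raise ValueError(f"muscle_kind must be one of {MUSCLE_KINDS}")
        if self.length_mm <= 2 * self.slice_mm:
            raise ValueError("length_mm must exceed two slice thicknesses")
        if self.max_radius_mm <= 0 or self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("radii and spacings must be positive")
        if not (0 <= self.taper < 1):
            raise ValueError("taper must lie in [0, 1)")

    def required_grid(self, margin_voxels: int = 5) -> tuple[int, int, int]:
        """Smallest grid holding the muscle plus the margin on every side."""
        wrap = abs(self.wrap_offset_mm)
        ni = int(np.ceil((2 * self.max_radius_mm + wrap) / self.pixel_mm)) + 2 * margin_voxels
        nj = int(np.ceil(2 * self.max_radius_mm / self.pixel_mm)) + 2 * margin_voxels
        nk = int(np.ceil(self.length_mm / self.slice_mm)) + 2 * margin_voxels
        return ni, nj, nk


@dataclass
class NoiseModel:
    """Operator-variability model for simulated re-segmentations.

    Boundary displacement SD interpolates from `belly_sigma_mm` at the
    mid-muscle to `extremity_sigma_mm` at the attachment ends;
    `correlation_length_mm` sets the in-slice smoothness of the displacement
    field; `end_slice_dropout_prob` is the chance that a terminal slice's
    contour is missed entirely.
    """

    belly_sigma_mm: float = 0.5
    extremity_sigma_mm: float = 3.0
    correlation_length_mm: float = 8.0
    end_slice_dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.belly_sigma_mm < 0 or self.extremity_sigma_mm < 0:
            raise ValueError("sigmas must be non-negative")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be positive")
        if not (0 <= self.end_slice_dropout_prob <= 1):
            raise ValueError("end_slice_dropout_prob must lie in [0, 1]")

    def sigma_at(self, u: float) -> float:
        """Displacement SD at normalized axial coordinate u = |p-c|/(L/2)."""
        u = min(max(float(u), 0.0), 1.0)
        return self.belly_sigma_mm + (self.extremity_sigma_mm - self.belly_sigma_mm) * u


@dataclass
class PhantomStudy:
    """One synthetic subject: ground truth, repeats, landmarks, atlas, bone."""

    truth: LabelVolume
    repeats: list[LabelVolume]
    landmarks: LandmarkSet
    atlas_landmarks: LandmarkSet
    atlas_attachments: LandmarkSet
    true_affine: AffineTransform
    bone_surface: SurfaceMesh
    spec: PhantomSpec
    noise: NoiseModel | None = None

    @property
    def true_axis(self) -> MuscleAxis:
        origin = self.true_affine.apply_points(self.atlas_attachments["origin"])[0]
        insertion = self.true_affine.apply_points(self.atlas_attachments["insertion"])[0]
        return make_axis(origin, insertion)


# ---------------------------------------------------------------------------
# Phantom construction


def _centerline(spec: PhantomSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centerline lateral offset cx(t) and radius r(t) at axial position t (mm)."""
    s = t / spec.length_mm
    cx = spec.wrap_offset_mm * np.sin(np.pi * np.clip(s, 0, 1))
    u = 2.0 * s - 1.0
    r = spec.max_radius_mm * (1.0 - spec.taper * u**2)
    return cx, r


def make_phantom(spec: PhantomSpec, landmark_jitter_mm: float = 0.0) -> PhantomStudy:
    """Build the ground-truth study for one synthetic subject (no repeats).

    The muscle runs along the world z (slice-normal) axis from the origin
    attachment at z=0 to the insertion at z=length.  Twelve bony landmarks
    sit at fixed offsets in the muscle frame; the atlas-side point sets are
    the exact preimages of the subject points under a seeded ground-truth
    affine, so a registration fitted to the landmark pairs must reproduce
    that affine when `landmark_jitter_mm` is zero.
    """
    ni_req, nj_req, nk_req = spec.required_grid()
    if spec.grid is None:
        ni, nj, nk = ni_req, nj_req, nk_req
    else:
        ni, nj, nk = spec.grid
        if ni < ni_req or nj < nj_req or nk < nk_req:
            raise ValueError(
                f"grid {spec.grid} too small for the muscle plus a 5-voxel margin: "
                f"needs at least ({ni_req}, {nj_req}, {nk_req})"
            )
    px, th = spec.pixel_mm, spec.slice_mm
    # world frame: x = in-plane (bow direction), y = in-plane, z = slice normal
    wrap = abs(spec.wrap_offset_mm)
    x0 = -(spec.max_radius_mm + 5 * px) if spec.wrap_offset_mm >= 0 else -(
        spec.max_radius_mm + wrap + 5 * px)
    y0 = -(spec.max_radius_mm + 5 * px)
    z0 = -(5 * th) + th / 2.0  # slice k=5 center sits at z = th/2
    affine = np.array(
        [[px, 0, 0, x0], [0, px, 0, y0], [0, 0, th, z0], [0, 0, 0, 1.0]]
    )

    xs = x0 + np.arange(ni) * px
    ys = y0 + np.arange(nj) * px
    zs = z0 + np.arange(nk) * th
    voxels = np.zeros((ni, nj, nk), dtype=np.uint8)
    inside = (zs >= 0) & (zs <= spec.length_mm)
    cx_all, r_all = _centerline(spec, zs)
    for k in np.nonzero(inside)[0]:
        d2 = (xs[:, None] - cx_all[k]) ** 2 + (ys[None, :] - 0.0) ** 2
        voxels[:, :, k] = d2 <= r_all[k] ** 2
    truth = LabelVolume(voxels, affine)
    if truth.n_foreground == 0:
        raise ValueError("phantom rasterized to an empty mask; check the spec")

    origin = np.array([0.0, 0.0, 0.0])
    insertion = np.array([0.0, 0.0, spec.length_mm])
    names, points = [], []
    for name, anchor, (ox, oy, oz) in _LANDMARK_OFFSETS:
        base = origin if anchor == "O" else insertion
        off = np.array([ox, oy, oz], dtype=float)
        if name.startswith("iliac_crest"):
            off[2] = 0.15 * spec.length_mm  # crest plane crosses the proximal muscle
        names.append(name)
        points.append(base + off)
    landmarks = LandmarkSet(names, np.array(points))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(7,)))
    true_affine = _random_affine(rng)
    inv = true_affine.inverse()
    atlas_landmarks = LandmarkSet(names, inv.apply_points(landmarks.points))
    atlas_attachments = LandmarkSet(
        ["origin", "insertion"], inv.apply_points(np.stack([origin, insertion]))
    )
    if landmark_jitter_mm > 0:
        jitter = rng.normal(0.0, landmark_jitter_mm, size=landmarks.points.shape)
        landmarks = LandmarkSet(names, landmarks.points + jitter)

    bone = _bone_mesh(spec)
    return PhantomStudy(
        truth=truth, repeats=[], landmarks=landmarks,
        atlas_landmarks=atlas_landmarks, atlas_attachments=atlas_attachments,
        true_affine=true_affine, bone_surface=bone, spec=spec,
    )


def _random_affine(rng: np.random.Generator) -> AffineTransform:
    """Seeded atlas→subject ground truth: mild rotation, scale, shear, shift."""
    angles = rng.uniform(-0.2, 0.2, size=3)

    def rot(axis: int, a: float) -> np.ndarray:
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c; m[j, j] = c; m[i, j] = -s; m[j, i] = s
        return m

    R = rot(0, angles[0]) @ rot(1, angles[1]) @ rot(2, angles[2])
    scales = np.diag(rng.uniform(0.9, 1.1, size=3))
    shear = np.eye(3)
    shear[0, 1] = rng.uniform(-0.05, 0.05)
    shear[1, 2] = rng.uniform(-0.05, 0.05)
    matrix = R @ scales @ shear
    translation = rng.uniform(-30, 30, size=3)
    return AffineTransform(matrix, translation)


def _bone_mesh(spec: PhantomSpec, n_theta: int = 24, n_axial: int = 16) -> SurfaceMesh:
    """A coarse bone-shaft tube beside the muscle (snapping substrate)."""
    radius = 12.0
    offset_x = spec.max_radius_mm + abs(spec.wrap_offset_mm) + radius + 8.0
    zs = np.linspace(-20.0, spec.length_mm + 20.0, n_axial)
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    verts = []
    for z in zs:
        for t in thetas:
            verts.append([offset_x + radius * np.cos(t), radius * np.sin(t), z])
    faces = []
    for a in range(n_axial - 1):
        for t in range(n_theta):
            t2 = (t + 1) % n_theta
            v00 = a * n_theta + t
            v01 = a * n_theta + t2
            v10 = (a + 1) * n_theta + t
            v11 = (a + 1) * n_theta + t2
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    return SurfaceMesh(np.array(verts), np.array(faces))


# ---------------------------------------------------------------------------
# Repeat simulation


def simulate_repeats(
    truth: LabelVolume,
    axis: MuscleAxis,
    noise: NoiseModel,
    n_repeats: int = 3,
) -> list[LabelVolume]:
    """Simulate `n_repeats` independent re-segmentations of `truth`.

    Slice by slice (along the third voxel axis), the boundary of the truth
    contour is displaced by a smooth Gaussian-correlated field whose SD
    follows the extremity weighting of `noise`; with probability
    `end_slice_dropout_prob` a terminal (first/last non-empty) slice is
    dropped entirely.  Each output is reduced to its largest 6-connected
    component so a repeat is a single plausible muscle.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats for a repeatability study")
    if truth.n_foreground == 0:
        raise ValueError("truth volume is empty")
    nk = truth.voxels.shape[2]
    nonempty = np.nonzero(truth.voxels.any(axis=(0, 1)))[0]
    terminal = {int(nonempty[0]), int(nonempty[-1])}
    px = float(np.linalg.norm(truth.affine[:3, 0]))
    smooth_vox = noise.correlation_length_mm / px
    half_L = axis.length_L / 2.0

    pure_copy = (
        noise.belly_sigma_mm == 0
        and noise.extremity_sigma_mm == 0
        and noise.end_slice_dropout_prob == 0
    )
    # smoothing a unit-variance white field scales its marginal SD by the L2
    # norm of the (wrapped) discrete kernel; dividing by it restores exact
    # unit marginal variance while keeping the spatial correlation
    shape2d = truth.voxels.shape[:2]
    delta = np.zeros(shape2d)
    delta[shape2d[0] // 2, shape2d[1] // 2] = 1.0
    kernel = ndimage.gaussian_filter(delta, smooth_vox, mode="wrap")
    kernel_norm = float(np.sqrt((kernel**2).sum()))
    repeats: list[LabelVolume] = []
    for r in range(n_repeats):
        if pure_copy:
            repeats.append(truth.copy())
            continue
        out = np.zeros_like(truth.voxels)
        for k in range(nk):
            slice2d = truth.voxels[:, :, k]
            if not slice2d.any():
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=noise.seed, spawn_key=(r, k))
            )
            if k in terminal and rng.random() < noise.end_slice_dropout_prob:
                log.info("repeat %d: terminal slice %d dropped (missed contour)", r, k)
                continue
            center_world = truth.world_coordinates(
                np.array([[(truth.voxels.shape[0] - 1) / 2.0,
                           (truth.voxels.shape[1] - 1) / 2.0, k]])
            )[0]
            u = abs(float(center_world @ axis.direction) - axis.center_c) / half_L
            sigma = noise.sigma_at(u)
            if sigma == 0:
                out[:, :, k] = slice2d
                continue
            sdt = (
                ndimage.distance_transform_edt(slice2d, sampling=px)
                - ndimage.distance_transform_edt(1 - slice2d, sampling=px)
            )
            white = rng.standard_normal(slice2d.shape)
            field = ndimage.gaussian_filter(white, smooth_vox, mode="wrap") / kernel_norm
            new_slice = (sdt + sigma * field) > 0
            if slice2d.any() and not new_slice.any():
                log.info("repeat %d slice %d: perturbation emptied the contour", r, k)
            out[:, :, k] = new_slice
        labels, n_comp = ndimage.label(out)  # 6-connected in 3D by default
        if n_comp > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
            out = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
        if not out.any():
            raise ValueError("simulated repeat is empty: noise level implausible")
        repeats.append(LabelVolume(out, truth.affine.copy()))
    return repeats


# ---------------------------------------------------------------------------
# Study I/O


def write_study(study: PhantomStudy, directory, overwrite: bool = False) -> Path:
    """Write a study to disk; returns the path of the JSON manifest.

    Refuses a non-empty target directory unless `overwrite` is set.  The
    manifest records every file plus the generating spec and noise model, so
    the study can be reloaded or regenerated losslessly.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace its contents"
        )
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    write_label_volume(study.truth, directory / "truth.nii.gz")
    paths["truth"] = "truth.nii.gz"
    repeat_files = []
    for i, rep in enumerate(study.repeats, start=1):
        name = f"repeat_{i:02d}.nii.gz"
        write_label_volume(rep, directory / name)
        repeat_files.append(name)
    paths["repeats"] = repeat_files
    write_landmarks(study.landmarks, directory / "landmarks.csv")
    write_landmarks(study.atlas_landmarks, directory / "atlas_landmarks.csv")
    write_landmarks(study.atlas_attachments, directory / "atlas_attachments.csv")
    paths["landmarks"] = "landmarks.csv"
    paths["atlas_landmarks"] = "atlas_landmarks.csv"
    paths["atlas_attachments"] = "atlas_attachments.csv"
    write_stl(study.bone_surface, directory / "bone.stl")
    paths["bone_surface"] = "bone.stl"
    manifest = {
        "format": "segrepeat-phantom-study/1",
        "paths": paths,
        "true_affine": study.true_affine.to_dict(),
        "spec": asdict(study.spec),
        "noise": asdict(study.noise) if study.noise is not None else None,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_study(manifest_path) -> PhantomStudy:
    """Reload a study written by `write_study`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    paths = manifest["paths"]
    spec_d = dict(manifest["spec"])
    if spec_d.get("grid") is not None:
        spec_d["grid"] = tuple(spec_d["grid"])
    spec = PhantomSpec(**spec_d)
    noise = NoiseModel(**manifest["noise"]) if manifest.get("noise") else None
    return PhantomStudy(
        truth=read_label_volume(root / paths["truth"]),
        repeats=[read_label_volume(root / p) for p in paths["repeats"]],
        landmarks=read_landmarks(root / paths["landmarks"]),
        atlas_landmarks=read_landmarks(root / paths["atlas_landmarks"]),
        atlas_attachments=read_landmarks(root / paths["atlas_attachments"]),
        true_affine=AffineTransform.from_dict(manifest["true_affine"]),
        bone_surface=read_stl(root / paths["bone_surface"]),
        spec=spec,
        noise=noise,
    )
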