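"""Origin–insertion axis and nested sub-volume decomposition.

A muscle's line of action is modelled as the straight line through its
origin and insertion attachment points.  Each segmentation is decomposed
into ten nested sub-volumes: starting from the mid-point between the
attachments, two parallel cutting planes orthogonal to that line are moved
apart in 5%-of-muscle-length steps; at each step only the tissue between
the planes is kept.  Level k therefore contains the central 10*k % of the
muscle length; level 10 is the complete, uncut segmentation (muscle tissue
may extend past the attachment planes).

For the iliopsoas a preliminary standardization cut removes the proximal
end above a plane through pelvic landmarks, so that repeats on scans with
different cranial coverage stay comparable.

Voxel selection uses voxel-center projections in world mm; voxels exactly
on a cutting plane are *included* (closed slab), which guarantees nesting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volio import LabelVolume

log = logging.getLogger(__name__)

__all__ = ["MuscleAxis", "make_axis", "projection_field", "standardize_proximal",
           "cut_series", "SubvolumeSeries"]


@dataclass
class MuscleAxis:
    """Muscle line of action from origin to insertion, in world mm."""

    origin: np.ndarray
    insertion: np.ndarray
    direction: np.ndarray  # unit vector origin -> insertion
    length_L: float        # ||insertion - origin|| in mm
    center_c: float        # scalar projection of the attachment mid-point


def make_axis(origin: np.ndarray, insertion: np.ndarray) -> MuscleAxis:
    origin = np.asarray(origin, dtype=float).reshape(3)
    insertion = np.asarray(insertion, dtype=float).reshape(3)
    delta = insertion - origin
    length = float(np.linalg.norm(delta))
    if length <= 1e-6:
        raise ValueError("origin and insertion coincide: cannot define a muscle axis")
    direction = delta / length
    center = float(((origin + insertion) / 2.0) @ direction)
    return MuscleAxis(origin, insertion, direction, length, center)


def projection_field(vol: LabelVolume, axis: MuscleAxis) -> np.ndarray:
    """Scalar projection of every voxel center onto the axis direction.

    Separable in the three index coordinates because the affine is linear:
    proj(i,j,k) = i*(col_i . d) + j*(col_j . d) + k*(col_k . d) + t . d.
    """
    A = vol.affine
    d = axis.direction
    coeffs = A[:3, :3].T @ d          # per-index-axis contribution
    const = float(A[:3, 3] @ d)
    ni, nj, nk = vol.voxels.shape
    pi = np.arange(ni) * coeffs[0]
    pj = np.arange(nj) * coeffs[1]
    pk = np.arange(nk) * coeffs[2]
    return pi[:, None, None] + pj[None, :, None] + pk[None, None, :] + const


def standardize_proximal(
    vol: LabelVolume, axis: MuscleAxis, plane_point: np.ndarray
) -> LabelVolume:
    """Remove tissue proximal to a cutting plane normal to the muscle axis.

    The plane passes through `plane_point`; proximal means toward the origin
    attachment, i.e. voxels whose axis projection falls strictly below the
    plane's (the direction vector points origin → insertion).  If the plane
    lies entirely proximal to the segmentation the volume is returned
    unchanged with a warning; a plane that would remove all foreground
    raises, since that indicates a landmark/segmentation mismatch.
    """
    plane_proj = float(np.asarray(plane_point, dtype=float).reshape(3) @ axis.direction)
    proj = projection_field(vol, axis)
    fg = vol.voxels > 0
    if not fg.any():
        raise ValueError("cannot standardize an empty volume")
    proximal = proj < plane_proj
    removed = proximal & fg
    if not removed.any():
        log.warning("standardization plane lies proximal to the whole muscle: no-op")
        return vol.copy()
    if removed.sum() == fg.sum():
        raise ValueError(
            "standardization plane removes the entire segmentation: "
            "check landmark placement against the muscle axis"
        )
    out = vol.voxels.copy()
    out[removed] = 0
    return LabelVolume(out, vol.affine.copy())


@dataclass
class SubvolumeSeries:
    """Nested sub-volumes keyed by level k=1..n (fraction 0.1*k of length L)."""

    levels: dict[int, LabelVolume]
    axis: MuscleAxis

    def __post_init__(self) -> None:
        ks = sorted(self.levels)
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("levels must be contiguous 1..n")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __getitem__(self, k: int) -> LabelVolume:
        return self.levels[k]


def cut_series(
    vol: LabelVolume,
    axis: MuscleAxis,
    step_fraction: float = 0.05,
    n_levels: int = 10,
) -> SubvolumeSeries:
    """Decompose a segmentation into `n_levels` nested central sub-volumes.

    Level k (k < n_levels) keeps voxels whose center projection p satisfies
    |p - center_c| <= k * step_fraction * L (closed slab, ties included);
    the final level is the complete, uncut segmentation.
    """
    if vol.n_foreground == 0:
        raise ValueError("cannot cut an empty segmentation")
    if step_fraction <= 0 or n_levels < 1:
        raise ValueError("step_fraction must be positive and n_levels >= 1")
    proj = projection_field(vol, axis)
    dist = np.abs(proj - axis.center_c)
    levels: dict[int, LabelVolume] = {}
    for k in range(1, n_levels):
        half_width = k * step_fraction * axis.length_L
        mask = vol.voxels * (dist <= half_width)
        levels[k] = LabelVolume(mask.astype(np.uint8), vol.affine.copy())
    levels[n_levels] = vol.copy()
    if levels[1].n_foreground == 0:
        raise ValueError(
            "innermost sub-volume is empty: the axis mid-point falls outside the "
            "segmentation — axis and segmentation are inconsistent"
        )
    return SubvolumeSeries(levels, axis)
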