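"""Landmark-based affine registration and attachment-point snapping.

Muscle attachment points are not visible on clinical MRI, so they are
transferred from a generic atlas: a 12-degree-of-freedom affine transform is
least-squares fitted (via SVD) to pairs of named bony landmarks identified
on both the atlas and the subject, and then applied to the atlas attachment
points.  Points that land off the bone can be snapped to the nearest point
on a bone surface mesh.

Correspondence between landmark sets is established by *name*, never by file
order.  A similarity fit (rotation + isotropic scale + translation, Umeyama)
is provided alongside the full affine for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volio import LandmarkSet, SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "AffineTransform",
    "fit_affine",
    "fit_similarity",
    "apply_transform",
    "snap_to_surface",
    "closest_point_on_triangles",
]


@dataclass
class AffineTransform:
    """World-mm affine map p -> matrix @ p + translation."""

    matrix: np.ndarray
    translation: np.ndarray
    rms_residual_mm: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.translation))):
            raise ValueError("transform entries must be finite")
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other: apply `other` first, then `self`."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.translation + self.translation
        )

    def homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.matrix
        h[:3, 3] = self.translation
        return h

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "rms_residual_mm": self.rms_residual_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.array(d["matrix"]), np.array(d["translation"]),
                   float(d.get("rms_residual_mm", 0.0)))


def _match_pairs(source: LandmarkSet, target: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    common = [n for n in source.names if n in target.names]
    if len(common) < len(source.names):
        missing = sorted(set(source.names) - set(common))
        log.warning("landmarks without a counterpart are ignored: %s", missing)
    src = np.array([source[n] for n in common])
    tgt = np.array([target[n] for n in common])
    return src, tgt


def fit_affine(
    source: LandmarkSet, target: LandmarkSet, min_pairs: int = 4
) -> AffineTransform:
    """Least-squares 12-DOF affine mapping source landmarks onto target.

    Minimizes sum_i ||A s_i + t - t_i||^2 over A (3x3) and t, solved through
    the SVD-based pseudoinverse of the homogeneous design matrix.  Pairs are
    matched by landmark name.

    Raises
    ------
    ValueError
        If fewer than `min_pairs` named pairs match, or the source points are
        (nearly) coplanar: the fit requires the smallest singular value of the
        centered source matrix to exceed 1e-9 times the largest.
    """
    src, tgt = _match_pairs(source, target)
    n = len(src)
    if n < min_pairs:
        raise ValueError(f"affine fit needs >= {min_pairs} matched landmark pairs, got {n}")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] <= 1e-9 * sv[0]:
        raise ValueError(
            "degenerate landmark configuration: source points are coplanar/collinear "
            f"(singular-value ratio {sv[-1] / sv[0]:.3e} <= 1e-9)"
        )
    design = np.hstack([src, np.ones((n, 1))])  # (n, 4)
    sol, *_ = np.linalg.lstsq(design, tgt, rcond=None)  # (4, 3)
    matrix = sol[:3].T
    translation = sol[3]
    residual = design @ sol - tgt
    rms = float(np.sqrt((residual**2).sum(axis=1).mean()))
    return AffineTransform(matrix, translation, rms_residual_mm=rms)


def fit_similarity(source: LandmarkSet, target: LandmarkSet) -> AffineTransform:
    """Umeyama similarity fit (rotation + isotropic scale + translation)."""
    src, tgt = _match_pairs(source, target)
    if len(src) < 3:
        raise ValueError("similarity fit needs >= 3 matched landmark pairs")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    xs, xt = src - mu_s, tgt - mu_t
    cov = xt.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = (xs**2).sum() / len(src)
    scale = np.trace(np.diag(D) @ S) / var_s
    t = mu_t - scale * R @ mu_s
    residual = xs @ (scale * R).T - xt
    rms = float(np.sqrt((residual**2).sum(axis=1).mean()))
    return AffineTransform(scale * R, t, rms_residual_mm=rms)


def apply_transform(transform: AffineTransform, landmarks: LandmarkSet) -> LandmarkSet:
    """Map every landmark through the transform; names and order preserved."""
    return LandmarkSet(list(landmarks.names), transform.apply_points(landmarks.points))


# ---------------------------------------------------------------------------
# Snap-to-surface


def closest_point_on_triangles(point: np.ndarray, mesh: SurfaceMesh) -> tuple[np.ndarray, float]:
    """Exact closest point on any triangle of the mesh (interior, edge or vertex).

    Vectorized over all faces (Ericson's region decomposition); for each
    triangle the true closest point is computed, so the result is the exact
    brute-force minimum.
    """
    if len(mesh.faces) == 0:
        raise ValueError("mesh has no triangles")
    p = np.asarray(point, dtype=float).reshape(3)
    a, b, c = mesh.triangle_corners()
    ab, ac, ap = b - a, c - a, p - a

    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    closest = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def assign(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.ndim == 2 else pts
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    v_ab = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    w_ac = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.divide(d4 - d3, denom_bc, out=np.zeros_like(d4), where=denom_bc != 0)
    assign((va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0), b + w_bc[:, None] * (c - b))

    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(vb), where=denom != 0)
    w = np.divide(vc, denom, out=np.zeros_like(vc), where=denom != 0)
    assign(np.ones(len(a), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)  # face

    dists = np.linalg.norm(closest - p, axis=1)
    i = int(np.argmin(dists))
    return closest[i], float(dists[i])


def snap_to_surface(
    point: np.ndarray, surface: SurfaceMesh, max_snap_mm: float = 15.0
) -> tuple[np.ndarray, bool]:
    """Relocate a point to the nearest point on a surface mesh.

    Returns (snapped point, snapped flag).  If the nearest surface point is
    further than `max_snap_mm` the input is returned unchanged with a warning:
    such a displacement would be anatomically implausible and is the automated
    analogue of a failed visual check.
    """
    if max_snap_mm <= 0:
        raise ValueError("max_snap_mm must be positive")
    if surface.n_vertices == 0 or len(surface.faces) == 0:
        raise ValueError("cannot snap to an empty mesh")
    p = np.asarray(point, dtype=float).reshape(3)
    nearest, dist = closest_point_on_triangles(p, surface)
    if dist > max_snap_mm:
        log.warning(
            "snap rejected: nearest surface point is %.2f mm away (limit %.2f mm); "
            "point left unchanged — verify the attachment placement", dist, max_snap_mm
        )
        return p, False
    return nearest, bool(dist > 1e-9)
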