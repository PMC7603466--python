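"""Planar homography algebra for sequential mosaicking.

A homography is a 3x3 projective transform relating two views of a
(locally) planar scene, defined up to scale and canonically normalized
so that ``h33 == 1``.  Two equivalent parameterizations are used
throughout the package:

* the 3x3 matrix form, convenient for composition and warping;
* the 4-point form — the displacements of the four patch corners —
  which conditions regression losses far better than the raw matrix
  entries (rotation/shear entries are tiny next to translations).

The in-plane rotation convention everywhere in this package is

    R(b) = [[cos b,  sin b],
            [-sin b, cos b]]

i.e. the transpose of the usual counter-clockwise matrix.  It matches
the convention of the rigid pair generator and the rotation–scale–
rotation decomposition, so angles recovered by :func:`decompose` are
directly comparable with generator inputs.

Coordinates are pixel coordinates, origin at the top-left, x right and
y down.  A *pairwise* homography ``H`` for frames ``(k, k+1)`` maps
frame ``k+1`` coordinates into frame ``k`` coordinates, so the relative
homography into a reference plane is the left product of pairwise
matrices (see :func:`compose_relative`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import ProjectiveTransform

__all__ = [
    "DegenerateGeometryError",
    "ProjectiveDegeneracyError",
    "DecompositionError",
    "FourPointHomography",
    "DecomposedHomography",
    "rotation2d",
    "rigid_matrix",
    "translation_matrix",
    "normalize_homography",
    "check_invertible",
    "fourpt_to_matrix",
    "matrix_to_fourpt",
    "compose_relative",
    "decompose",
    "recompose",
    "apply_homography",
    "default_corners",
    "wrap_angle",
]

_DET_EPS = 1e-12
#: |h31|,|h32| above this triggers a non-affine warning in decompose().
AFFINE_TOL = 1e-3


class DegenerateGeometryError(ValueError):
    """Corner configuration is collinear/coincident; no homography fits."""


class ProjectiveDegeneracyError(ValueError):
    """A point is mapped to (or from) infinity by the homography."""


class DecompositionError(ValueError):
    """The 2x2 block cannot be decomposed as rotation-scale-rotation."""


def wrap_angle(a: float) -> float:
    """Wrap an angle to the canonical branch (-pi, pi]."""
    a = float(a)
    w = (a + np.pi) % (2.0 * np.pi) - np.pi
    if w == -np.pi:
        w = np.pi
    return w


def rotation2d(beta: float) -> np.ndarray:
    """2x2 rotation in the package convention [[c, s], [-s, c]]."""
    c, s = np.cos(beta), np.sin(beta)
    return np.array([[c, s], [-s, c]], dtype=float)


def translation_matrix(tx: float, ty: float) -> np.ndarray:
    """3x3 pure-translation homography."""
    h = np.eye(3)
    h[0, 2] = tx
    h[1, 2] = ty
    return h


def rigid_matrix(beta: float, tx: float, ty: float, degrees: bool = False) -> np.ndarray:
    """Rigid homography: rotation by ``beta`` about the origin, then translation.

    This is exactly the corner map used by controlled pair generation:
    ``x' = R(beta) x + (tx, ty)``.
    """
    if degrees:
        beta = np.deg2rad(beta)
    h = np.eye(3)
    h[:2, :2] = rotation2d(beta)
    h[0, 2] = tx
    h[1, 2] = ty
    return h


def normalize_homography(h: np.ndarray) -> np.ndarray:
    """Return a copy scaled so h33 == 1; validate shape and invertibility."""
    h = np.asarray(h, dtype=float)
    if h.shape != (3, 3):
        raise ValueError(f"homography must be 3x3, got {h.shape}")
    if not np.all(np.isfinite(h)):
        raise ValueError("homography contains non-finite entries")
    if abs(h[2, 2]) < _DET_EPS:
        raise ProjectiveDegeneracyError("h33 is (numerically) zero; cannot normalize")
    h = h / h[2, 2]
    check_invertible(h)
    return h


def check_invertible(h: np.ndarray) -> None:
    if abs(np.linalg.det(h)) <= _DET_EPS:
        raise ValueError("homography is singular (|det| <= 1e-12)")


def default_corners(width: int, height: int) -> np.ndarray:
    """Patch corner coordinates in fixed order TL, TR, BR, BL.

    Corners sit on the outermost pixel centers, e.g. (127, 0) for a
    128-wide patch.
    """
    w, h = width - 1, height - 1
    return np.array([[0.0, 0.0], [w, 0.0], [w, float(h)], [0.0, float(h)]])


def _check_corner_geometry(corners: np.ndarray) -> None:
    """Reject coincident or collinear 4-corner configurations."""
    c = np.asarray(corners, dtype=float)
    if c.shape != (4, 2):
        raise ValueError(f"corners must be 4x2, got {c.shape}")
    for i in range(4):
        for j in range(i + 1, 4):
            if np.hypot(*(c[i] - c[j])) < 1e-9:
                raise DegenerateGeometryError(f"corners {i} and {j} coincide")
    # any 3 corners collinear -> degenerate for DLT
    for i in range(4):
        tri = np.delete(c, i, axis=0)
        u, v = tri[1] - tri[0], tri[2] - tri[0]
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        if area2 < 1e-9:
            raise DegenerateGeometryError("three corners are collinear")


@dataclass(frozen=True)
class FourPointHomography:
    """4-point homography: displacements of the four source corners.

    Attributes
    ----------
    corners : (4, 2) float array
        Source corner coordinates (u_i, v_i), fixed order TL, TR, BR, BL.
    displacements : (4, 2) float array
        Per-corner displacements (du_i, dv_i), pixels.
    """

    corners: np.ndarray
    displacements: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.corners, dtype=float)
        d = np.asarray(self.displacements, dtype=float)
        _check_corner_geometry(c)
        if d.shape != (4, 2):
            raise ValueError(f"displacements must be 4x2, got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacements contain non-finite values")
        object.__setattr__(self, "corners", c)
        object.__setattr__(self, "displacements", d)

    @property
    def du(self) -> np.ndarray:
        return self.displacements[:, 0]

    @property
    def dv(self) -> np.ndarray:
        return self.displacements[:, 1]

    @property
    def displaced_corners(self) -> np.ndarray:
        return self.corners + self.displacements

    def to_flat(self) -> np.ndarray:
        """(du1, dv1, ..., du4, dv4) — the serialized / regression order."""
        return self.displacements.reshape(-1).copy()

    @classmethod
    def from_flat(cls, flat: Sequence[float], corners: np.ndarray) -> "FourPointHomography":
        d = np.asarray(flat, dtype=float).reshape(4, 2)
        return cls(corners=np.asarray(corners, dtype=float), displacements=d)

    @classmethod
    def zero(cls, corners: np.ndarray) -> "FourPointHomography":
        return cls(corners=np.asarray(corners, dtype=float), displacements=np.zeros((4, 2)))


@dataclass(frozen=True)
class DecomposedHomography:
    """Rotation–scale–rotation (+ translation) affine decomposition.

    The 2x2 linear block is ``R(theta) @ diag(s_g, s_h) @ R(gamma)`` in
    the package rotation convention; ``t_x, t_y`` are taken directly
    from h13, h23.  Canonical form: ``s_g >= s_h > 0``; for isotropic
    blocks the whole rotation lives in ``theta`` and ``gamma == 0``;
    otherwise ``theta`` is folded into (-pi/2, pi/2].
    """

    theta: float
    gamma: float
    s_g: float
    s_h: float
    t_x: float
    t_y: float

    def __post_init__(self):
        if not (self.s_g > 0 and self.s_h > 0):
            raise DecompositionError("scales must be strictly positive")
        for name in ("theta", "gamma"):
            a = getattr(self, name)
            if not (-np.pi < a <= np.pi + 1e-15):
                raise ValueError(f"{name} must lie in (-pi, pi], got {a}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.gamma, self.s_g, self.s_h, self.t_x, self.t_y])


def fourpt_to_matrix(fp: FourPointHomography) -> np.ndarray:
    """Convert 4-point form to the 3x3 matrix via the DLT.

    Uses Hartley-normalized direct linear transform on the four exact
    corner correspondences; for non-degenerate corners the result
    reproduces each correspondence to well below 1e-8 px.
    """
    src = fp.corners
    dst = fp.displaced_corners
    _check_corner_geometry(src)
    try:
        _check_corner_geometry(dst)
    except DegenerateGeometryError as e:
        raise DegenerateGeometryError(f"displaced corners degenerate: {e}") from e
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        ok = bool(tform)
    else:  # older scikit-image
        tform = ProjectiveTransform()
        ok = tform.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise DegenerateGeometryError("DLT failed on the given correspondences")
    return normalize_homography(tform.params)


def matrix_to_fourpt(h: np.ndarray, corners: np.ndarray) -> FourPointHomography:
    """Convert a 3x3 homography to 4-point form at the given source corners."""
    h = normalize_homography(h)
    corners = np.asarray(corners, dtype=float)
    mapped = apply_homography(h, corners)
    return FourPointHomography(corners=corners, displacements=mapped - corners)


def apply_homography(h: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map 2D points through a homography with projective division.

    Raises
    ------
    ProjectiveDegeneracyError
        if a point's homogeneous denominator vanishes (names its index).
    """
    h = np.asarray(h, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    hom = np.hstack([pts, ones]) @ h.T
    w = hom[:, 2]
    bad = np.nonzero(np.abs(w) < _DET_EPS)[0]
    if bad.size:
        raise ProjectiveDegeneracyError(
            f"point index {int(bad[0])} maps to infinity (denominator ~ 0)"
        )
    out = hom[:, :2] / w[:, None]
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def compose_relative(pairwise: Sequence[np.ndarray], reference_index: int = 0) -> list:
    """Accumulate pairwise homographies into per-frame relative homographies.

    ``pairwise[i]`` maps frame ``i+1`` coordinates into frame ``i``
    coordinates.  The returned list has one entry per frame (length
    ``len(pairwise) + 1``); entry ``j`` maps frame ``j`` into the
    reference frame (the mosaic plane), and the entry at
    ``reference_index`` is the identity.
    """
    pairwise = [normalize_homography(h) for h in pairwise]
    if len(pairwise) == 0:
        raise ValueError("empty pairwise homography list")
    n_frames = len(pairwise) + 1
    if not (0 <= reference_index < n_frames):
        raise ValueError(f"reference_index {reference_index} out of range for {n_frames} frames")
    relative = [None] * n_frames
    relative[reference_index] = np.eye(3)
    for j in range(reference_index + 1, n_frames):
        relative[j] = normalize_homography(relative[j - 1] @ pairwise[j - 1])
    for j in range(reference_index - 1, -1, -1):
        relative[j] = normalize_homography(relative[j + 1] @ np.linalg.inv(pairwise[j]))
    return relative


def decompose(h: np.ndarray) -> DecomposedHomography:
    """Decompose an (affine) homography into rotation–scale–rotation + translation.

    The 2x2 block is factored by SVD as ``R(theta) diag(s_g, s_h)
    R(gamma)``; the translation is read off h13, h23 directly.  The
    projective row is ignored (a warning is emitted when |h31| or |h32|
    exceeds 1e-3, i.e. the affine assumption is visibly violated).

    Canonicalization makes the decomposition a true function: sign
    factors are folded into the angles so both scales are positive,
    isotropic blocks put the whole rotation into ``theta`` (gamma = 0),
    and otherwise ``theta`` is reduced to (-pi/2, pi/2] using the
    (theta, gamma) -> (theta + pi, gamma + pi) gauge freedom.
    """
    h = normalize_homography(h)
    if abs(h[2, 0]) > AFFINE_TOL or abs(h[2, 1]) > AFFINE_TOL:
        warnings.warn(
            "homography is visibly non-affine (|h31| or |h32| > 1e-3); "
            "decomposition ignores the projective row",
            stacklevel=2,
        )
    a = h[:2, :2]
    det = np.linalg.det(a)
    if abs(det) < _DET_EPS:
        raise DecompositionError("2x2 linear block is singular")
    if det < 0:
        raise DecompositionError(
            "2x2 block is orientation-reversing; rotation-scale-rotation "
            "with positive scales cannot represent a reflection"
        )
    u, s, vt = np.linalg.svd(a)
    # det(a) > 0 so u and vt are both rotations or both reflections;
    # fold the common reflection into the second singular direction.
    if np.linalg.det(u) < 0:
        u = u.copy()
        vt = vt.copy()
        u[:, 1] *= -1.0
        vt[1, :] *= -1.0
    # R(b) = [[cos b, sin b], [-sin b, cos b]]  =>  b = atan2(R[0,1], R[0,0])
    theta = np.arctan2(u[0, 1], u[0, 0])
    gamma = np.arctan2(vt[0, 1], vt[0, 0])
    s_g, s_h = float(s[0]), float(s[1])
    if abs(s_g - s_h) < 1e-10:
        # isotropic block: only theta + gamma is determined; put it all in theta
        theta = wrap_angle(theta + gamma)
        gamma = 0.0
    elif not (-np.pi / 2 < theta <= np.pi / 2):
        theta = wrap_angle(theta + np.pi)
        gamma = wrap_angle(gamma + np.pi)
    return DecomposedHomography(
        theta=wrap_angle(theta),
        gamma=wrap_angle(gamma),
        s_g=s_g,
        s_h=s_h,
        t_x=float(h[0, 2]),
        t_y=float(h[1, 2]),
    )


def rotation_angle(h: np.ndarray) -> float:
    """Total in-plane rotation of the 2x2 block (radians, package convention).

    This is the angle of the polar-decomposition rotation factor,
    ``theta + gamma`` of :func:`decompose`.  Unlike ``theta`` alone —
    whose split against ``gamma`` is ill-conditioned when the two
    scales are nearly equal — the total rotation is a stable function
    of the matrix, so it is the right quantity for comparing the
    rotation content of two near-rigid homographies.
    """
    h = np.asarray(h, dtype=float)
    a = h[:2, :2]
    if np.linalg.det(a) <= 0:
        raise DecompositionError("2x2 block must be orientation-preserving")
    u, _, vt = np.linalg.svd(a)
    r = u @ vt
    if np.linalg.det(r) < 0:  # fold the common reflection out
        u = u.copy()
        u[:, 1] *= -1.0
        r = u @ vt
    return float(np.arctan2(r[0, 1], r[0, 0]))


def recompose(d: DecomposedHomography) -> np.ndarray:
    """Rebuild the affine homography from its decomposition (bottom row 0,0,1)."""
    if not (d.s_g > 0 and d.s_h > 0):
        raise DecompositionError("scales must be strictly positive")
    a = rotation2d(d.theta) @ np.diag([d.s_g, d.s_h]) @ rotation2d(d.gamma)
    h = np.eye(3)
    h[:2, :2] = a
    h[0, 2] = d.t_x
    h[1, 2] = d.t_y
    return h
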