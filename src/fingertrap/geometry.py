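"""Low-level rigid-body and backbone geometry helpers.

Rotations are handled through :class:`scipy.spatial.transform.Rotation`;
this module only adds the small amount of glue the rest of the package
needs: a rigid-transform container, Kabsch superposition on paired point
sets, torsion angles, and an internal-coordinate (NeRF) backbone builder
used for helical linkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

# Ideal backbone internal coordinates (Engh & Huber averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = np.deg2rad(111.2)
ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)

ALPHA_PHI = -57.0
ALPHA_PSI = -47.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` (Å)."""

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if np.max(np.abs(rot @ rot.T - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(
        cls, axis: np.ndarray, angle_deg: float, point: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``point`` along ``axis``."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        if point is None:
            return cls(rot, np.zeros(3))
        point = np.asarray(point, dtype=float)
        return cls(rot, point - rot @ point)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of paired point sets.

    Returns the proper rigid transform that maps ``mobile`` onto
    ``reference`` with minimal RMSD, together with that RMSD (Å).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be paired (n, 3) arrays of equal shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 point pairs")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    mob_c = mobile - mob_center
    ref_c = reference - ref_center
    # Degenerate (collinear) sets leave a rotational degree of freedom.
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = float(rssd) / np.sqrt(n)
    matrix = rot.as_matrix()
    transform = RigidTransform(matrix, ref_center - matrix @ mob_center)
    return transform, rmsd


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    m = np.cross(n0, b1 / np.linalg.norm(b1))
    angle = -np.degrees(np.arctan2(np.dot(m, n1), np.dot(n0, n1)))
    return float(-180.0 if np.isclose(angle, 180.0) else angle)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: position d with given c-d bond, b-c-d angle (rad)
    and a-b-c-d torsion (degrees)."""
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def extend_backbone(seed: np.ndarray, phis: np.ndarray, psis: np.ndarray,
                    seed_psi: float = ALPHA_PSI) -> np.ndarray:
    """NeRF backbone growth honouring phi and psi torsions.

    ``seed`` is the previous residue's (N, CA, C); ``phis[i]``/``psis[i]``
    are the torsions of appended residue i (psi of residue i orients the
    N of residue i+1, psi of the seed residue is ``seed_psi``).  Omega is
    fixed trans.  Returns an (n, 3, 3) array of (N, CA, C) coordinates.
    """
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    psis = np.atleast_1d(np.asarray(psis, dtype=float))
    if phis.shape != psis.shape:
        raise ValueError("phi and psi series must have equal length")
    prev_n, prev_ca, prev_c = (np.asarray(a, dtype=float) for a in seed)
    out = np.empty((len(phis), 3, 3))
    for i in range(len(phis)):
        psi_prev = psis[i - 1] if i > 0 else seed_psi
        # N(i): dihedral(N(i-1), CA(i-1), C(i-1), N(i)) is psi(i-1).
        n = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        # CA(i): omega torsion (CA(i-1)-C(i-1)-N(i)) fixed trans.
        ca = place_atom(prev_ca, prev_c, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        # C(i): phi torsion (C(i-1)-N(i)-CA(i)).
        c = place_atom(prev_c, n, ca, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        out[i] = (n, ca, c)
        prev_n, prev_ca, prev_c = n, ca, c
    return out


def residue_frame(backbone: np.ndarray) -> RigidTransform:
    """Orthonormal frame attached to one residue's (N, CA, C) backbone."""
    n, ca, c = (np.asarray(a, dtype=float) for a in backbone)
    x = c - ca
    x /= np.linalg.norm(x)
    v = n - ca
    y = v - np.dot(v, x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return RigidTransform(np.column_stack([x, y, z]), ca)


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis (unit vector) of a point cloud."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
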