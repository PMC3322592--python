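"""Rigid-body superposition and ideal-geometry completion of mainchain atoms.

Superposition is the closed-form Kabsch solution (SVD with determinant correction
so only proper rotations are returned — a mirror image can never superpose onto a
chiral fragment).  A batched variant serves the fragment-search re-scoring stage,
which superposes thousands of small point sets per query.

N, Calpha and C positions determine the remaining mainchain atoms: Cbeta sits at
the ideal tetrahedral position off Calpha and the carbonyl O lies in the peptide
plane defined by Calpha, C and the next residue's N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGLE_N_CA_CB,
    BOND_C_O,
    BOND_CA_CB,
)


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too degenerate for a unique construction."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t`` in orthogonal angstrom coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(rot) < 0:
            raise ValueError("improper rotation (det < 0) is not a rigid motion here")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_3x4(self) -> list[list[float]]:
        """Row-major 3x4 [R | t] matrix for JSON reports."""
        return np.hstack([self.rotation, self.translation[:, None]]).tolist()

    @classmethod
    def from_3x4(cls, mat) -> "RigidTransform":
        m = np.asarray(mat, dtype=float).reshape(3, 4)
        return cls(m[:, :3], m[:, 3])


def superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of `moving` onto `fixed` over proper rotations.

    Returns the transform minimising sum |R m + t - f|^2 and the minimised RMSD.
    Requires at least 3 points; collinear point sets (second singular value of the
    cross-covariance below 1e-8) raise :class:`DegenerateGeometryError` because the
    rotation about the common line is undetermined.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must both be (n, 3) arrays")
    if len(moving) < 3:
        raise ValueError("superposition needs at least 3 points")
    if not (np.isfinite(moving).all() and np.isfinite(fixed).all()):
        raise ValueError("coordinates contain NaN/inf")
    rots, trans, rmsds = superpose_many(moving[None], fixed, check_degenerate=True)
    return RigidTransform(rots[0], trans[0]), float(rmsds[0])


def superpose_many(
    moving_batch: np.ndarray,
    fixed: np.ndarray,
    check_degenerate: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Kabsch: superpose each of `moving_batch` (m, k, 3) onto `fixed` (k, 3).

    Returns (rotations (m,3,3), translations (m,3), rmsds (m,)).  Mirror solutions
    are rejected by flipping the sign of the smallest singular vector whenever the
    determinant of the raw solution is negative.
    """
    mb = np.asarray(moving_batch, dtype=float)
    fx = np.asarray(fixed, dtype=float)
    cf = fx.mean(axis=0)
    f0 = fx - cf
    cm = mb.mean(axis=1)
    m0 = mb - cm[:, None, :]
    # cross-covariance per batch item: (3, 3)
    h = np.einsum("bki,kj->bij", m0, f0)
    u, s, vt = np.linalg.svd(h)
    if check_degenerate and np.any(s[:, 1] < 1e-8):
        raise DegenerateGeometryError("collinear point set: rotation undetermined")
    det = np.linalg.det(np.einsum("bij,bjk->bik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    d = np.ones_like(u[..., 0])
    d[..., -1] = np.sign(det)
    # R = V diag(1,1,det) U^T
    rot = np.einsum("bij,bj,bkj->bik", np.transpose(vt, (0, 2, 1)), d, u)
    trans = cf - np.einsum("bij,bj->bi", rot, cm)
    moved = np.einsum("bij,bkj->bki", rot, mb) + trans[:, None, :]
    rmsds = np.sqrt(np.mean(np.sum((moved - fx) ** 2, axis=2), axis=1))
    return rot, trans, rmsds


@dataclass(frozen=True)
class IdealGeometry:
    """Fixed ideal-geometry constants used to complete mainchain atoms.

    These are documented constants, not fitted values: ``d_ca_cb`` and ``d_c_o``
    are standard Engh–Huber-style bond lengths, ``o_angle`` the Calpha-C-O angle
    and ``cb_angle`` the N-Calpha-Cbeta tetrahedral angle (degrees).
    """

    d_ca_cb: float = BOND_CA_CB
    d_c_o: float = BOND_C_O
    o_angle: float = 121.0
    cb_angle: float = ANGLE_N_CA_CB


IDEAL = IdealGeometry()


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-8:
        raise DegenerateGeometryError(f"degenerate geometry: zero-length {what}")
    return v / n


def place_cbeta(n_xyz, ca_xyz, c_xyz, res_type: str = "A"):
    """Ideal tetrahedral Cbeta position from the mainchain N, Calpha, C.

    Returns ``None`` for glycine (no Cbeta).  The construction is frame-local:
    the Cbeta direction makes the ideal N-Calpha-Cbeta angle with both the
    Calpha->N and Calpha->C bonds, on the side giving an L-amino acid.
    """
    if res_type in ("G", "GLY"):
        return None
    n_xyz = np.asarray(n_xyz, dtype=float)
    ca = np.asarray(ca_xyz, dtype=float)
    c_xyz = np.asarray(c_xyz, dtype=float)
    u = _unit(n_xyz - ca, "Calpha-N bond")
    v = _unit(c_xyz - ca, "Calpha-C bond")
    cross = np.cross(u, v)
    if np.linalg.norm(cross) < 1e-8:
        raise DegenerateGeometryError("N, Calpha, C are collinear")
    cos_t = np.cos(np.deg2rad(IDEAL.cb_angle))
    # direction = p (u + v) + s (u x v);  p from the two equal angle constraints
    p = cos_t / (1.0 + u @ v)
    base = p * (u + v)
    s_sq = (1.0 - base @ base) / (cross @ cross)
    if s_sq <= 0:
        raise DegenerateGeometryError("cannot place Cbeta: angle constraints infeasible")
    # positive sign on the cross term selects the L-configuration
    direction = base + np.sqrt(s_sq) * cross
    return ca + IDEAL.d_ca_cb * direction


def place_oxygen(ca_xyz, c_xyz, n_next_xyz):
    """Carbonyl O in the peptide plane, trans to Calpha across C.

    O lies along the outward bisector of the Calpha-C-N(next) angle, in the plane
    of the three input atoms, at the ideal C=O distance — the standard planar
    sp2 construction (both flanking angles come out near 121-122 degrees).
    """
    ca = np.asarray(ca_xyz, dtype=float)
    c = np.asarray(c_xyz, dtype=float)
    n_next = np.asarray(n_next_xyz, dtype=float)
    u = _unit(ca - c, "C-Calpha bond")
    v = _unit(n_next - c, "C-N bond")
    if np.linalg.norm(np.cross(u, v)) < 1e-8:
        raise DegenerateGeometryError("Calpha, C, N(next) are collinear")
    direction = _unit(-(u + v), "carbonyl bisector")
    return c + IDEAL.d_c_o * direction
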