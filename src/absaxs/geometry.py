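"""Rigid-body and internal-coordinate primitives.

Everything downstream (Monte Carlo sampling, complex assembly, scattering)
reduces to the handful of operations here: radius of gyration, least-squares
superposition (Kabsch), minimum inter-structure distance, three-point angles
and backbone torsion rotations.

Conventions
-----------
* Coordinates are Angstrom throughout.
* Dihedral angles follow the IUPAC convention: cis = 0 deg, positive when the
  far bond rotates clockwise viewed from the first toward the fourth atom.
* "Downstream" of a phi/psi bond means all atoms C-terminal of the rotated
  bond within the same chain; inter-chain links are not treated as
  connectivity (the antibody model has structurally independent Fab domains
  and hinge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structio import Structure

__all__ = [
    "Transform",
    "radius_of_gyration",
    "superpose",
    "min_pair_distance",
    "three_point_angle",
    "apply_torsion",
    "measure_dihedral",
    "rotation_about_axis",
]


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3, translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValidationError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def apply_structure(self, s: Structure) -> Structure:
        return s.with_coord(self.apply(s.coord))

    def compose(self, other: "Transform") -> "Transform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        Rt = self.rotation.T
        return Transform(Rt, -Rt @ self.translation)


def radius_of_gyration(s: Structure, weights: np.ndarray | None = None) -> float:
    """Weighted radius of gyration, Rg^2 = sum w |r - rbar|^2 / sum w."""
    if s.n_atoms == 0:
        raise ValidationError("radius of gyration of empty structure")
    xyz = s.coord
    if weights is None:
        w = np.ones(len(xyz))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (len(xyz),) or np.any(w <= 0):
            raise ValidationError("weights must be positive, one per atom")
    center = (w[:, None] * xyz).sum(axis=0) / w.sum()
    d2 = ((xyz - center) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> Transform:
    """Least-squares proper rotation + translation mapping mobile onto ref."""
    mc = mobile_xyz.mean(axis=0)
    rc = ref_xyz.mean(axis=0)
    H = (mobile_xyz - mc).T @ (ref_xyz - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return Transform(R, t)


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: tuple[np.ndarray, np.ndarray],
) -> tuple[Transform, float]:
    """Optimal rigid superposition of paired selections (Kabsch).

    Parameters
    ----------
    selection : (mobile_indices, reference_indices)
        Equal-length paired atom index arrays, >= 3 non-collinear points.

    Returns
    -------
    (Transform, rmsd)
        The transform maps *all* coordinates of ``mobile`` into the reference
        frame; the RMSD is evaluated over the selection after applying it.
    """
    mi, ri = (np.asarray(x, dtype=np.intp) for x in selection)
    if len(mi) != len(ri):
        raise ValidationError("paired selections must have equal size")
    if len(mi) < 3:
        raise ValidationError("superposition needs >= 3 paired atoms")
    a = mobile.coord[mi]
    b = reference.coord[ri]
    for xyz in (a, b):
        centered = xyz - xyz.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValidationError("degenerate (collinear/coincident) selection")
    T = _kabsch(a, b)
    rmsd = float(np.sqrt(((T.apply(a) - b) ** 2).sum(axis=1).mean()))
    return T, rmsd


def min_pair_distance(a: Structure, b: Structure) -> float:
    """Minimum distance over all inter-structure atom pairs."""
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValidationError("min_pair_distance of empty structure")
    # KD-tree on the larger set; exact nearest-neighbour query
    small, large = (a.coord, b.coord) if a.n_atoms <= b.n_atoms else (b.coord, a.coord)
    tree = cKDTree(large)
    d, _ = tree.query(small, k=1)
    return float(d.min())


def three_point_angle(p1, vertex, p2) -> float:
    """Angle p1-vertex-p2 in degrees, in [0, 180]."""
    v1 = np.asarray(p1, dtype=np.float64) - np.asarray(vertex, dtype=np.float64)
    v2 = np.asarray(p2, dtype=np.float64) - np.asarray(vertex, dtype=np.float64)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValidationError("coincident points in angle computation")
    c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def rotation_about_axis(
    point: np.ndarray, axis: np.ndarray, angle_deg: float
) -> Transform:
    """Proper rotation by ``angle_deg`` about the line through ``point`` along ``axis``."""
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValidationError("zero-length rotation axis")
    u = axis / n
    theta = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    point = np.asarray(point, dtype=np.float64)
    return Transform(R, point - R @ point)


def measure_dihedral(p1, p2, p3, p4) -> float:
    """IUPAC dihedral angle in degrees for the four points."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


_PHI_FIXED_NAMES = {"N", "H", "HN", "H1", "H2", "H3"}
_PSI_MOVING_NAMES = {"O", "OXT"}


def _torsion_atoms(s: Structure, chain: str, res: int, angle_name: str):
    """Axis atom indices and downstream mover indices for a phi/psi pivot."""
    angle = angle_name.lower().replace("φ", "phi").replace("ψ", "psi")
    if angle not in ("phi", "psi"):
        raise ValidationError(f"unknown torsion name {angle_name!r}")
    in_chain = s.chain_id == chain
    res_mask = in_chain & (s.res_id == res)
    if not res_mask.any():
        raise ValidationError(f"no residue {res} in chain {chain!r}")

    def _one(name: str) -> int:
        idx = np.flatnonzero(res_mask & (s.atom_name == name))
        if len(idx) != 1:
            raise ValidationError(
                f"residue {chain}/{res} lacks a unique backbone atom {name!r}"
            )
        return int(idx[0])

    i_n, i_ca, i_c = _one("N"), _one("CA"), _one("C")
    downstream = in_chain & (s.res_id > res)
    if angle == "phi":
        axis = (i_n, i_ca)
        within = res_mask & ~np.isin(s.atom_name, list(_PHI_FIXED_NAMES | {"CA"}))
    else:
        axis = (i_ca, i_c)
        within = res_mask & np.isin(s.atom_name, list(_PSI_MOVING_NAMES))
    movers = np.flatnonzero(downstream | within)
    return axis, movers


def apply_torsion(
    s: Structure, pivot: tuple[str, int, str], delta: float
) -> Structure:
    """Rotate all atoms downstream of a phi/psi bond by ``delta`` degrees.

    The pivot is (chain_id, residue_number, "phi"|"psi"). Bond lengths and
    bond angles are preserved exactly; only the named dihedral (and rigid
    geometry downstream of it) changes. The measured dihedral increases by
    ``delta`` under the IUPAC sign convention.
    """
    chain, res, angle_name = pivot
    (i_a, i_b), movers = _torsion_atoms(s, chain, res, angle_name)
    if movers.size == 0:
        return s.copy()
    pa, pb = s.coord[i_a], s.coord[i_b]
    # IUPAC positive = clockwise viewed a->b, i.e. a negative right-hand
    # rotation of the C-terminal side about the a->b axis
    T = rotation_about_axis(pa, pb - pa, -delta)
    coord = s.coord.copy()
    coord[movers] = T.apply(coord[movers])
    return s.with_coord(coord)
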