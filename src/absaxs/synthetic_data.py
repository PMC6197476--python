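"""Toy structures and synthetic "experimental" data.

Every pipeline stage is exercised on a self-contained toy world instead of
undeposited instrument data:

* a Y-shaped three-domain antibody (two Fab pseudo-domains and one Fc joined
  by two polypeptide hinges with ideal backbone geometry, so phi/psi pivots
  are real torsions),
* a D2-symmetric four-subunit antigen (the tetramer stand-in),
* rigid docked Fab-antigen poses (standing in for docking-protocol output),
* noisy scattering profiles of known ground-truth structures.

Pseudo-domains are carbon-like point scatterers on a jittered cubic lattice
inside a sphere: cheap Debye sums with realistic Rg and P(r) shapes. Every
generator is a pure function of (config, seed). The default tetramer sits
near Rg 27 A (the real antigen's scale); the default antibody near Rg 28 A.
The antibody's proportions are chosen for *internal consistency with the
assembly filters* rather than to match the real antibody's Rg: its two
hinge-proximal Fab anchor atoms sit ~34 A apart, so the 40 A ring-closure
rule is satisfiable by rings mirroring the built antibody, exactly as the
real molecule's short upper hinge places the two heavy-chain residue-211
C-alphas within that reach; and the arm angle matches the 109.47 deg the
antigen's D2 symmetry subtends between paired binding sites
(2 x 71 + 2 x 109.47 ~= 360 closes a planar ring).

Crucially, the Fab pseudo-domain is *canonical*: every Fab copy (standalone,
in an antibody, in a docked pose) carries identical internal coordinates and
atom order, so heavy-chain-style superpositions between copies are exact and
pairing selections by atom order is valid.
"""

from __future__ import annotations

import logging
import warnings as _warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .errors import PlacementError, ValidationError
from .geometry import (
    Transform,
    min_pair_distance,
    radius_of_gyration,
    rotation_about_axis,
)
from .structio import ScatteringProfile, Structure, concat_structures

logger = logging.getLogger(__name__)

__all__ = [
    "ToyBuildConfig",
    "NoiseModel",
    "make_toy_antibody",
    "make_toy_fab",
    "make_toy_fc",
    "make_toy_tetramer",
    "make_docked_pose",
    "make_synthetic_profile",
]

# ideal backbone geometry (Engh-Huber): bond lengths in A, angles in degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0
# extended-strand dihedrals used for the as-built hinge
PHI0 = -140.0
PSI0 = 135.0


@dataclass(frozen=True)
class ToyBuildConfig:
    """Geometry of the toy world.

    ``domain_radius`` is the pseudo-domain sphere radius (A);
    ``atoms_per_domain`` the pseudo-atom count per domain; ``hinge_length``
    the residue count of each hinge; ``lattice_spacing`` the cubic lattice
    pitch inside domains; ``arm_angle_deg`` the built Fab-Fc-Fab angle;
    ``antigen_subunit_radius``/``antigen_center_distance`` size and placement
    of the tetramer subunits (defaults reproduce the tetramer/antibody Rg
    scale of the real system).
    """

    domain_radius: float = 15.0
    atoms_per_domain: int = 80
    hinge_length: int = 3
    seed: int = 0
    lattice_spacing: float = 5.5
    arm_angle_deg: float = 71.0
    antigen_subunit_radius: float = 14.0
    antigen_center_distance: float = 24.75

    def __post_init__(self):
        if self.domain_radius <= 0:
            raise ValidationError("domain_radius must be positive")
        if self.atoms_per_domain < 10:
            raise ValidationError("atoms_per_domain must be >= 10")
        if self.hinge_length < 3:
            raise ValidationError("hinge_length must be >= 3")
        if self.lattice_spacing <= 0:
            raise ValidationError("lattice_spacing must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Counting-style noise: sigma(Q) = rel_floor * I(Q) * (1 + q_slope * Q).

    A relative floor with a Q-proportional growth term, emulating the
    monotone loss of signal-to-noise with Q in column-coupled scattering
    data. ``rel_floor = 0`` gives noiseless profiles with no sigma column.
    """

    rel_floor: float = 0.02
    q_slope: float = 5.0
    seed: int = 0

    def sigma(self, q: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        s = self.rel_floor * np.abs(intensity) * (1.0 + self.q_slope * np.asarray(q))
        if np.any(s <= 0):
            raise ValidationError("noise model produced nonpositive sigma")
        return s


# ---------------------------------------------------------------------------
# pseudo-domain construction
# ---------------------------------------------------------------------------


def _domain_ball(cfg: ToyBuildConfig, stream: str, radius: float | None = None) -> np.ndarray:
    """Canonical jittered-lattice point cloud inside a sphere, centred at 0.

    Deterministic for a given (cfg.seed, stream). The same stream name yields
    bit-identical coordinates, which is what makes Fab copies superposable
    exactly.
    """
    radius = cfg.domain_radius if radius is None else radius
    # stream tag hashed stably (process-independent) into the seed sequence
    rng = np.random.default_rng([cfg.seed % (2**31), zlib.crc32(stream.encode())])
    # keep the site count feasible for non-default radii
    spacing = cfg.lattice_spacing * radius / cfg.domain_radius
    jitter_max = 0.25 * spacing
    k = int(np.floor(radius / spacing))
    axis = np.arange(-k, k + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= radius - jitter_max
    pts = pts[inside]
    if len(pts) < cfg.atoms_per_domain:
        raise ValidationError(
            f"lattice too coarse: {len(pts)} sites < {cfg.atoms_per_domain} atoms; "
            "reduce lattice_spacing or atoms_per_domain"
        )
    chosen = rng.choice(len(pts), size=cfg.atoms_per_domain, replace=False)
    chosen.sort()
    cloud = pts[chosen] + rng.uniform(-jitter_max, jitter_max, size=(cfg.atoms_per_domain, 3))
    return cloud - cloud.mean(axis=0)


def _ball_structure(
    cloud: np.ndarray, chain: str, res_start: int = 1, res_name: str = "ALA"
) -> Structure:
    n = len(cloud)
    return Structure(
        serial=np.arange(1, n + 1),
        chain_id=np.full(n, chain),
        res_id=np.arange(res_start, res_start + n),
        res_name=np.full(n, res_name),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coord=cloud,
    )


def _fab_face_labels(cloud: np.ndarray) -> dict[str, np.ndarray]:
    """Canonical Fab labels in the local frame.

    +x is the outward (paratope) face; -x faces the hinge. ``paratope`` is
    the outer ~20% of atoms by x, ``fab_align`` the rest (the
    away-from-interface alignment region), ``fab_anchor`` the single
    hinge-proximal atom (the "residue 211 C-alpha" analogue).
    """
    x = cloud[:, 0]
    cut = np.quantile(x, 0.8)
    paratope = np.flatnonzero(x >= cut)
    align = np.flatnonzero(x < cut)
    anchor = np.array([int(np.argmin(x))])
    return {"paratope": paratope, "fab_align": align, "fab_anchor": anchor}


# ---------------------------------------------------------------------------
# hinge construction (NeRF internal-coordinate building)
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position d with |c-d| = bond, angle(b,c,d) and dihedral(a,b,c,d) given."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = bond * np.array(
        [
            -np.cos(ang),
            np.sin(ang) * np.cos(dih),
            np.sin(ang) * np.sin(dih),
        ]
    )
    basis = np.column_stack([bc, m, n])
    return c + basis @ d_local


def _hinge_backbone(n_res: int) -> np.ndarray:
    """(3 n_res, 3) extended backbone (N, CA, C per residue), ideal geometry."""
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([BOND_N_CA, 0.0, 0.0]),
    ]
    # first C placed in the xy-plane
    ang = np.radians(ANGLE_N_CA_C)
    coords.append(
        coords[1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    )
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, PSI0)
        ca_new = _place_atom(ca_prev, c_prev, n_new, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_new = _place_atom(c_prev, n_new, ca_new, BOND_CA_C, ANGLE_N_CA_C, PHI0)
        coords.extend([n_new, ca_new, c_new])
    return np.asarray(coords)


def _hinge_structure(n_res: int, chain: str) -> Structure:
    xyz = _hinge_backbone(n_res)
    n_atoms = len(xyz)
    return Structure(
        serial=np.arange(1, n_atoms + 1),
        chain_id=np.full(n_atoms, chain),
        res_id=np.repeat(np.arange(1, n_res + 1), 3),
        res_name=np.full(n_atoms, "GLY"),
        atom_name=np.tile(["N", "CA", "C"], n_res),
        element=np.tile(["N", "C", "C"], n_res),
        coord=xyz,
    )


def _align_x_to(u: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +x to the unit vector u (minimal rotation)."""
    x = np.array([1.0, 0.0, 0.0])
    u = u / np.linalg.norm(u)
    v = np.cross(x, u)
    c = float(x @ u)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([-1.0, 1.0, -1.0])  # 180 deg about y
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _fab_cloud(cfg: ToyBuildConfig) -> np.ndarray:
    """Canonical Fab point cloud: jittered ball plus an exact anchor atom.

    The hinge-proximal anchor (the "residue 211 C-alpha" analogue) is pinned
    to the -x pole at 1.5 A inside the sphere so its position -- which the
    ring-closure filter measures -- is a deterministic feature of the domain
    geometry rather than an accident of the lattice subset.
    """
    cloud = _domain_ball(cfg, "fab")
    i = int(np.argmin(cloud[:, 0]))
    cloud[i] = np.array([-(cfg.domain_radius - 1.5), 0.0, 0.0])
    return cloud


def make_toy_fab(cfg: ToyBuildConfig) -> Structure:
    """Canonical standalone Fab pseudo-domain with paratope/alignment labels."""
    cloud = _fab_cloud(cfg)
    s = _ball_structure(cloud, chain="A")
    s.labels = {"fab": np.arange(len(cloud)), **_fab_face_labels(cloud)}
    return s


def make_toy_fc(cfg: ToyBuildConfig) -> Structure:
    """Standalone Fc pseudo-domain building block."""
    cloud = _domain_ball(cfg, "fc")
    s = _ball_structure(cloud, chain="F")
    s.labels = {"fc": np.arange(len(cloud))}
    return s


def make_toy_antibody(cfg: ToyBuildConfig) -> Structure:
    """Y-shaped three-domain toy antibody with torsion-capable hinges.

    Chains: F = Fc; A = hinge1 + Fab1; B = hinge2 + Fab2. Hinge residues are
    1..hinge_length with N/CA/C backbone at ideal geometry; Fab pseudo-atoms
    follow as one-atom residues so "downstream of a hinge pivot" carries the
    whole arm. Labels: Fc, hinge1/2, Fab1/2, paratope1/2, fab1/2_align,
    fab1/2_anchor and the heavy-chain residues-1-211 analogue. The available
    phi/psi pivots of the middle hinge residues are recorded in
    ``meta["default_pivots"]``.
    """
    fc = _ball_structure(_domain_ball(cfg, "fc"), chain="F")
    fc.labels = {"Fc": np.arange(fc.n_atoms)}
    half = np.radians(cfg.arm_angle_deg / 2.0)
    directions = {
        "1": np.array([np.sin(half), np.cos(half), 0.0]),
        "2": np.array([-np.sin(half), np.cos(half), 0.0]),
    }
    fab_cloud = _fab_cloud(cfg)
    face = _fab_face_labels(fab_cloud)
    arms = []
    L = cfg.hinge_length
    for arm_id, chain in (("1", "A"), ("2", "B")):
        u = directions[arm_id]
        hinge = _hinge_structure(L, chain=chain)
        # orient the as-built hinge so its end-to-end vector runs along u
        ete = hinge.coord[-1] - hinge.coord[0]
        Ru = _align_x_to(u) @ _align_x_to(ete / np.linalg.norm(ete)).T
        start = (cfg.domain_radius + 1.5) * u
        hinge_xyz = (hinge.coord - hinge.coord[0]) @ Ru.T + start
        hinge = hinge.with_coord(hinge_xyz)
        # Fab ball: -x side (anchor) toward the hinge end, +x (paratope) outward
        Rf = _align_x_to(u)
        end = hinge_xyz[-1]
        fab_center = end + (1.5 + cfg.domain_radius) * u
        fab_xyz = fab_cloud @ Rf.T + fab_center
        fab = _ball_structure(fab_xyz, chain=chain, res_start=L + 1)
        arm = concat_structures([hinge, fab], rechain=False)
        off = hinge.n_atoms
        arm.labels = {
            f"hinge{arm_id}": np.arange(hinge.n_atoms),
            f"Fab{arm_id}": off + np.arange(fab.n_atoms),
            f"paratope{arm_id}": off + face["paratope"],
            f"fab{arm_id}_align": off + face["fab_align"],
            f"fab{arm_id}_anchor": off + face["fab_anchor"],
        }
        arms.append(arm)
    ab = concat_structures([fc, arms[0], arms[1]], rechain=False)
    # re-number serials once; labels already merged by concat
    mid = (L + 1) // 2
    pivot_res = [r for r in (mid - 1, mid, mid + 1) if 2 <= r <= L - 1] or [2]
    ab.meta["default_pivots"] = tuple(
        (chain, r, ang)
        for chain in ("A", "B")
        for r in pivot_res
        for ang in ("phi", "psi")
    )
    ab.labels["heavy1_res1_211-analogue"] = ab.labels["Fab1"]
    ab.meta["build_config"] = cfg
    ab.meta["fab_fc_separation"] = float(
        np.linalg.norm(
            ab.centroid(ab.labels["Fab1"]) - ab.centroid(ab.labels["Fc"])
        )
    )
    return ab


def make_toy_tetramer(cfg: ToyBuildConfig) -> Structure:
    """Four identical subunits with exact D2 symmetry about the origin.

    Subunit 1 sits at a generic centre; subunits 2-4 are its images under
    180-degree rotations about z, x and y. The two recorded generators of the
    point group are available in ``meta["symmetry_axes"]`` (z and x; the
    third axis is their product), with ``meta["symmetry_center"]`` at the
    origin. The centre of mass is exactly zero by construction.
    """
    cloud = _domain_ball(cfg, "subunit", radius=cfg.antigen_subunit_radius)
    c0 = cfg.antigen_center_distance * np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    rots = [
        np.eye(3),
        np.diag([-1.0, -1.0, 1.0]),  # 180 about z
        np.diag([1.0, -1.0, -1.0]),  # 180 about x
        np.diag([-1.0, 1.0, -1.0]),  # 180 about y
    ]
    parts = []
    for i, (R, chain) in enumerate(zip(rots, "WXYZ"), start=1):
        xyz = (cloud + c0) @ R.T
        sub = _ball_structure(xyz, chain=chain)
        sub.labels = {f"sub{i}": np.arange(len(xyz))}
        parts.append(sub)
    ag = concat_structures(parts, rechain=False)
    ag.labels["antigen_all"] = np.arange(ag.n_atoms)
    ag.meta["symmetry_axes"] = (
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    ag.meta["symmetry_center"] = np.zeros(3)
    ag.meta["build_config"] = cfg
    return ag


def make_docked_pose(
    ab: Structure,
    ag: Structure,
    subunit: str,
    gap: float = 4.0,
    seed: int = 0,
    max_retries: int = 20,
) -> Structure:
    """Rigidly place a Fab so its paratope face sits ``gap`` A from a subunit.

    Stands in for docking-protocol output: the Fab's paratope normal is
    pointed at the chosen antigen subunit, given a seeded random spin about
    the approach axis, and translated along the approach axis until the
    minimum Fab-antigen atom distance equals ``gap`` (bisection to 0.02 A).
    The antigen keeps its own (symmetry-recorded) frame.

    Returns the combined pose with unit labels ``fab`` and ``antigen`` (inner
    labels namespaced, e.g. ``fab:paratope``).
    """
    if "paratope" not in ab.labels:
        raise ValidationError('ab needs a "paratope" label')
    sub_idx = ag.label_indices(subunit)
    rng = np.random.default_rng(seed)
    ag_center = np.asarray(ag.meta.get("symmetry_center", ag.centroid()))
    u = ag.centroid(sub_idx) - ag_center
    if np.linalg.norm(u) < 1e-9:
        raise ValidationError("subunit centroid coincides with antigen centre")
    u /= np.linalg.norm(u)
    fab_center = ab.centroid()
    v = ab.centroid(ab.labels["paratope"]) - fab_center
    v /= np.linalg.norm(v)
    sub_surface = ag.centroid(sub_idx)
    for attempt in range(max_retries):
        spin = rng.uniform(0.0, 360.0)
        R = _align_x_to(-u) @ _align_x_to(v).T  # v -> -u
        Rspin = rotation_about_axis(np.zeros(3), u, spin).rotation
        Rtot = Rspin @ R
        local = (ab.coord - fab_center) @ Rtot.T
        # slide along +u until min distance hits the gap
        probe = ab.with_coord(local)

        def mind(t: float) -> float:
            return min_pair_distance(probe.with_coord(local + sub_surface + t * u), ag)

        t_lo, t_hi = 0.0, 8.0 * (gap + np.ptp(local) + 1.0)
        if mind(t_lo) > gap:
            t_lo = -t_hi
            if mind(t_lo) > gap:
                continue  # cannot approach; respin
        if mind(t_hi) < gap:
            continue
        for _ in range(60):
            t_mid = 0.5 * (t_lo + t_hi)
            if mind(t_mid) < gap:
                t_lo = t_mid
            else:
                t_hi = t_mid
            if t_hi - t_lo < 1e-4:
                break
        placed = probe.with_coord(local + sub_surface + t_hi * u)
        d = min_pair_distance(placed, ag)
        if max(gap - 0.5, 0.0) <= d <= gap + 2.0:
            pose = concat_structures([placed, ag], prefixes=["fab", "antigen"])
            pose.meta["subunit"] = subunit
            pose.meta["gap"] = gap
            pose.meta["seed"] = seed
            if gap > 8.0:
                _warnings.warn(
                    "gap > 8 A: symmetric replication may leave no contact "
                    "that survives the clash filter",
                    stacklevel=2,
                )
            return pose
    raise PlacementError(
        f"could not place Fab at gap {gap} A after {max_retries} retries"
    )


def make_synthetic_profile(
    truth: Structure,
    qgrid: np.ndarray,
    noise: NoiseModel | None = None,
) -> ScatteringProfile:
    """Noisy scattering profile of a ground-truth structure.

    Intensity is the exact Debye profile plus Gaussian noise of standard
    deviation sigma(Q) from the noise model; the sigma column reports the
    true sigma(Q). ``noise=None`` or a zero floor returns the noiseless
    profile without a sigma column.
    """
    from .saxscalc import debye_profile  # local import to avoid cycle

    clean = debye_profile(truth, qgrid)
    if noise is None or noise.rel_floor == 0.0:
        return clean
    sig = noise.sigma(clean.q, clean.intensity)
    rng = np.random.default_rng(noise.seed)
    noisy = clean.intensity + rng.normal(0.0, sig)
    return ScatteringProfile(clean.q, noisy, sig)
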