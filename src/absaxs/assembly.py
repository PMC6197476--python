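"""Rigid-body assembly of candidate antibody-antigen complexes.

Builds the candidate species compared against the scattering data, using
only superposition onto shared Fab frames plus three geometric acceptance
filters:

* hard clash rule -- any inter-unit atom pair closer than 8.0 A rejects the
  assembly (strict inequality: exactly 8.0 A passes);
* antibody pre-filter for ring closure -- Fab-Fc-Fab angle (between domain
  centroids) within [70, 90] degrees;
* ring-closure rule -- the anchor ("residue 211 C-alpha" analogue) atoms of
  the two dangling Fabs must lie closer than 40 A before the second Fc is
  added.

Assembly is rigid-body only: internal geometry of every unit is preserved
exactly. Docked Fab-antigen poses are maintained as given (their sub-8 A
contact is the binding interface, not a clash).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ClashRejection, ValidationError
from .geometry import (
    min_pair_distance,
    radius_of_gyration,
    rotation_about_axis,
    superpose,
    three_point_angle,
)
from .structio import Structure, concat_structures, extract_unit
from .tamc import Ensemble

__all__ = [
    "AssemblyFilters",
    "ComplexTopology",
    "symmetrize_pose",
    "attach_antibody",
    "attach_pose_antigen",
    "attach_block",
    "fab_fc_fab_angle",
    "build_monodentate_ensemble",
    "build_bidentate_ensemble",
]


@dataclass(frozen=True)
class AssemblyFilters:
    """The geometric acceptance thresholds for complex building."""

    clash_min: float = 8.0
    fabfcfab_window: tuple[float, float] = (70.0, 90.0)
    ring_calpha_max: float = 40.0

    def __post_init__(self):
        if self.clash_min <= 0:
            raise ValidationError("clash_min must be positive")
        lo, hi = self.fabfcfab_window
        if not lo < hi:
            raise ValidationError("empty Fab-Fc-Fab angle window")
        if self.ring_calpha_max <= 0:
            raise ValidationError("ring_calpha_max must be positive")


@dataclass(frozen=True)
class ComplexTopology:
    """Composition and linkage of a candidate complex.

    ``linkage`` is a list of (antibody_node, antigen_node) binding edges.
    Monodentate 2:2 complexes are simple paths through the binding graph;
    bidentate 2:2 complexes are a single cycle.
    """

    n_antibody: int
    n_antigen: int
    kind: str
    linkage: tuple = ()

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(f"ab{i}" for i in range(self.n_antibody))
        g.add_nodes_from(f"ag{i}" for i in range(self.n_antigen))
        g.add_edges_from(self.linkage)
        return g

    def validate(self) -> None:
        g = self.graph()
        if self.kind in ("monodentate", "bidentate") and (
            self.n_antibody != 2 or self.n_antigen != 2
        ):
            raise ValidationError(f"{self.kind} complexes must be 2:2")
        if self.kind == "monodentate":
            if not nx.is_connected(g) or len(nx.cycle_basis(g)) != 0:
                raise ValidationError("monodentate linkage must be a simple path")
            degs = sorted(d for _, d in g.degree())
            if degs != [1, 1, 2, 2]:
                raise ValidationError("monodentate linkage must be a simple path")
        elif self.kind == "bidentate":
            if not nx.is_connected(g) or len(nx.cycle_basis(g)) != 1:
                raise ValidationError("bidentate linkage must be a single cycle")
            if any(d != 2 for _, d in g.degree()):
                raise ValidationError("bidentate linkage must be a single cycle")


# ---------------------------------------------------------------------------
# single-step operations
# ---------------------------------------------------------------------------


def symmetrize_pose(
    pose: Structure,
    axis_index: int = 0,
    filters: AssemblyFilters | None = None,
) -> Structure:
    """Replicate the Fab of a docked pose through an antigen 2-fold axis.

    The second Fab is the first rotated 180 degrees about the chosen recorded
    symmetry axis of the antigen, giving the two-Fabs-one-antigen building
    block. Raises :class:`ClashRejection` when the two Fabs come closer than
    the clash threshold.
    """
    filters = filters or AssemblyFilters()
    fab = extract_unit(pose, "fab")
    ag = extract_unit(pose, "antigen")
    axes = ag.meta.get("symmetry_axes")
    if axes is None:
        raise ValidationError("antigen has no recorded symmetry axes")
    axis = np.asarray(axes[axis_index], dtype=np.float64)
    center = np.asarray(ag.meta.get("symmetry_center", ag.centroid()))
    T = rotation_about_axis(center, axis, 180.0)
    fab_b = T.apply_structure(fab)
    d = min_pair_distance(fab, fab_b)
    if d < filters.clash_min:
        raise ClashRejection(d, filters.clash_min, "symmetrized Fab pair")
    out = concat_structures([fab, fab_b, ag], prefixes=["fab_a", "fab_b", "antigen"])
    out.meta["axis_index"] = axis_index
    return out


def _paired_align(
    mobile: Structure, mobile_label: str, target: Structure, target_label: str
):
    """Index pairs for canonical-order alignment selections."""
    mi = mobile.label_indices(mobile_label)
    ti = target.label_indices(target_label)
    if len(mi) != len(ti):
        raise ValidationError(
            f"alignment selections differ in size: {mobile_label} ({len(mi)}) "
            f"vs {target_label} ({len(ti)})"
        )
    return mi, ti


def attach_antibody(
    full_ab: Structure,
    complex_s: Structure,
    anchor_prefix: str,
    new_prefix: str,
    ab_fab: str = "Fab1",
    filters: AssemblyFilters | None = None,
) -> Structure:
    """Superpose a full antibody onto an anchor Fab of a complex.

    The antibody's ``ab_fab`` domain is aligned (over the non-interface
    ``fab*_align`` atoms) onto the complex's ``anchor_prefix`` Fab; the
    complex stays frozen and the antibody moves. The antibody's aligned Fab
    is then dropped -- the anchor Fab already represents it -- and the rest
    (Fc, hinges, the free Fab) is added under ``new_prefix``.

    Clash rule: every atom of the added part must stay >= ``clash_min`` from
    every complex atom outside the anchor Fab (the anchor Fab is the
    antibody's own domain, so proximity to it is covalent geometry, not a
    clash).
    """
    filters = filters or AssemblyFilters()
    arm = ab_fab[-1]  # "1" or "2"
    mi, ti = _paired_align(
        full_ab, f"fab{arm}_align", complex_s, f"{anchor_prefix}:fab_align"
    )
    T, rmsd = superpose(full_ab, complex_s, (mi, ti))
    moved = T.apply_structure(full_ab)
    fab_atoms = set(moved.label_indices(ab_fab).tolist())
    keep = np.array(
        [i for i in range(moved.n_atoms) if i not in fab_atoms], dtype=np.intp
    )
    remainder = moved.subset(keep)
    anchor_atoms = complex_s.label_indices(anchor_prefix)
    others_mask = np.ones(complex_s.n_atoms, dtype=bool)
    others_mask[anchor_atoms] = False
    others = complex_s.subset(np.flatnonzero(others_mask), keep_labels=False)
    if others.n_atoms and remainder.n_atoms:
        d = min_pair_distance(remainder, others)
        if d < filters.clash_min:
            raise ClashRejection(d, filters.clash_min, f"attach {new_prefix}")
    out = concat_structures([complex_s, remainder], prefixes=[None, new_prefix])
    out.meta[f"{new_prefix}:align_rmsd"] = rmsd
    return out


def attach_pose_antigen(
    pose: Structure,
    complex_s: Structure,
    target_fab_align: str,
    target_fab_unit: str,
    new_prefix: str,
    filters: AssemblyFilters | None = None,
) -> Structure:
    """Add a docked pose's antigen to a free Fab of the complex.

    The pose's Fab is superposed onto the target free Fab (alignment atoms
    exclude the interface) and only the antigen is added -- the predicted
    Fab-antigen docked configuration is thereby maintained. The target Fab is
    exempt from the clash rule against the new antigen (it is the binding
    partner); everything else must stay >= ``clash_min`` away.
    """
    filters = filters or AssemblyFilters()
    mi, ti = _paired_align(pose, "fab:fab_align", complex_s, target_fab_align)
    T, rmsd = superpose(pose, complex_s, (mi, ti))
    moved = T.apply_structure(pose)
    antigen = extract_unit(moved, "antigen")
    target_atoms = complex_s.label_indices(target_fab_unit)
    others_mask = np.ones(complex_s.n_atoms, dtype=bool)
    others_mask[target_atoms] = False
    others = complex_s.subset(np.flatnonzero(others_mask), keep_labels=False)
    if others.n_atoms:
        d = min_pair_distance(antigen, others)
        if d < filters.clash_min:
            raise ClashRejection(d, filters.clash_min, f"attach {new_prefix}")
    out = concat_structures([complex_s, antigen], prefixes=[None, new_prefix])
    out.meta[f"{new_prefix}:align_rmsd"] = rmsd
    return out


def attach_block(
    block: Structure,
    complex_s: Structure,
    target_fab_align: str,
    target_fab_unit: str,
    new_prefix: str,
    filters: AssemblyFilters | None = None,
) -> Structure:
    """Align a two-Fab-one-antigen block onto a Fab of the complex.

    The block's ``fab_a`` is superposed onto the target Fab and dropped; the
    antigen and the dangling ``fab_b`` are added under ``new_prefix``. The
    target Fab is clash-exempt against the added antigen contact.
    """
    filters = filters or AssemblyFilters()
    mi, ti = _paired_align(block, "fab_a:fab_align", complex_s, target_fab_align)
    T, rmsd = superpose(block, complex_s, (mi, ti))
    moved = T.apply_structure(block)
    drop = set(moved.label_indices("fab_a").tolist())
    keep = np.array(
        [i for i in range(moved.n_atoms) if i not in drop], dtype=np.intp
    )
    added = moved.subset(keep)
    target_atoms = complex_s.label_indices(target_fab_unit)
    others_mask = np.ones(complex_s.n_atoms, dtype=bool)
    others_mask[target_atoms] = False
    others = complex_s.subset(np.flatnonzero(others_mask), keep_labels=False)
    if others.n_atoms:
        d = min_pair_distance(added, others)
        if d < filters.clash_min:
            raise ClashRejection(d, filters.clash_min, f"attach {new_prefix}")
    out = concat_structures([complex_s, added], prefixes=[None, new_prefix])
    out.meta[f"{new_prefix}:align_rmsd"] = rmsd
    return out


def fab_fc_fab_angle(ab: Structure) -> float:
    """Fab-Fc-Fab angle between domain centroids, degrees."""
    return three_point_angle(
        ab.centroid(ab.label_indices("Fab1")),
        ab.centroid(ab.label_indices("Fc")),
        ab.centroid(ab.label_indices("Fab2")),
    )


# ---------------------------------------------------------------------------
# ensemble builders
# ---------------------------------------------------------------------------


def _ensemble(members, rows, attempts, seed) -> Ensemble:
    meta = pd.DataFrame(rows)
    return Ensemble(
        members=members,
        meta=meta,
        info={
            "attempts": attempts,
            "accepted": len(members),
            "acceptance_rate": (len(members) / attempts) if attempts else 0.0,
            "seed": seed,
        },
    )


def build_monodentate_ensemble(
    fab2_complexes: Ensemble,
    fab_poses: Ensemble,
    antibodies: Ensemble,
    filters: AssemblyFilters,
    n_target: int,
    seed: int = 0,
    max_attempts: int | None = None,
) -> Ensemble:
    """Chain-topology 2:2 complexes: antigen - Ab1 - shared antigen - Ab2.

    Each draw takes one two-Fab-one-antigen block, two full antibodies
    (attached to the block's two Fabs) and one docked pose whose antigen is
    added to a free Fab of the first antibody. Draws are uniform with a
    seeded generator until ``n_target`` acceptances or the attempt cap;
    members that fail any clash check are rejected and counted.
    """
    if n_target == 0:
        return _ensemble([], [], 0, seed)
    for name, e in (
        ("fab2_complexes", fab2_complexes),
        ("fab_poses", fab_poses),
        ("antibodies", antibodies),
    ):
        if len(e) == 0:
            raise ValidationError(f"empty input ensemble: {name}")
    rng = np.random.default_rng(seed)
    cap = max_attempts if max_attempts is not None else 200 * n_target + 50
    members, rows = [], []
    attempts = 0
    topology = ComplexTopology(
        n_antibody=2,
        n_antigen=2,
        kind="monodentate",
        linkage=(("ab0", "ag0"), ("ab1", "ag0"), ("ab0", "ag1")),
    )
    topology.validate()
    while len(members) < n_target and attempts < cap:
        attempts += 1
        i_blk = int(rng.integers(len(fab2_complexes)))
        i_ab1 = int(rng.integers(len(antibodies)))
        i_ab2 = int(rng.integers(len(antibodies)))
        i_pose = int(rng.integers(len(fab_poses)))
        try:
            c = attach_antibody(
                antibodies.members[i_ab1],
                fab2_complexes.members[i_blk],
                anchor_prefix="fab_a",
                new_prefix="ab1",
                filters=filters,
            )
            c = attach_antibody(
                antibodies.members[i_ab2],
                c,
                anchor_prefix="fab_b",
                new_prefix="ab2",
                filters=filters,
            )
            c = attach_pose_antigen(
                fab_poses.members[i_pose],
                c,
                target_fab_align="ab1:fab2_align",
                target_fab_unit="ab1:Fab2",
                new_prefix="ag2",
                filters=filters,
            )
        except ClashRejection:
            continue
        c.meta["topology"] = topology
        members.append(c)
        rows.append(
            {
                "member": len(members) - 1,
                "block": i_blk,
                "antibody_1": i_ab1,
                "antibody_2": i_ab2,
                "pose": i_pose,
                "rg": radius_of_gyration(c),
            }
        )
    return _ensemble(members, rows, attempts, seed)


def build_bidentate_ensemble(
    antibodies: Ensemble,
    fab2_complexes: Ensemble,
    fc_blocks: Ensemble,
    filters: AssemblyFilters,
    n_target: int,
    seed: int = 0,
    max_attempts: int | None = None,
) -> Ensemble:
    """Cyclic 2:2 complexes: Ab1 - antigen A - Ab2 - antigen B - Ab1.

    Antibody candidates are pre-filtered to the Fab-Fc-Fab angle window.
    One block is aligned onto each Fab of the base antibody (adding an
    antigen and a dangling Fab each); ring closure requires the two dangling
    Fabs' anchor atoms to lie within the ring C-alpha threshold (strict <),
    evaluated before the second antibody's Fc is placed. The Fc is then added
    facing away from the ring centre at antibody-like separation and the
    usual clash rule applies. An unsatisfiable angle window yields an empty
    ensemble with diagnostics, not an error.

    Because ring-compatible combinations are a sub-0.1% fraction of blind
    (antibody, block, block) draws, the builder enumerates anchor positions
    for every combination first (one rigid superposition each), keeps only
    those passing the ring rule, and assembles a seeded random order of that
    candidate list -- the desk-scale equivalent of the exhaustive production
    ensembles this emulates.
    """
    if n_target == 0:
        return _ensemble([], [], 0, seed)
    for name, e in (
        ("antibodies", antibodies),
        ("fab2_complexes", fab2_complexes),
        ("fc_blocks", fc_blocks),
    ):
        if len(e) == 0:
            raise ValidationError(f"empty input ensemble: {name}")
    lo, hi = filters.fabfcfab_window
    angles = [fab_fc_fab_angle(ab) for ab in antibodies.members]
    eligible = [i for i, a in enumerate(angles) if lo <= a <= hi]
    if not eligible:
        out = _ensemble([], [], 0, seed)
        out.info["reason"] = (
            f"no antibody candidate with Fab-Fc-Fab angle in [{lo}, {hi}] deg"
        )
        return out
    rng = np.random.default_rng(seed)
    members, rows = [], []
    attempts = 0
    topology = ComplexTopology(
        n_antibody=2,
        n_antigen=2,
        kind="bidentate",
        linkage=(("ab0", "ag0"), ("ab0", "ag1"), ("ab1", "ag0"), ("ab1", "ag1")),
    )
    topology.validate()
    # Ring-compatible (antibody, block, block) triples are rare under blind
    # pairing, so enumerate them first: superposing a block onto an arm is a
    # rigid map, so each dangling-Fab anchor position costs one Kabsch fit
    # on the alignment atoms. Full assembly (and every clash check) runs
    # only on candidates that already satisfy the ring rule.
    anchors = {1: [], 2: []}
    for arm in (1, 2):
        for i_ab in eligible:
            ab = antibodies.members[i_ab]
            ti = ab.label_indices(f"fab{arm}_align")
            for j, blk in enumerate(fab2_complexes.members):
                mi = blk.label_indices("fab_a:fab_align")
                T, _ = superpose(blk, ab, (mi, ti))
                anchor = T.apply(blk.coord[blk.label_indices("fab_b:fab_anchor")])[0]
                anchors[arm].append((i_ab, j, anchor))
    candidates = []
    for i_ab in eligible:
        a1s = [(j, a) for (i, j, a) in anchors[1] if i == i_ab]
        a2s = [(j, a) for (i, j, a) in anchors[2] if i == i_ab]
        for j1, p1 in a1s:
            for j2, p2 in a2s:
                if float(np.linalg.norm(p1 - p2)) < filters.ring_calpha_max:
                    candidates.append((i_ab, j1, j2))
    rng.shuffle(candidates)
    cap = max_attempts if max_attempts is not None else len(candidates)
    for i_ab, i_b1, i_b2 in candidates[:cap]:
        if len(members) >= n_target:
            break
        attempts += 1
        i_fc = int(rng.integers(len(fc_blocks)))
        ab = antibodies.members[i_ab]
        try:
            c = attach_block(
                fab2_complexes.members[i_b1],
                ab,
                target_fab_align="fab1_align",
                target_fab_unit="Fab1",
                new_prefix="blk1",
                filters=filters,
            )
            c = attach_block(
                fab2_complexes.members[i_b2],
                c,
                target_fab_align="fab2_align",
                target_fab_unit="Fab2",
                new_prefix="blk2",
                filters=filters,
            )
        except ClashRejection:
            continue
        a1 = c.coord[c.label_indices("blk1:fab_b:fab_anchor")][0]
        a2 = c.coord[c.label_indices("blk2:fab_b:fab_anchor")][0]
        ring_d = float(np.linalg.norm(a1 - a2))
        if not ring_d < filters.ring_calpha_max:
            continue
        try:
            c = _place_second_fc(
                c, fc_blocks.members[i_fc], a1, a2, filters
            )
        except ClashRejection:
            continue
        c.meta["topology"] = topology
        members.append(c)
        rows.append(
            {
                "member": len(members) - 1,
                "antibody": i_ab,
                "block_1": i_b1,
                "block_2": i_b2,
                "fc": i_fc,
                "fabfcfab_angle": angles[i_ab],
                "ring_anchor_distance": ring_d,
                "rg": radius_of_gyration(c),
            }
        )
    out = _ensemble(members, rows, attempts, seed)
    out.info["ring_candidates"] = len(candidates)
    if not candidates:
        out.info["reason"] = "no ring-compatible (antibody, block, block) combination"
    return out


def _place_second_fc(
    c: Structure,
    fc: Structure,
    anchor1: np.ndarray,
    anchor2: np.ndarray,
    filters: AssemblyFilters,
) -> Structure:
    """Complete the second antibody by placing its Fc beyond the dangling Fabs.

    The Fc centre goes on the ray from the ring centre through the midpoint
    of the two dangling-Fab anchors, at a distance echoing the built
    antibody's Fab-Fc centroid separation.
    """
    f1 = c.centroid(c.label_indices("blk1:fab_b"))
    f2 = c.centroid(c.label_indices("blk2:fab_b"))
    mid = 0.5 * (anchor1 + anchor2)
    ring_center = c.centroid()
    w = mid - ring_center
    norm = np.linalg.norm(w)
    if norm < 1e-9:
        raise ValidationError("degenerate ring geometry")
    w /= norm
    half_gap2 = (0.5 * np.linalg.norm(f1 - f2)) ** 2
    span = c.meta.get("fab_fc_separation", 70.0)
    offset2 = max(span**2 - half_gap2, (2.0 * filters.clash_min) ** 2)
    target = 0.5 * (f1 + f2) + np.sqrt(offset2) * w
    placed = fc.with_coord(fc.coord - fc.centroid() + target)
    d = min_pair_distance(placed, c)
    if d < filters.clash_min:
        raise ClashRejection(d, filters.clash_min, "second Fc placement")
    out = concat_structures([c, placed], prefixes=[None, "fc2"])
    return out
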