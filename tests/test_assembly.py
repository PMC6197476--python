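"""Complex assembly: symmetrization, attachment, filters, topology."""

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import cdist

import absaxs as ax
from absaxs.assembly import fab_fc_fab_angle
from absaxs.errors import ClashRejection, ValidationError
from absaxs.geometry import rotation_about_axis


def min_between(member, idx_a, idx_b):
    """Brute-force O(N^2) minimum distance between two atom index sets."""
    return cdist(member.coord[idx_a], member.coord[idx_b]).min()


class TestSymmetrizePose:
    def test_replication_is_involutive(self, pose, filters):
        blk = ax.symmetrize_pose(pose, axis_index=0, filters=filters)
        ag = ax.extract_unit(blk, "antigen")
        axis = ag.meta["symmetry_axes"][0]
        center = ag.meta["symmetry_center"]
        T = rotation_about_axis(center, axis, 180.0)
        fa = blk.coord[blk.label_indices("fab_a")]
        fb = blk.coord[blk.label_indices("fab_b")]
        np.testing.assert_allclose(T.apply(fb), fa, atol=1e-9)

    def test_antigen_unchanged_and_both_fabs_in_contact(self, pose, filters):
        blk = ax.symmetrize_pose(pose, axis_index=0, filters=filters)
        ag = ax.extract_unit(blk, "antigen")
        np.testing.assert_allclose(
            ag.coord, ax.extract_unit(pose, "antigen").coord, atol=1e-12
        )
        gap = pose.meta["gap"]
        for fab_label in ("fab_a", "fab_b"):
            f = blk.subset(blk.label_indices(fab_label))
            d = ax.min_pair_distance(f, ag)
            assert gap - 0.5 <= d <= gap + 2.0

    def test_overlapping_replication_is_rejected(self, fab, antigen, filters):
        # a Fab docked on the 2-fold axis overlaps its own image
        ag = antigen.copy()
        ag.labels["on_axis"] = ag.label_indices("sub1")
        ag.meta["symmetry_axes"] = (np.array([1.0, 1.0, 1.0]) / np.sqrt(3),)
        pose = ax.make_docked_pose(fab, ag, "sub1", gap=4.0, seed=2)
        with pytest.raises(ClashRejection) as exc:
            ax.symmetrize_pose(pose, axis_index=0, filters=filters)
        assert exc.value.min_distance < 8.0


class TestAttachAntibody:
    def test_alignment_is_exact_for_rigid_toy(self, antibody, block_ensemble, filters):
        blk = block_ensemble.members[0]
        c = ax.attach_antibody(antibody, blk, "fab_a", "ab1", filters=filters)
        assert c.meta["ab1:align_rmsd"] < 1e-6
        # the complex part is frozen: block coordinates unchanged
        np.testing.assert_array_equal(c.coord[: blk.n_atoms], blk.coord)

    def test_composition_bookkeeping(self, antibody, block_ensemble, filters):
        blk = block_ensemble.members[0]
        c = ax.attach_antibody(antibody, blk, "fab_a", "ab1", filters=filters)
        # added atoms = full antibody minus its anchored Fab
        fab_size = len(antibody.label_indices("Fab1"))
        assert c.n_atoms == blk.n_atoms + antibody.n_atoms - fab_size

    def test_engineered_overlap_is_rejected(self, antibody, block_ensemble, filters):
        blk = block_ensemble.members[0].copy()
        # park a foreign antigen copy right where the antibody's Fc will go
        probe = ax.attach_antibody(antibody, blk, "fab_a", "probe", filters=filters)
        fc_center = probe.centroid(probe.label_indices("probe:Fc"))
        from absaxs.structio import concat_structures

        sab = blk.subset(blk.label_indices("antigen"))
        sab = sab.with_coord(sab.coord - sab.coord.mean(0) + fc_center)
        spiked = concat_structures([blk, sab], prefixes=[None, "spoiler"])
        with pytest.raises(ClashRejection) as exc:
            ax.attach_antibody(antibody, spiked, "fab_a", "ab1", filters=filters)
        assert exc.value.min_distance < 8.0


@pytest.fixture(scope="module")
def monodentate(block_ensemble, pose_ensemble, antibody_ensemble, filters):
    return ax.build_monodentate_ensemble(
        block_ensemble, pose_ensemble, antibody_ensemble, filters,
        n_target=6, seed=17,
    )


@pytest.fixture(scope="module")
def bidentate(antibody_ensemble, block_ensemble, fc_ensemble, filters):
    return ax.build_bidentate_ensemble(
        antibody_ensemble, block_ensemble, fc_ensemble, filters,
        n_target=6, seed=19,
    )


class TestMonodentateEnsemble:
    def test_builds_members(self, monodentate):
        assert len(monodentate) == 6

    def test_members_repass_brute_force_clash_filter(self, monodentate, filters):
        # re-derive every clash check of the build from label bookkeeping and
        # scan all atom pairs; maintained docked Fab-antigen contacts are the
        # binding interface and stay out of scope, as in the build itself
        for member in monodentate.members:
            L = member.label_indices
            all_idx = np.arange(member.n_atoms)
            checks = [
                (L("fab_a"), L("fab_b")),  # symmetrized Fab pair
                (L("ab1"), np.concatenate([L("antigen"), L("fab_b")])),
                (L("ab2"), np.concatenate([L("fab_a"), L("antigen"), L("ab1")])),
                (
                    L("ag2"),
                    np.setdiff1d(all_idx, np.concatenate([L("ag2"), L("ab1:Fab2")])),
                ),
            ]
            for ia, ib in checks:
                assert min_between(member, ia, ib) >= filters.clash_min

    def test_composition_is_two_antibodies_two_antigens(
        self, monodentate, antibody, antigen
    ):
        for member in monodentate.members:
            assert member.n_atoms == 2 * antibody.n_atoms + 2 * antigen.n_atoms

    def test_linkage_graph_is_simple_path(self, monodentate):
        topo = monodentate.members[0].meta["topology"]
        g = topo.graph()
        assert nx.is_connected(g)
        assert len(nx.cycle_basis(g)) == 0
        assert sorted(d for _, d in g.degree()) == [1, 1, 2, 2]
        topo.validate()

    def test_zero_target_returns_empty(
        self, block_ensemble, pose_ensemble, antibody_ensemble, filters
    ):
        ens = ax.build_monodentate_ensemble(
            block_ensemble, pose_ensemble, antibody_ensemble, filters,
            n_target=0, seed=1,
        )
        assert len(ens) == 0


class TestBidentateEnsemble:
    def test_builds_members(self, bidentate):
        assert len(bidentate) >= 1

    def test_members_satisfy_paper_filters(self, bidentate, filters):
        lo, hi = filters.fabfcfab_window
        for _, row in bidentate.meta.iterrows():
            assert lo <= row["fabfcfab_angle"] <= hi
            assert row["ring_anchor_distance"] < filters.ring_calpha_max
        # direct re-measurement, not trusting the recorded metadata
        for member in bidentate.members:
            a1 = member.coord[member.label_indices("blk1:fab_b:fab_anchor")][0]
            a2 = member.coord[member.label_indices("blk2:fab_b:fab_anchor")][0]
            assert np.linalg.norm(a1 - a2) < filters.ring_calpha_max
            assert lo <= fab_fc_fab_angle(member) <= hi

    def test_members_repass_brute_force_clash_filter(self, bidentate, filters):
        for member in bidentate.members:
            L = member.label_indices
            all_idx = np.arange(member.n_atoms)
            added = np.concatenate([L("blk1"), L("blk2"), L("fc2")])
            ab_atoms = np.setdiff1d(all_idx, added)
            checks = [
                (L("blk1"), np.setdiff1d(ab_atoms, L("Fab1"))),
                (L("blk2"), np.concatenate(
                    [np.setdiff1d(ab_atoms, L("Fab2")), L("blk1")]
                )),
                (L("fc2"), np.setdiff1d(all_idx, L("fc2"))),
                # symmetrized Fab pairs inside each block
                (L("blk1:fab_b"), L("Fab1")),
                (L("blk2:fab_b"), L("Fab2")),
            ]
            for ia, ib in checks:
                assert min_between(member, ia, ib) >= filters.clash_min

    def test_linkage_graph_is_single_cycle(self, bidentate):
        topo = bidentate.members[0].meta["topology"]
        g = topo.graph()
        assert nx.is_connected(g)
        assert len(nx.cycle_basis(g)) == 1
        assert all(d == 2 for _, d in g.degree())
        topo.validate()

    def test_unsatisfiable_angle_window_yields_empty_ensemble(
        self, antibody_ensemble, block_ensemble, fc_ensemble
    ):
        narrow = ax.AssemblyFilters(fabfcfab_window=(89.9, 90.0))
        ens = ax.build_bidentate_ensemble(
            antibody_ensemble, block_ensemble, fc_ensemble, narrow,
            n_target=4, seed=3,
        )
        assert len(ens) == 0
        assert "reason" in ens.info


def test_topology_validation_rejects_malformed_graphs():
    bad = ax.ComplexTopology(
        n_antibody=2, n_antigen=2, kind="bidentate",
        linkage=(("ab0", "ag0"), ("ab0", "ag1"), ("ab1", "ag0")),
    )
    with pytest.raises(ValidationError):
        bad.validate()
    not22 = ax.ComplexTopology(n_antibody=1, n_antigen=2, kind="monodentate")
    with pytest.raises(ValidationError):
        not22.validate()
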