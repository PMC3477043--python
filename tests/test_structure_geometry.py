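"""Mutation, rotamer, hydrogen-bond, salt-bridge, staple and helix detectors."""

import numpy as np
import pytest

import pocketpca as pp
from pocketpca.binding_site import StructureModel
from pocketpca.errors import ContractError, GeometryError
from pocketpca.structure_geometry import (
    find_hbonds,
    find_hydrophobic_staple,
    find_salt_bridge,
    helix_backbone_hbonds,
    measure_chi1,
    mutate_residue,
    scan_chi1,
)
from pocketpca.synthetic_data import generate_structure_fixture


@pytest.fixture()
def tripeptide():
    """Ideal 3-residue poly-Ala chain used as a mutation substrate."""
    model, _ = generate_structure_fixture("ideal-helix", n_residues=3)
    return model


@pytest.fixture()
def valine_model(tripeptide):
    """Tripeptide with an idealized Val at residue 2 (χ1 = −60°)."""
    return mutate_residue(tripeptide, ("A", 2), "VAL")


class TestMutateResidue:
    def test_mutation_to_gly_truncates_to_backbone(self, valine_model):
        mutated = mutate_residue(valine_model, ("A", 2), "GLY")
        names = {a.name for a in mutated.residue("A", 2)}
        assert names == {"N", "CA", "C", "O"}
        assert mutated.residue("A", 2)[0].resname == "GLY"

    def test_ala_to_ala_is_identity(self, tripeptide):
        assert mutate_residue(tripeptide, ("A", 2), "ALA") is tripeptide

    def test_backbone_never_moves(self, valine_model):
        mutated = mutate_residue(valine_model, ("A", 2), "THR")
        for name in ("N", "CA", "C", "O"):
            before = [a for a in valine_model.residue("A", 2) if a.name == name][0]
            after = [a for a in mutated.residue("A", 2) if a.name == name][0]
            assert (before.x, before.y, before.z) == (after.x, after.y, after.z)

    def test_val_to_thr_preserves_cb_and_chi1(self, valine_model):
        chi1_val = measure_chi1(valine_model.residue("A", 2))
        mutated = mutate_residue(valine_model, ("A", 2), "THR")
        thr = mutated.residue("A", 2)
        assert {a.name for a in thr} == {"N", "CA", "C", "O", "CB", "OG1", "CG2"}
        cb_before = [a for a in valine_model.residue("A", 2) if a.name == "CB"][0]
        cb_after = [a for a in thr if a.name == "CB"][0]
        np.testing.assert_allclose(cb_before.coord, cb_after.coord, atol=1e-12)
        assert measure_chi1(thr) == pytest.approx(chi1_val, abs=1.0)

    def test_unsupported_ring_target_rejected(self, tripeptide):
        with pytest.raises(GeometryError):
            mutate_residue(tripeptide, ("A", 2), "TRP")

    def test_missing_backbone_is_a_geometry_error(self, valine_model):
        stripped = StructureModel(
            atoms=tuple(
                a for a in valine_model.atoms if not (a.resnum == 2 and a.name == "O")
            )
        )
        with pytest.raises(GeometryError):
            mutate_residue(stripped, ("A", 2), "SER")


class TestScanChi1:
    def test_states_hit_requested_angles(self, tripeptide):
        ser_model = mutate_residue(tripeptide, ("A", 2), "SER")
        states = scan_chi1(ser_model, ("A", 2))
        assert len(states) == 3
        for state, requested in zip(states, (-60.0, 60.0, 180.0)):
            assert state.chi1 == pytest.approx(requested)
            measured = measure_chi1(state.model.residue("A", 2))
            assert measured == pytest.approx(requested, abs=1.0)

    def test_rescanning_current_chi1_round_trips(self, valine_model):
        chi1 = measure_chi1(valine_model.residue("A", 2))
        state = scan_chi1(valine_model, ("A", 2), angles=[chi1])[0]
        before = {a.name: a.coord for a in valine_model.residue("A", 2)}
        after = {a.name: a.coord for a in state.model.residue("A", 2)}
        sq = [np.sum((before[n] - after[n]) ** 2) for n in before]
        rmsd = float(np.sqrt(np.mean(sq)))
        assert rmsd < 0.05

    def test_glycine_has_no_chi1(self, tripeptide):
        gly = mutate_residue(tripeptide, ("A", 2), "GLY")
        with pytest.raises(ContractError):
            scan_chi1(gly, ("A", 2))


class TestHBonds:
    def test_pair_within_thresholds_detected(self):
        model, _ = generate_structure_fixture("hbond-pair", distance=2.9, angle=150.0)
        donors = model.select(resnum=1, atom_names=["O"])
        acceptors = model.select(resnum=2, atom_names=["N"])
        bonds = find_hbonds(model, donors, acceptors)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-6)
        assert bonds[0].angle == pytest.approx(150.0, abs=1e-6)

    def test_distance_beyond_cutoff_rejected(self):
        model, _ = generate_structure_fixture("hbond-pair", distance=4.2, angle=150.0)
        bonds = find_hbonds(
            model,
            model.select(resnum=1, atom_names=["O"]),
            model.select(resnum=2, atom_names=["N"]),
        )
        assert bonds == []

    def test_angle_below_minimum_rejected(self):
        model, _ = generate_structure_fixture("hbond-pair", distance=2.9, angle=100.0)
        bonds = find_hbonds(
            model,
            model.select(resnum=1, atom_names=["O"]),
            model.select(resnum=2, atom_names=["N"]),
        )
        assert bonds == []

    def test_empty_selection_rejected(self):
        model, _ = generate_structure_fixture("hbond-pair", distance=2.9, angle=150.0)
        with pytest.raises(pp.errors.SelectionError):
            find_hbonds(model, [], model.select(resnum=2))


class TestSaltBridge:
    @pytest.fixture()
    def lys_glu(self, tripeptide):
        """Lys and Glu side chains planted at a controllable NZ–OE distance."""
        helix, _ = generate_structure_fixture("ideal-helix", n_residues=6)
        model = mutate_residue(helix, ("A", 1), "LYS")
        return mutate_residue(model, ("A", 5), "GLU")

    def test_presence_follows_distance(self, lys_glu):
        result = find_salt_bridge(lys_glu, ("A", 1), ("A", 5))
        nz = lys_glu.select(resnum=1, atom_names=["NZ"])[0]
        oes = lys_glu.select(resnum=5, atom_names=["OE1", "OE2"])
        expected = min(np.linalg.norm(nz.coord - o.coord) for o in oes)
        assert result.min_distance == pytest.approx(expected, abs=1e-9)
        assert result.present == (expected <= 4.0)

    def test_threshold_monotone(self, lys_glu):
        base = find_salt_bridge(lys_glu, ("A", 1), ("A", 5), d_max=2.0)
        wide = find_salt_bridge(lys_glu, ("A", 1), ("A", 5), d_max=50.0)
        assert wide.present  # any finite geometry is present at a huge cutoff
        if base.present:
            assert wide.present

    def test_wrong_residue_types_rejected(self, lys_glu):
        with pytest.raises(ContractError):
            find_salt_bridge(lys_glu, ("A", 5), ("A", 1))  # swapped roles


class TestHydrophobicStaple:
    def test_equilateral_within_cutoff_present(self):
        model, _ = generate_structure_fixture("staple-triangle", d12=4.0, d13=4.0, d23=4.0)
        result = find_hydrophobic_staple(model, [("A", 217), ("A", 219), ("A", 278)])
        assert result.present
        assert all(d == pytest.approx(4.0, abs=1e-6) for d in result.pair_distances.values())

    def test_one_long_edge_breaks_the_staple(self):
        model, _ = generate_structure_fixture("staple-triangle", d12=4.0, d13=7.0, d23=4.5)
        result = find_hydrophobic_staple(model, [("A", 217), ("A", 219), ("A", 278)])
        assert not result.present

    def test_glycine_site_rejected(self, tripeptide):
        gly_model = mutate_residue(tripeptide, ("A", 2), "GLY")
        with pytest.raises(ContractError):
            find_hydrophobic_staple(
                gly_model, [("A", 1), ("A", 2), ("A", 3)]
            )


class TestHelixHBonds:
    def test_ideal_helix_fully_bonded(self, helix12):
        table = helix_backbone_hbonds(helix12, "A", 1, 12)
        assert table.fraction_satisfied == 1.0

    def test_extended_chain_has_no_helical_bonds(self):
        model, _ = generate_structure_fixture("extended-chain", n_residues=12)
        table = helix_backbone_hbonds(model, "A", 1, 12)
        assert table.fraction_satisfied == 0.0

    def test_displaced_residue_breaks_exactly_its_pairs(self, helix12):
        import dataclasses

        shifted = []
        for a in helix12.atoms:
            if a.resnum == 6:
                shifted.append(dataclasses.replace(a, z=a.z + 2.0))
            else:
                shifted.append(a)
        perturbed = StructureModel(atoms=tuple(shifted))
        table = helix_backbone_hbonds(perturbed, "A", 1, 12)
        for entry in table.entries:
            involved = entry.resnum_i == 6 or entry.resnum_i4 == 6
            reference = helix_backbone_hbonds(helix12, "A", 1, 12).entries[
                entry.resnum_i - 1
            ]
            if not involved:
                assert entry.satisfied == reference.satisfied

        broken = [e for e in table.entries if e.resnum_i == 6 or e.resnum_i4 == 6]
        assert any(not e.satisfied for e in broken)

    def test_short_range_rejected(self, helix12):
        with pytest.raises(ContractError):
            helix_backbone_hbonds(helix12, "A", 1, 4)


class TestRigidMotionInvariance:
    def test_detectors_are_rigid_motion_invariant(self, random_rotation):
        R, t = random_rotation
        helix, _ = generate_structure_fixture("ideal-helix", n_residues=8)
        moved = helix.transformed(R, t)
        a = helix_backbone_hbonds(helix, "A", 1, 8)
        b = helix_backbone_hbonds(moved, "A", 1, 8)
        for x, y in zip(a.entries, b.entries):
            assert x.satisfied == y.satisfied
            assert x.distance == pytest.approx(y.distance, abs=1e-9)

        staple, _ = generate_structure_fixture("staple-triangle", d12=4.0, d13=4.2, d23=3.9)
        sites = [("A", 217), ("A", 219), ("A", 278)]
        before = find_hydrophobic_staple(staple, sites)
        after = find_hydrophobic_staple(staple.transformed(R, t), sites)
        assert before.present == after.present
        for key in before.pair_distances:
            assert before.pair_distances[key] == pytest.approx(
                after.pair_distances[key], abs=1e-9
            )

    def test_chi1_is_rigid_motion_invariant(self, random_rotation):
        R, t = random_rotation
        helix, _ = generate_structure_fixture("ideal-helix", n_residues=3)
        ser = mutate_residue(helix, ("A", 2), "SER", chi1=73.0)
        chi_before = measure_chi1(ser.residue("A", 2))
        chi_after = measure_chi1(ser.transformed(R, t).residue("A", 2))
        assert chi_after == pytest.approx(chi_before, abs=1e-6)
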