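import numpy as np
import pytest

from quatfun.structure_annotation import (
    MAX_SASA_GXG,
    PDBParseError,
    ResidueKey,
    classify_binding_site,
    compute_contacts,
    compute_sasa,
    hydrophobic_fraction,
    identify_interface,
    identify_ligand_binding_residues,
    identify_surface,
    ligand_interface_distance,
    parse_structure,
    shrake_rupley,
    sphere_points,
    vdw_radius,
)
from quatfun.synthetic_data import DimerSpec, generate_dimer

from conftest import TWO_CHAIN_PDB


def atom_line(serial, name, resname, chain, resnum, x, y, z, element,
              record="ATOM"):
    return (
        f"{record:<6s}{serial:5d} {name:<4s} {resname:>3s} {chain}"
        f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
        f"{element:>2s}"
    )


class TestParseStructure:
    def test_two_chain_identity(self):
        s = parse_structure(TWO_CHAIN_PDB)
        assert s.chains == ["A", "B"]
        assert len(s.atoms) == 4
        assert s.atoms[0].vdw_radius == pytest.approx(1.70)
        assert s.resnames[ResidueKey("A", 1, "")] == "ALA"

    def test_waters_dropped(self):
        text = TWO_CHAIN_PDB.replace(
            "END",
            atom_line(9, "O", "HOH", "W", 1, 50.0, 0, 0, "O",
                      record="HETATM") + "\nEND",
        )
        s = parse_structure(text)
        assert s.ligands == []

    def test_zinc_hetatm_is_metal_ligand(self):
        text = TWO_CHAIN_PDB.replace(
            "END",
            atom_line(9, "ZN", "ZN", "A", 90, 50.0, 0, 0, "ZN",
                      record="HETATM") + "\nEND",
        )
        s = parse_structure(text)
        assert len(s.ligands) == 1
        assert s.ligands[0].is_metal
        assert not s.ligands[0].is_biologically_relevant

    def test_malformed_record_reports_line(self):
        bad = TWO_CHAIN_PDB.replace("   3.800   0.000   0.000",
                                    "   x.800   0.000   0.000", 1)
        with pytest.raises(PDBParseError, match="line 2"):
            parse_structure(bad)

    def test_no_atoms_errors(self):
        with pytest.raises(PDBParseError):
            parse_structure("END\n")

    def test_first_model_only(self):
        text = ("MODEL        1\n" + TWO_CHAIN_PDB.replace("END", "ENDMDL")
                + "MODEL        2\n"
                + atom_line(9, "CA", "ALA", "C", 1, 90, 0, 0, "C")
                + "\nENDMDL\nEND\n")
        s = parse_structure(text)
        assert s.chains == ["A", "B"]


class TestContacts:
    def two_atom_structure(self, d):
        text = "\n".join([
            atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            atom_line(2, "CA", "GLY", "B", 1, d, 0, 0, "C"),
            "END",
        ])
        return parse_structure(text)

    def test_carbon_pair_within_threshold(self):
        # r=1.7 each, probe 0.25 -> threshold 3.9
        s = self.two_atom_structure(3.8)
        contacts = compute_contacts(s, probe_radius=0.25)
        assert len(contacts.residue_pairs) == 1

    def test_carbon_pair_outside_threshold(self):
        s = self.two_atom_structure(4.0)
        contacts = compute_contacts(s, probe_radius=0.25)
        assert len(contacts.residue_pairs) == 0

    def test_probe_zero_pure_vdw(self):
        assert len(compute_contacts(self.two_atom_structure(3.39),
                                    0.0).residue_pairs) == 1
        assert len(compute_contacts(self.two_atom_structure(3.41),
                                    0.0).residue_pairs) == 0

    def test_monotone_in_probe(self):
        s = parse_structure(TWO_CHAIN_PDB)
        previous = set()
        for probe in (0.0, 0.1, 0.25, 0.5, 1.0):
            pairs = compute_contacts(s, probe).residue_pairs
            assert previous <= pairs
            previous = pairs


class TestInterface:
    def test_planted_interface_recovered(self, sbs_annotated, sbs_spec):
        _, truth, topology, _, _, _ = sbs_annotated
        assert topology.interface_size == 2 * sbs_spec.interface_width
        for chain in ("A", "B"):
            got = sorted(k.resnum for k in topology.interface_residues[chain])
            assert got == truth["interface"][chain]

    @pytest.mark.parametrize("probe", [0.1, 0.25, 0.5])
    def test_recovery_across_probe_range(self, sbs_dimer, probe):
        pdb_text, truth = sbs_dimer
        s = parse_structure(pdb_text)
        topology = identify_interface(s, compute_contacts(s, probe))
        got = sorted(k.resnum for k in topology.interface_residues["A"])
        assert got == truth["interface"]["A"]

    def test_ligand_only_contact_not_interface(self, sbs_annotated):
        # SBS LBRs touch only the ligand, never the other chain
        _, truth, topology, annotations, sites, _ = sbs_annotated
        interface = {k for ks in topology.interface_residues.values()
                     for k in ks}
        assert not (sites[0].lbr_set & interface)

    def test_monomer_errors(self):
        text = "\n".join([
            atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            atom_line(2, "CA", "GLY", "A", 2, 3.8, 0, 0, "C"),
            "END",
        ])
        s = parse_structure(text)
        with pytest.raises(ValueError, match="2 protein chains"):
            identify_interface(s, compute_contacts(s))

    def test_no_interchain_contacts_warns_empty(self):
        text = "\n".join([
            atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            atom_line(2, "CA", "GLY", "B", 1, 50, 0, 0, "C"),
            "END",
        ])
        s = parse_structure(text)
        with pytest.warns(UserWarning, match="empty interface"):
            topology = identify_interface(s, compute_contacts(s))
        assert topology.interface_size == 0


class TestSasa:
    def test_isolated_atom_analytic(self):
        for r, p in [(1.7, 0.21), (1.52, 1.4), (1.8, 0.0)]:
            area = shrake_rupley(np.zeros((1, 3)), np.array([r]), p)
            assert area[0] == pytest.approx(4 * np.pi * (r + p) ** 2,
                                            rel=1e-6)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        areas = shrake_rupley(coords, radii, 0.21)
        for i in range(2):
            assert areas[i] == pytest.approx(
                4 * np.pi * (radii[i] + 0.21) ** 2, rel=1e-6
            )

    def test_enclosed_atom_near_zero(self):
        # dense shell of atoms on a sphere of radius 3 around the center
        shell = sphere_points(200) * 3.0
        coords = np.vstack([[0.0, 0, 0], shell])
        radii = np.full(len(coords), 1.7)
        areas = shrake_rupley(coords, radii, 0.2)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_density_convergence(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 2.3]])
        radii = np.array([1.7, 1.7])
        a1 = shrake_rupley(coords, radii, 0.21, n_points=960).sum()
        a2 = shrake_rupley(coords, radii, 0.21, n_points=1920).sum()
        assert abs(a1 - a2) / a2 < 0.01

    def test_bad_point_count(self):
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((1, 3)), np.array([1.7]), 0.2, n_points=0)

    def test_occluders_reduce_area(self):
        coords = np.zeros((1, 3))
        radii = np.array([1.7])
        free = shrake_rupley(coords, radii, 0.21)[0]
        occluded = shrake_rupley(
            coords, radii, 0.21,
            occluder_coords=np.array([[2.0, 0, 0]]),
            occluder_radii=np.array([1.7]),
        )[0]
        assert occluded < free


class TestLigandBindingResidues:
    def test_planted_lbrs_recovered(self, sbs_annotated):
        s, truth, _, _, sites, _ = sbs_annotated
        got = {c: sorted(k.resnum for k in sites[0].lbr_set if k.chain == c)
               for c in "AB"}
        expected = truth["ligands"][sites[0].ligand_id]["lbrs"]
        assert got["A"] == expected["A"] and got["B"] == expected["B"]

    def test_distant_ligand_empty(self):
        text = TWO_CHAIN_PDB.replace(
            "END",
            atom_line(9, "C1", "LIG", "L", 900, 50.0, 50.0, 0, "C",
                      record="HETATM") + "\nEND",
        )
        s = parse_structure(text)
        assert identify_ligand_binding_residues(s, s.ligands[0]) == frozenset()

    def test_infinite_tolerance_empty(self, sbs_annotated):
        s = sbs_annotated[0]
        lig = next(l for l in s.ligands if not l.is_metal)
        assert identify_ligand_binding_residues(
            s, lig, tol=np.inf
        ) == frozenset()

    def test_metal_ligand_rejected(self):
        text = TWO_CHAIN_PDB.replace(
            "END",
            atom_line(9, "ZN", "ZN", "A", 90, 1.0, 0, 0, "ZN",
                      record="HETATM") + "\nEND",
        )
        s = parse_structure(text)
        with pytest.raises(ValueError, match="metal"):
            identify_ligand_binding_residues(s, s.ligands[0])


class TestBindingSiteClassification:
    def test_two_chain_site_is_mbs(self):
        lbrs = frozenset({ResidueKey("A", 1, ""), ResidueKey("B", 4, "")})
        assert classify_binding_site(lbrs).site_type == "MBS"

    def test_single_chain_site_is_sbs(self):
        lbrs = frozenset({ResidueKey("A", 1, ""), ResidueKey("A", 4, "")})
        assert classify_binding_site(lbrs).site_type == "SBS"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_binding_site(frozenset())

    def test_chain_relabeling_invariance(self):
        lbrs = frozenset({ResidueKey("A", 1, ""), ResidueKey("B", 4, "")})
        relabeled = frozenset(
            {ResidueKey("X", 1, ""), ResidueKey("Y", 4, "")}
        )
        assert (classify_binding_site(lbrs).site_type
                == classify_binding_site(relabeled).site_type)

    def test_two_mbs_sites_counted(self):
        pdb_text, truth = generate_dimer(
            DimerSpec(ligand_mode="MBS", n_mbs_sites=2, seed=3)
        )
        from quatfun.structure_annotation import annotate_structure
        s = parse_structure(pdb_text)
        topology, _, sites, _ = annotate_structure(
            s, rsa_reference=truth["rsa_reference"]
        )
        assert topology.n_mbs_sites == 2
        assert topology.complex_class == "MBS"


class TestSurface:
    def test_interface_residue_never_surface(self, sbs_annotated):
        _, _, topology, annotations, _, _ = sbs_annotated
        for keys in topology.interface_residues.values():
            for key in keys:
                assert not annotations[key].is_surface

    def test_lbr_never_surface(self, sbs_annotated):
        _, _, _, annotations, sites, _ = sbs_annotated
        for key in sites[0].lbr_set:
            assert not annotations[key].is_surface

    def test_planted_surface_recovered(self, sbs_annotated):
        _, truth, _, annotations, _, _ = sbs_annotated
        got = sorted((k.chain, k.resnum)
                     for k, a in annotations.items() if a.is_surface)
        expected = sorted((c, r) for c in "AB" for r in truth["surface"][c])
        assert got == expected

    def test_missing_reference_errors(self, sbs_annotated):
        s = sbs_annotated[0]
        _, per_residue = compute_sasa(s, 0.21, n_points=240)
        with pytest.raises(KeyError, match="missing from RSA reference"):
            identify_surface(s, per_residue, {"A": 129.0})

    def test_low_rsa_not_surface(self, sbs_annotated):
        s, truth = sbs_annotated[0], sbs_annotated[1]
        _, per_residue = compute_sasa(s, 0.21, n_points=240)
        # inflate the reference so every RSA falls below 0.2
        big = {aa: 1e6 for aa in MAX_SASA_GXG}
        surface, rsa = identify_surface(s, per_residue, big)
        assert surface == frozenset()
        assert all(v < 0.2 for v in rsa.values())


class TestLigandInterfaceDistance:
    def _structure(self, positions):
        lines = [
            atom_line(i + 1, "CA", "ALA", chain, resnum, *xyz, "C")
            for i, (chain, resnum, xyz) in enumerate(positions)
        ]
        return parse_structure("\n".join(lines + ["END"]))

    def test_constant_field(self):
        s = self._structure([
            ("A", 1, (0, 0, 0)), ("A", 2, (10, 0, 0)),
            ("A", 5, (0, 4, 0)), ("A", 6, (10, 4, 0)),
        ])
        interface = {ResidueKey("A", 1, ""), ResidueKey("A", 2, "")}
        lbrs = {ResidueKey("A", 5, ""), ResidueKey("A", 6, "")}
        assert ligand_interface_distance(s, interface, lbrs) == pytest.approx(4.0)

    def test_mixed_nearest_distances(self):
        # nearest-LBR distances are 3 and 5 -> mean 4
        s = self._structure([
            ("A", 1, (0, 0, 0)), ("A", 2, (100, 0, 0)),
            ("A", 5, (0, 3, 0)), ("A", 6, (100, 5, 0)),
        ])
        interface = {ResidueKey("A", 1, ""), ResidueKey("A", 2, "")}
        lbrs = {ResidueKey("A", 5, ""), ResidueKey("A", 6, "")}
        assert ligand_interface_distance(s, interface, lbrs) == pytest.approx(4.0)

    def test_single_interface_residue(self):
        s = self._structure([("A", 1, (0, 0, 0)), ("A", 5, (0, 7, 0))])
        assert ligand_interface_distance(
            s, {ResidueKey("A", 1, "")}, {ResidueKey("A", 5, "")}
        ) == pytest.approx(7.0)

    def test_empty_sets_error(self, sbs_annotated):
        s = sbs_annotated[0]
        with pytest.raises(ValueError):
            ligand_interface_distance(s, set(), {ResidueKey("A", 1, "")})

    def test_rigid_body_invariance(self, sbs_annotated, sbs_dimer):
        from scipy.spatial.transform import Rotation
        pdb_text, truth = sbs_dimer
        s = sbs_annotated[0]
        interface = {ResidueKey("A", r, "") for r in truth["interface"]["A"]}
        lbrs = {ResidueKey("A", r, "")
                for r in truth["ligands"]["LIG_L900"]["lbrs"]["A"]}
        base = ligand_interface_distance(s, interface, lbrs)

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        import dataclasses
        moved_atoms = [
            dataclasses.replace(a, coord=tuple(rot @ np.array(a.coord) + shift))
            for a in s.atoms
        ]
        moved = dataclasses.replace(s, atoms=moved_atoms)
        assert ligand_interface_distance(
            moved, interface, lbrs
        ) == pytest.approx(base, abs=1e-9)

    def test_all_pairs_policy_differs(self, sbs_annotated, sbs_dimer):
        pdb_text, truth = sbs_dimer
        s = sbs_annotated[0]
        interface = {ResidueKey("A", r, "") for r in truth["interface"]["A"]}
        lbrs = {ResidueKey("A", r, "")
                for r in truth["ligands"]["LIG_L900"]["lbrs"]["A"]}
        nearest = ligand_interface_distance(s, interface, lbrs,
                                            policy="nearest-lbr")
        allpairs = ligand_interface_distance(s, interface, lbrs,
                                             policy="all-pairs")
        assert allpairs > nearest


class TestHydrophobicFraction:
    def test_half(self):
        assert hydrophobic_fraction("LVKE") == pytest.approx(0.5)

    def test_all_glycine(self):
        assert hydrophobic_fraction("GGGG") == 0.0

    def test_all_cysteine(self):
        assert hydrophobic_fraction("CCC") == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            hydrophobic_fraction("")


def test_vdw_table_defaults():
    assert vdw_radius("C") == 1.70
    assert vdw_radius("N") == 1.55
    assert vdw_radius("O") == 1.52
    assert vdw_radius("SE") == 1.80   # unknown -> default
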