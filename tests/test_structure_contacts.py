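"""Interface geometry: superposition, contact criteria, SASA, GXGX."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phabkit.formats_io import Atom, StructureModel
from phabkit.numbering import NumberedPosition
from phabkit.structure_contacts import (
    AromaticRing,
    ContactCriteria,
    buried_surface,
    classify_pi_pi,
    detect_all_contacts,
    detect_hbonds,
    detect_pi_cation,
    detect_pi_pi,
    detect_water_bridges,
    extract_rings,
    find_gxgx,
    kabsch_superpose,
    paratope_shell,
    ring_geometry,
    sasa,
)
from phabkit.synthkit import make_interface


def _atom(serial, name, element, xyz, resname="ALA", resseq=1, chain="A", het=False):
    return Atom(serial=serial, name=name, element=element, residue_name=resname,
                residue_seq=resseq, insertion_code="", chain_id=chain,
                xyz=tuple(xyz), is_hetatm=het)


# --------------------------------------------------------------------------
# Kabsch superposition
# --------------------------------------------------------------------------

def test_superpose_identical_sets_gives_zero_rmsd():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(20, 3))
    res = kabsch_superpose(x, x)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)


def test_superpose_pure_translation():
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(15, 3))
    mob = ref + np.array([5.0, 0.0, 0.0])
    res = kabsch_superpose(ref, mob)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.translation, [-5.0, 0.0, 0.0], atol=1e-9)


def test_superpose_recovers_noise_level_rmsd():
    rng = np.random.default_rng(2)
    ref = rng.normal(scale=8.0, size=(100, 3))
    rot = Rotation.from_euler("z", 30, degrees=True)
    rmsds = []
    per_axis = 0.3 / math.sqrt(3.0)  # 0.3 A expected positional displacement
    for seed in range(5):
        noise = np.random.default_rng(seed).normal(scale=per_axis, size=(100, 3))
        mob = rot.apply(ref) + noise + 2.0
        rmsds.append(kabsch_superpose(ref, mob).rmsd)
    assert all(0.25 <= r <= 0.45 for r in rmsds)


def test_superpose_rmsd_matches_brute_force_recomputation():
    """Independent oracle: apply the transform and recompute the RMSD directly."""
    rng = np.random.default_rng(3)
    ref = rng.normal(scale=5.0, size=(40, 3))
    mob = Rotation.random(rng=4).apply(ref) + rng.normal(scale=0.5, size=(40, 3))
    res = kabsch_superpose(ref, mob)
    moved = res.apply(mob)
    brute = math.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    assert res.rmsd == pytest.approx(brute, rel=1e-9)


def test_superpose_rejects_degenerate_inputs():
    line = np.array([[float(i), 0.0, 0.0] for i in range(10)])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line)
    with pytest.raises(ValueError, match="3 atom"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# --------------------------------------------------------------------------
# Ring geometry
# --------------------------------------------------------------------------

def _ring(centroid, normal, radius=1.39):
    from phabkit.synthkit import _RING_NAMES, _hexagon

    atoms = [
        _atom(i + 1, n, "C", xyz, resname="PHE")
        for i, (n, xyz) in enumerate(zip(_RING_NAMES, _hexagon(np.asarray(centroid, float),
                                                               np.asarray(normal, float),
                                                               radius)))
    ]
    return AromaticRing.from_atoms(atoms)


def test_parallel_stacked_rings_geometry():
    a = _ring([0, 0, 0], [0, 0, 1])
    b = _ring([0, 0, 3.6], [0, 0, 1])
    d, ang, off = ring_geometry(a, b)
    assert (d, ang, off) == pytest.approx((3.6, 0.0, 0.0), abs=1e-9)


def test_prescribed_t_shaped_geometry_round_trips():
    model = make_interface("pi_pi", distance=5.0, angle=75.0, offset=1.5)
    rings_a = extract_rings(model.chain("A"))
    rings_b = extract_rings(model.chain("B"))
    d, ang, off = ring_geometry(rings_a[0], rings_b[0])
    assert d == pytest.approx(5.0, abs=1e-6)
    assert ang == pytest.approx(75.0, abs=1e-6)
    assert off == pytest.approx(1.5, abs=1e-6)


def test_offset_follows_pythagoras():
    a = _ring([0, 0, 0], [0, 0, 1])
    b = _ring([1.5, 0, 3.4], [0, 0, 1])
    d, ang, off = ring_geometry(a, b)
    assert d == pytest.approx(math.hypot(1.5, 3.4), abs=1e-9)
    assert ang == pytest.approx(0.0, abs=1e-9)
    assert off == pytest.approx(1.5, abs=1e-9)


def test_degenerate_ring_rejected():
    atoms = [_atom(i + 1, n, "C", (float(i), 0, 0)) for i, n in enumerate(["CG", "CD1", "CD2"])]
    with pytest.raises(ValueError, match="collinear"):
        AromaticRing.from_atoms(atoms)


# --------------------------------------------------------------------------
# Detectors on constructive fixtures
# --------------------------------------------------------------------------

def test_pi_pi_detection_and_classification():
    t_shaped = detect_pi_pi(make_interface("pi_pi", distance=5.0, angle=75.0),
                            ligand_chains={"B"})
    assert len(t_shaped) == 1 and t_shaped[0].classification == "T-shaped"
    parallel = detect_pi_pi(make_interface("pi_pi", distance=3.6, angle=0.0),
                            ligand_chains={"B"})
    assert len(parallel) == 1 and parallel[0].classification == "parallel"
    assert classify_pi_pi(45.0) == "intermediate"


def test_pi_pi_outside_range_rejected():
    assert detect_pi_pi(make_interface("pi_pi", distance=5.3, angle=75.0),
                        ligand_chains={"B"}) == []
    assert detect_pi_pi(make_interface("pi_pi", distance=3.2, angle=0.0),
                        ligand_chains={"B"}) == []


def test_hbond_detected_at_2p4_with_valid_angles():
    m = make_interface("hbond", da_distance=2.4, donor_angle=165.0, acceptor_angle=150.0)
    found = detect_hbonds(m, ligand_chains={"B"})
    assert len(found) == 1
    c = found[0]
    assert c.distance == pytest.approx(2.4, abs=1e-6)
    assert c.donor_angle == pytest.approx(165.0, abs=1e-6)
    assert c.acceptor_angle == pytest.approx(150.0, abs=1e-6)


def test_hbond_boundary_2p6_rejected_by_default_but_kept_conventionally():
    m = make_interface("hbond", da_distance=2.6, donor_angle=165.0, acceptor_angle=150.0)
    assert detect_hbonds(m, ligand_chains={"B"}) == []
    assert len(detect_hbonds(m, ContactCriteria.conventional(), ligand_chains={"B"})) == 1


def test_hbond_bad_donor_angle_rejected():
    m = make_interface("hbond", da_distance=2.4, donor_angle=100.0, acceptor_angle=150.0)
    assert detect_hbonds(m, ligand_chains={"B"}) == []


def test_water_bridge_detected_and_removed_with_water():
    m = make_interface("water_bridge", d_receptor=2.7, d_ligand=2.7)
    found = detect_water_bridges(m, ligand_chains={"B"})
    assert len(found) == 1
    assert found[0].distance == pytest.approx(2.7, abs=1e-6)
    dry = StructureModel(atoms=[a for a in m.atoms if not a.is_water])
    assert detect_water_bridges(dry, ligand_chains={"B"}) == []


def test_water_bridge_long_leg_rejected():
    m = make_interface("water_bridge", d_receptor=2.7, d_ligand=3.0)
    assert detect_water_bridges(m, ligand_chains={"B"}) == []


def test_pi_cation_distance_window():
    assert len(detect_pi_cation(make_interface("pi_cation", distance=4.2),
                                ligand_chains={"B"})) == 1
    assert detect_pi_cation(make_interface("pi_cation", distance=4.8),
                           ligand_chains={"B"}) == []


def test_cation_between_two_stacked_rings_contacts_only_the_near_one():
    from phabkit.synthkit import _RING_NAMES, _hexagon

    atoms = []
    for k, z in enumerate((0.0, 2.0)):
        for i, (n, xyz) in enumerate(
            zip(_RING_NAMES, _hexagon(np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0])))
        ):
            atoms.append(_atom(6 * k + i + 1, n, "C", xyz, resname="PHE", resseq=k + 1, chain="A"))
    atoms.append(_atom(13, "NZ", "N", (0, 0, 6.0), resname="LYS", resseq=1, chain="B"))
    model = StructureModel(atoms=atoms)
    found = detect_pi_cation(model, ligand_chains={"B"})
    assert len(found) == 1  # 4.0 A ring yes, 6.0 A ring no


def test_every_emitted_contact_revalidates_against_criteria():
    crit = ContactCriteria()
    for kind, params in [
        ("pi_pi", {"distance": 4.4, "angle": 80.0, "offset": 1.0}),
        ("hbond", {"da_distance": 2.3, "donor_angle": 150.0, "acceptor_angle": 140.0}),
        ("water_bridge", {"d_receptor": 2.6, "d_ligand": 2.75}),
        ("pi_cation", {"distance": 4.0}),
    ]:
        model = make_interface(kind, **params)
        for c in detect_all_contacts(model, crit, ligand_chains={"B"}):
            assert c.satisfies(crit)


def test_detectors_invariant_under_rigid_transforms():
    model = make_interface("pi_pi", distance=4.8, angle=70.0, offset=1.2)
    ref = detect_pi_pi(model, ligand_chains={"B"})[0]
    for seed in range(3):
        rot = Rotation.random(rng=seed)
        shift = np.random.default_rng(seed).normal(scale=20.0, size=3)
        moved = StructureModel(
            atoms=[
                Atom(**{**a.__dict__, "xyz": tuple(rot.apply(np.array(a.xyz)) + shift)})
                for a in model.atoms
            ]
        )
        c = detect_pi_pi(moved, ligand_chains={"B"})[0]
        assert c.distance == pytest.approx(ref.distance, abs=1e-9)
        assert c.interplanar_angle == pytest.approx(ref.interplanar_angle, abs=1e-7)
        assert c.offset == pytest.approx(ref.offset, abs=1e-9)


# --------------------------------------------------------------------------
# Paratope shell and GXGX
# --------------------------------------------------------------------------

def test_paratope_shell_inclusion_boundary():
    # side-chain CB at 9.5 from the antigen atom -> included at 10 A
    model = StructureModel(atoms=[
        _atom(1, "CB", "C", (0, 0, 0), resname="ALA", resseq=1, chain="H"),
        _atom(2, "P", "P", (9.5, 0, 0), resname="LIG", resseq=9, chain="P", het=True),
    ])
    inside = paratope_shell(model, ligand_chains={"P"}, radius=10.0)
    assert [k[:2] for k in inside] == [("H", 1)]
    model_far = StructureModel(atoms=[
        _atom(1, "CB", "C", (0, 0, 0), resname="ALA", resseq=1, chain="H"),
        _atom(2, "P", "P", (10.5, 0, 0), resname="LIG", resseq=9, chain="P", het=True),
    ])
    assert paratope_shell(model_far, ligand_chains={"P"}, radius=10.0) == []


def test_backbone_only_proximity_does_not_count():
    model = StructureModel(atoms=[
        _atom(1, "CA", "C", (0, 0, 0), resname="GLY", resseq=1, chain="H"),
        _atom(2, "P", "P", (5.0, 0, 0), resname="LIG", resseq=9, chain="P", het=True),
    ])
    assert paratope_shell(model, ligand_chains={"P"}, radius=10.0) == []


def test_contact_mode_shell_is_subset_of_radius_shell():
    for kind, params in [
        ("hbond", {"da_distance": 2.4, "donor_angle": 160.0, "acceptor_angle": 150.0}),
        ("pi_pi", {"distance": 4.6, "angle": 75.0}),
        ("pi_cation", {"distance": 4.0}),
    ]:
        model = make_interface(kind, **params)
        contact_res = set(paratope_shell(model, ligand_chains={"B"}, contact_mode=True))
        radius_res = set(paratope_shell(model, ligand_chains={"B"}, radius=10.0))
        assert contact_res <= radius_res


def _numbered_segment(spec):
    return [
        (NumberedPosition("kabat", n, ins, "H"), aa) for (n, ins), aa in spec
    ]


def test_gxgx_found_in_parental_cdr_h3():
    seg = _numbered_segment(zip([(95, ""), (96, ""), (97, ""), (98, ""), (99, "")], "LGSGN"))
    matches = find_gxgx(seg)
    assert len(matches) == 1
    g1, g2 = matches[0]
    assert (g1.render(), g2.render()) == ("96", "98")


def test_gxgx_found_in_matured_cdr_h3_at_same_positions():
    seg = _numbered_segment(zip([(95, ""), (96, ""), (97, ""), (98, ""), (99, "")], "LGTGS"))
    matches = find_gxgx(seg)
    assert [(a.render(), b.render()) for a, b in matches] == [("96", "98")]


def test_gxgx_absent_from_non_glycine_segment():
    seg = _numbered_segment(zip([(95, ""), (96, ""), (97, ""), (98, "")], "AAAA"))
    assert find_gxgx(seg) == []


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

def test_isolated_carbon_sasa_matches_sphere_area():
    a = _atom(1, "C", "C", (0, 0, 0))
    area = sasa([a], probe=1.7, n_points=960)[0]
    assert area == pytest.approx(4 * math.pi * 3.4**2, rel=0.01)


def test_distant_atoms_bury_nothing():
    a = _atom(1, "C", "C", (0, 0, 0))
    b = _atom(2, "C", "C", (100, 0, 0), chain="B")
    assert buried_surface([a], [b], probe=1.7, n_points=480) == pytest.approx(0.0, abs=1e-9)


def _two_sphere_exposed(r1, r2, d):
    """Analytic spherical-cap oracle for two overlapping spheres."""
    def exposed(ra, rb):
        if d >= ra + rb:
            return 4 * math.pi * ra * ra
        h = ra - (d * d + ra * ra - rb * rb) / (2 * d)
        return 4 * math.pi * ra * ra - 2 * math.pi * ra * h
    return exposed(r1, r2) + exposed(r2, r1)


def test_two_sphere_overlap_matches_cap_formula():
    probe = 1.7
    r = 1.7 + probe
    for d in (2.0, 3.0, 4.5):
        a = _atom(1, "C", "C", (0, 0, 0))
        b = _atom(2, "C", "C", (d, 0, 0))
        total = sasa([a, b], probe=probe, n_points=960).sum()
        assert total == pytest.approx(_two_sphere_exposed(r, r, d), rel=0.02)


def test_buried_surface_halved_with_per_side():
    a = [_atom(1, "C", "C", (0, 0, 0))]
    b = [_atom(2, "C", "C", (3.0, 0, 0), chain="B")]
    total = buried_surface(a, b, n_points=960)
    per_side = buried_surface(a, b, n_points=960, per_side=True)
    assert total > 0 and per_side == pytest.approx(total / 2)


def test_sasa_agrees_with_independent_biotite_implementation():
    import biotite.structure as struc

    rng = np.random.default_rng(8)
    coords = rng.normal(scale=3.0, size=(12, 3))
    atoms = [_atom(i + 1, "C", "C", xyz, resseq=i + 1) for i, xyz in enumerate(coords)]
    ours = sasa(atoms, probe=1.4, n_points=2000).sum()
    arr = struc.AtomArray(len(atoms))
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, len(atoms) + 1)
    arr.res_name[:] = "ALA"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    theirs = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                        vdw_radii="Single").sum()
    assert ours == pytest.approx(theirs, rel=0.03)


def test_sasa_rejects_empty_input():
    with pytest.raises(ValueError, match="no atoms"):
        sasa([])
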