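import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mtlattice as mt
from mtlattice import geometry as geo

from conftest import small_params, small_template


# ---------------------------------------------------------------------------
# mass center


def test_mass_center_symmetry():
    xyz = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    assert np.allclose(geo.mass_center(xyz, ["C", "C"]), 0.0)


def test_mass_center_weighted_hand_computed():
    # one C at origin, one O at (1,0,0): x = m_O / (m_C + m_O)
    xyz = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    c = geo.mass_center(xyz, ["C", "O"], weighting="mass")
    assert c[0] == pytest.approx(15.999 / (12.011 + 15.999), abs=1e-3)


def test_mass_center_geometric_equals_mass_for_carbon(rng):
    xyz = rng.normal(size=(50, 3))
    assert np.allclose(geo.mass_center(xyz, ["C"] * 50, "mass"),
                       geo.mass_center(xyz, ["C"] * 50, "geometric"))


def test_mass_center_empty_rejected():
    with pytest.raises(ValueError):
        geo.mass_center(np.empty((0, 3)), [])


# ---------------------------------------------------------------------------
# Kabsch superposition


def test_kabsch_identity(rng):
    xyz = rng.normal(size=(30, 3))
    R, t, rmsd, ang = geo.kabsch_superpose(xyz, xyz)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert ang == pytest.approx(0.0, abs=1e-6)


def test_kabsch_recovers_known_rotation(rng):
    xyz = rng.normal(size=(40, 3)) * [3, 7, 20]
    theta = 27.692
    Rz = Rotation.from_euler("z", theta, degrees=True).as_matrix()
    moved = xyz @ Rz.T + [5.0, -2.0, 11.0]
    _, _, rmsd, ang = geo.kabsch_superpose(xyz, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert ang == pytest.approx(theta, abs=1e-6)


def test_kabsch_noise_rmsd_monte_carlo(rng):
    # noise sigma per coordinate on one copy: E[rmsd] = sigma * sqrt(3)
    n, sigma = 10_000, 0.8
    xyz = rng.normal(size=(n, 3)) * [10, 20, 40]
    noisy = xyz + rng.normal(scale=sigma, size=(n, 3))
    _, _, rmsd, _ = geo.kabsch_superpose(noisy, xyz)
    assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.1)


def test_kabsch_degenerate_rejected(rng):
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(ValueError):
        geo.kabsch_superpose(line, line)
    with pytest.raises(ValueError):
        geo.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# lattice descriptors


def test_dimer_spacings_default_and_alternate_rise(default_annotation, default_singlet):
    model, _ = default_singlet
    d = geo.dimer_spacings(default_annotation, model, 0)
    assert len(d) == 5
    assert np.allclose(d, 80.0, atol=1e-9)

    params = small_params(dimer_rise=82.0)
    m2, _ = mt.build_singlet(params, small_template(params))
    ann2 = mt.annotate(m2)
    assert np.allclose(geo.dimer_spacings(ann2, m2, 3), 82.0, atol=1e-9)


def test_dimer_spacings_with_jitter(rng):
    params = small_params(n_repeats=8)
    model, _ = mt.build_singlet(params, small_template(params))
    jittered = model.copy()
    for atoms in jittered.chains.values():
        dx, dy, dz = rng.normal(scale=0.3, size=3)  # rigid per-chain jitter
        for a in atoms:
            a.x += dx
            a.y += dy
            a.z += dz
    ann = mt.annotate(jittered)
    vals = np.concatenate([geo.dimer_spacings(ann, jittered, pf) for pf in range(13)])
    assert abs(vals.mean() - 80.0) < 0.2


@pytest.mark.parametrize("n_pf", [12, 13])
def test_interprotofilament_angle_closed_form(n_pf):
    params = small_params(n_pf=n_pf)
    model, _ = mt.build_singlet(params, small_template(params))
    ann = mt.annotate(model)
    for iface in range(3):
        ang = geo.interprotofilament_angle(ann, model, iface)
        assert ang == pytest.approx(360.0 / n_pf, abs=0.05)


def test_superposing_dimer_on_itself_gives_zero(default_annotation, default_singlet):
    model, _ = default_singlet
    from mtlattice.geometry import _paired_dimer_coords

    xa, _ = _paired_dimer_coords(model, default_annotation, "S", 0, 1, 2)
    _, _, rmsd, ang = geo.kabsch_superpose(xa, xa)
    # arccos((tr-1)/2) near identity has a sqrt(2*eps) ~ 1e-6 deg floor
    assert ang == pytest.approx(0.0, abs=1e-5)


# ---------------------------------------------------------------------------
# tilt angle


def test_tilt_trivial_cases(rng):
    plane = rng.normal(size=(200, 3)) * [30, 30, 0.5]  # slab in xy
    rod_in_plane = np.outer(np.linspace(-20, 20, 10), [1.0, 0, 0])
    rod_normal = np.outer(np.linspace(-20, 20, 10), [0.0, 0, 1.0])
    assert geo.tilt_angle(rod_in_plane, plane[:100], plane[100:]) == pytest.approx(0.0, abs=0.5)
    assert geo.tilt_angle(rod_normal, plane[:100], plane[100:]) == pytest.approx(90.0, abs=0.5)


def test_tilt_parameter_recovery(default_singlet):
    model, truth = default_singlet
    res = mt.MicrotubuleLatticeModel(model, compute_interface_areas=False,
                                     compute_rmsd=False).fit()
    tilts = np.asarray(res.mip["TAI"]["tilt_deg"])
    assert np.all(np.abs(tilts - 51.5) < 0.5)


def test_tilt_degenerate_mip_rejected():
    with pytest.raises(ValueError):
        geo.tilt_angle(np.zeros((2, 3)), np.eye(3), np.eye(3))


# ---------------------------------------------------------------------------
# SASA and interface area


def test_sasa_single_atom_closed_form():
    area = geo.shrake_rupley_sasa(np.zeros((1, 3)), ["C"])
    assert area[0] == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)


def test_sasa_far_apart_atoms_additive():
    xyz = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    areas = geo.shrake_rupley_sasa(xyz, ["C", "N"])
    singles = [geo.shrake_rupley_sasa(xyz[i:i + 1], [e])[0] for i, e in enumerate(["C", "N"])]
    assert np.allclose(areas, singles)


def test_sasa_fully_buried_atom():
    from mtlattice.geometry import _fibonacci_sphere

    shell = 3.0 * _fibonacci_sphere(80)
    xyz = np.vstack([[0.0, 0, 0], shell])
    areas = geo.shrake_rupley_sasa(xyz, ["C"] * len(xyz))
    assert areas[0] < 1.0


def test_sasa_unknown_element_warns():
    with pytest.warns(UserWarning, match="vdW"):
        geo.shrake_rupley_sasa(np.zeros((1, 3)), ["Xx"])


def test_sasa_matches_biotite(rng):
    """Independent cross-check against biotite's Shrake-Rupley on one radii set."""
    biotite_struc = pytest.importorskip("biotite.structure")
    n = 60
    xyz = rng.normal(scale=4.0, size=(n, 3))
    mine = geo.shrake_rupley_sasa(xyz, ["C"] * n).sum()
    arr = biotite_struc.AtomArray(n)
    arr.coord = xyz.astype(np.float32)
    arr.element = np.array(["C"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.chain_id = np.array(["A"] * n)
    theirs = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960,
                                vdw_radii=np.full(n, 1.70)).sum()
    assert mine == pytest.approx(theirs, rel=0.02)


def test_interface_area_disjoint_zero():
    a = np.zeros((1, 3))
    b = np.array([[50.0, 0, 0]])
    assert geo.interface_area(a, ["C"], b, ["C"]) == pytest.approx(0.0, abs=1e-9)


def test_interface_area_symmetric(rng):
    a = rng.normal(scale=3, size=(20, 3))
    b = rng.normal(scale=3, size=(20, 3)) + [4.0, 0, 0]
    ab = geo.interface_area(a, ["C"] * 20, b, ["C"] * 20)
    ba = geo.interface_area(b, ["C"] * 20, a, ["C"] * 20)
    assert ab == pytest.approx(ba, abs=1e-9)
    assert ab > 0


def test_interface_area_two_spheres_matches_cap_formula():
    """ΔSASA/2 of two identical atoms equals the buried spherical-cap area."""
    d = 3.0
    R = 1.70 + 1.4
    h = R - d / 2.0
    expected = 2 * np.pi * R * h  # one cap per sphere, averaged over 2
    got = geo.interface_area(np.zeros((1, 3)), ["C"], np.array([[d, 0, 0]]), ["C"])
    assert got == pytest.approx(expected, rel=0.02)


# ---------------------------------------------------------------------------
# decoration descriptors


def test_periodicity_every_second_dimer():
    params = small_params(n_repeats=8)
    model, truth = mt.build_singlet(params, small_template(params))
    model, truth = mt.decorate_mips(model, truth,
                                    mt.MIPDecoration(class_name="sparse", periodicity=160.0))
    ann = mt.annotate(model)
    assert geo.axial_periodicity(ann, model, "SPA") == pytest.approx(16.0, abs=1e-6)


def test_periodicity_single_copy_undefined():
    params = small_params(n_repeats=2)
    model, truth = mt.build_singlet(params, small_template(params))
    # one copy per column: the decoration period spans the whole lattice
    model, truth = mt.decorate_mips(
        model, truth,
        mt.MIPDecoration(class_name="solo", periodicity=2 * params.dimer_rise))
    ann = mt.annotate(model)
    with pytest.raises(ValueError, match="undefined"):
        geo.axial_periodicity(ann, model, "SOL")


def test_handedness_flips_with_generator_sign():
    for sign, expected in ((-1, "left"), (1, "right")):
        params = small_params(handedness_sign=sign)
        model, truth = mt.build_singlet(params, small_template(params))
        model, truth = mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="tails"))
        ann = mt.annotate(model)
        assert geo.spiral_handedness(ann, model, "TAI") == expected


def test_handedness_flat_ring_is_none():
    params = small_params(n_starts=0)  # zero stagger: flat rings, no spiral
    model, truth = mt.build_singlet(params, small_template(params))
    model, truth = mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="ring"))
    ann = mt.assign_protofilaments(model)
    assert geo.spiral_handedness(ann, model, "RIN") == "none"


def test_copies_per_repeat_counts(default_annotation, default_singlet, doublet_arc):
    model, _ = default_singlet
    assert geo.copies_per_repeat(default_annotation, model, "TAI") == 12
    dmodel, _ = doublet_arc
    dann = mt.annotate(dmodel)
    assert geo.copies_per_repeat(dann, dmodel, "SPA") == 3


def test_copies_per_repeat_undecorated(default_annotation, default_singlet):
    model, _ = default_singlet
    assert geo.copies_per_repeat(default_annotation, model, "NOPE") == 0


# ---------------------------------------------------------------------------
# MIP pairwise RMSD


def test_identical_copies_rmsd_zero():
    params = small_params(n_repeats=2)
    model, truth = mt.build_singlet(params, small_template(params))
    model, truth = mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="tails"))
    ann = mt.annotate(model)
    _, M = geo.mip_pairwise_rmsd(ann, model, "TAI")
    off = M[~np.eye(len(M), dtype=bool)]
    assert np.abs(off).max() < 1e-6
    assert np.abs(M - M.T).max() < 1e-3


def test_perturbed_copies_rmsd_monte_carlo(rng):
    """Two copies jittered with per-coordinate sigma: E[RMSD] = sigma*sqrt(6)
    (both copies independently perturbed)."""
    params = small_params(n_repeats=2)
    model, truth = mt.build_singlet(params, mt.build_dimer_template(200, seed=0))
    model, truth = mt.decorate_mips(
        model, truth, mt.MIPDecoration(class_name="tails", pf_span=[0, 5], n_atoms=400))
    sigma = 1.0
    for cid in [c for c in model.chains if c.startswith("TAI")]:
        for a in model.chains[cid]:
            d = rng.normal(scale=sigma, size=3)
            a.x += d[0]
            a.y += d[1]
            a.z += d[2]
    ann = mt.annotate(model)
    _, M = geo.mip_pairwise_rmsd(ann, model, "TAI")
    off = M[~np.eye(len(M), dtype=bool)]
    assert np.median(off) == pytest.approx(sigma * np.sqrt(6), rel=0.15)


# ---------------------------------------------------------------------------
# rigid-body invariance of the whole report


def test_descriptors_invariant_to_rigid_motion(rng):
    params = small_params()
    model, truth = mt.build_singlet(params, small_template(params))
    model, truth = mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="tails"))
    R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    moved = model.transformed(R, np.array([120.0, -40.0, 300.0]))
    kw = dict(compute_interface_areas=False, compute_rmsd=False)
    r0 = mt.MicrotubuleLatticeModel(model, **kw).fit()
    r1 = mt.MicrotubuleLatticeModel(moved, **kw).fit()
    for key in r0.spacings:
        assert np.allclose(r0.spacings[key], r1.spacings[key], atol=1e-3)
    for key in r0.ipf_angles:
        assert r0.ipf_angles[key] == pytest.approx(r1.ipf_angles[key], abs=1e-3)
    t0 = np.asarray(r0.mip["TAI"]["tilt_deg"])
    t1 = np.asarray(r1.mip["TAI"]["tilt_deg"])
    assert np.allclose(t0, t1, atol=1e-3)
    assert r0.mip["TAI"]["handedness"] == r1.mip["TAI"]["handedness"]
    assert r0.mip["TAI"]["copies_per_repeat"] == r1.mip["TAI"]["copies_per_repeat"]
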