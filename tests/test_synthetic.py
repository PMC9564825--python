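import numpy as np
import pytest

import mtlattice as mt
from mtlattice.synthetic import ALPHA_RES, BETA_RES

from conftest import small_params, small_template


# ---------------------------------------------------------------------------
# dimer template


def test_template_centered_and_deterministic():
    t1 = mt.build_dimer_template(n_atoms_per_monomer=30, seed=7)
    t2 = mt.build_dimer_template(n_atoms_per_monomer=30, seed=7)
    assert np.allclose(t1.coords(), t2.coords())
    assert np.abs(t1.coords().mean(axis=0)).max() < 1e-6


def test_template_principal_axis_along_z():
    t = mt.build_dimer_template(n_atoms_per_monomer=50, seed=3)
    xyz = t.coords()
    cov = np.cov((xyz - xyz.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    main = evecs[:, np.argmax(evals)]
    angle = np.degrees(np.arccos(abs(main @ [0, 0, 1.0])))
    assert angle < 1e-3


def test_template_monomers_distinguishable():
    t = mt.build_dimer_template(n_atoms_per_monomer=10, seed=0)
    assert t.chain_res_names("a") == {ALPHA_RES}
    assert t.chain_res_names("b") == {BETA_RES}
    # alpha sits below beta (plus end up)
    assert t.coords(["a"])[:, 2].mean() < t.coords(["b"])[:, 2].mean()


def test_template_too_few_atoms_rejected():
    with pytest.raises(ValueError):
        mt.build_dimer_template(n_atoms_per_monomer=3)


# ---------------------------------------------------------------------------
# singlet lattice


def nearest_lateral_class_counts(model, truth):
    """Brute-force count of heterotypic lateral interfaces from coordinates."""
    lat = truth.lattice
    by_chain = {
        cid: (lab["pf_index"], lab["role"], model.coords([cid]).mean(axis=0))
        for cid, lab in truth.chain_labels.items()
        if lab["role"] in ("alpha", "beta") and lab["tubule"] in ("S", "A")
    }
    het = {}
    for j in range(lat.n_pf):
        pf_b = (j + 1) % lat.n_pf
        a_items = [(r, c) for (pf, r, c) in by_chain.values() if pf == j]
        b_items = [(r, c) for (pf, r, c) in by_chain.values() if pf == pf_b]
        flags = []
        for r, c in a_items:
            d = [np.linalg.norm(c - cb) for _, cb in b_items]
            k = int(np.argmin(d))
            if abs(b_items[k][1][2] - c[2]) < 0.75 * lat.monomer_len:
                flags.append(r != b_items[k][0])
        het[j] = np.mean(flags)
    return het


def test_singlet_counts_and_single_seam(default_singlet):
    model, truth = default_singlet
    lat = truth.lattice
    tub_chains = [c for c, l in truth.chain_labels.items() if l["role"] in ("alpha", "beta")]
    assert lat.n_pf == 13
    assert len(tub_chains) == 13 * 6 * 2  # 78 dimers
    het = nearest_lateral_class_counts(model, truth)
    seams = [j for j, f in het.items() if f > 0.5]
    assert seams == [lat.seam_index]
    assert all(f == 0.0 for j, f in het.items() if j != lat.seam_index)


def test_singlet_dimer_spacing_by_construction(default_singlet):
    model, truth = default_singlet
    for pf in range(13):
        centers = []
        for k in range(truth.lattice.n_repeats):
            cids = [c for c, l in truth.chain_labels.items()
                    if l["role"] in ("alpha", "beta") and l["pf_index"] == pf
                    and l["axial_index"] == k]
            centers.append(model.coords(cids).mean(axis=0))
        d = np.linalg.norm(np.diff(np.array(centers), axis=0), axis=1)
        assert np.allclose(d, 80.0, atol=1e-9)


def test_14pf_closure_adjusts_stagger_and_keeps_one_seam():
    params = small_params(n_pf=14)
    assert params.stagger == pytest.approx(3 * params.monomer_len / 14)
    model, truth = mt.build_singlet(params, small_template(params))
    het = nearest_lateral_class_counts(model, truth)
    assert sum(f > 0.5 for f in het.values()) == 1


def test_explicit_bad_stagger_warns_and_adjusts():
    with pytest.warns(UserWarning, match="closure"):
        p = mt.LatticeParams(stagger=7.0)
    assert p.stagger == pytest.approx(3 * 40.0 / 13)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        mt.LatticeParams(n_pf=2)
    with pytest.raises(ValueError):
        mt.LatticeParams(dimer_rise=-1)
    with pytest.raises(ValueError):
        mt.LatticeParams(seam_index=13)


# ---------------------------------------------------------------------------
# doublet


def test_doublet_labels_present(doublet_arc):
    model, truth = doublet_arc
    prefixes = {c[:3] for c in model.chains if c[0] in "AB"}
    assert {f"A{i:02d}" for i in range(1, 14)} <= prefixes
    assert {f"B{i:02d}" for i in range(1, 11)} <= prefixes
    assert truth.n_pf_B == 10


def test_doublet_b_arc_is_open(doublet_arc):
    """The B tubule arc has n_pf_B - 1 = 9 lateral interfaces and no seam."""
    model, truth = doublet_arc
    ann = mt.annotate(model)
    assert ann.tubules["B"].closed is False
    assert len(ann.tubules["B"].interfaces) == 9
    assert ann.tubules["B"].seam_interface is None


def test_doublet_a_tubule_matches_singlet():
    params = small_params()
    tpl = small_template(params)
    dm, dt = mt.build_doublet(params, template=tpl)
    sm, st = mt.build_singlet(params, template=tpl)
    a_xyz = dm.coords([c for c in dm.chains if c.startswith("A")])
    s_xyz = sm.coords()
    assert np.allclose(a_xyz, s_xyz)


def test_doublet_needs_enough_b_pfs():
    with pytest.raises(ValueError):
        mt.build_doublet(n_pf_B=3)


# ---------------------------------------------------------------------------
# decoration


def test_full_spiral_copy_count(default_singlet):
    _, truth = default_singlet
    dec = truth.decorations[0]
    # 12 decorated interfaces x 6 axial repeats
    assert len(dec.placements) == 12 * 6
    interfaces = {p[0] for p in dec.placements}
    assert truth.lattice.seam_index not in interfaces
    assert len(interfaces) == 12


def test_arc_decoration_three_interfaces(doublet_arc):
    _, truth = doublet_arc
    dec = truth.decorations[0]
    assert len({p[0] for p in dec.placements}) == 3


def test_explicit_seam_decoration_rejected(default_singlet):
    model, truth = default_singlet
    with pytest.raises(ValueError, match="seam"):
        mt.decorate_mips(model, truth,
                         mt.MIPDecoration(class_name="bad", pf_span=[truth.lattice.seam_index]))


def test_zero_tilt_rods_lie_in_plane():
    params = small_params()
    model, truth = mt.build_singlet(params, small_template(params))
    model, truth = mt.decorate_mips(model, truth,
                                    mt.MIPDecoration(class_name="flat", tilt=0.0))
    res = mt.MicrotubuleLatticeModel(model, compute_interface_areas=False,
                                     compute_rmsd=False).fit()
    tilts = np.array(res.mip["FLA"]["tilt_deg"])
    assert np.nanmax(np.abs(tilts)) < 0.5


def test_bad_periodicity_rejected(default_singlet):
    model, truth = default_singlet
    with pytest.raises(ValueError, match="periodicity"):
        mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="x", periodicity=33.0))


def test_longitudinal_filament_mode():
    params = small_params()
    model, truth = mt.build_singlet(params, small_template(params))
    model, truth = mt.decorate_mips(
        model, truth,
        mt.MIPDecoration(class_name="saxo", mode="longitudinal_filament", pf_span=[0, 1]),
    )
    dec = truth.decorations[0]
    assert len(dec.placements) == 2 * params.n_repeats
    assert all(np.allclose(p[3], [0, 0, 1.0]) for p in dec.placements)


def test_ground_truth_roundtrip(tmp_path, default_singlet):
    _, truth = default_singlet
    p = str(tmp_path / "gt.json")
    truth.to_json(p)
    back = mt.GroundTruth.from_json(p)
    assert back.lattice.to_dict() == truth.lattice.to_dict()
    assert back.chain_labels == truth.chain_labels
    assert len(back.decorations[0].placements) == len(truth.decorations[0].placements)
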