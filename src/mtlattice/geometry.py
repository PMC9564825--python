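"""Geometric descriptors of microtubule lattices and their MIP decorations.

Mass centers, Kabsch superposition and rotation angles, longitudinal dimer
spacings, interprotofilament rotation angles, MIP tilt angles against the
flanking-dimer plane, Shrake–Rupley solvent-accessible surface area and
ΔSASA/2 interface burial, axial periodicity, spiral handedness, copy counts
per repeat, and pairwise RMSD of MIP copies after superposing their
associated α-tubulins.

All angles are reported in degrees, distances in Å, and periodicities in nm
at the reporting layer (Å/10).
"""

from __future__ import annotations

import warnings

import gemmi
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .annotate import LatticeAnnotation
from .model_io import StructureModel

__all__ = [
    "mass_center",
    "kabsch_superpose",
    "dimer_spacings",
    "interprotofilament_angle",
    "tilt_angle",
    "shrake_rupley_sasa",
    "interface_area",
    "axial_periodicity",
    "spiral_handedness",
    "copies_per_repeat",
    "mip_pairwise_rmsd",
]

#: van der Waals radii (Å) used for SASA; unknown elements fall back to C
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70


# ---------------------------------------------------------------------------
# mass centers and superposition


def mass_center(coords: np.ndarray, elements=None, weighting: str = "mass") -> np.ndarray:
    """Weighted mean position; mass weighting uses standard atomic masses."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("mass_center of an empty selection")
    if weighting == "geometric" or elements is None:
        return coords.mean(axis=0)
    if weighting != "mass":
        raise ValueError("weighting must be 'mass' or 'geometric'")
    w = np.array([gemmi.Element(e).weight for e in elements], float)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def chain_mass_center(model: StructureModel, chain_ids, weighting: str = "mass") -> np.ndarray:
    return mass_center(model.coords(chain_ids), model.elements(chain_ids), weighting)


def kabsch_superpose(mobile: np.ndarray, ref: np.ndarray):
    """Least-squares proper rotation mapping ``mobile`` onto ``ref``.

    Returns (R, t, rmsd, rotation_angle_deg) with x_ref ≈ R @ x_mobile + t.
    The rotation angle is arccos((trace(R) - 1) / 2). Reflection-optimal
    cases are resolved to a proper rotation (det(R) = +1).
    """
    mobile = np.asarray(mobile, float).reshape(-1, 3)
    ref = np.asarray(ref, float).reshape(-1, 3)
    if mobile.shape != ref.shape:
        raise ValueError(f"paired sets differ in size: {mobile.shape} vs {ref.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    cm, cr = mobile.mean(axis=0), ref.mean(axis=0)
    P, Q = mobile - cm, ref - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("collinear atom sets: rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    diff = (mobile @ R.T + t) - ref
    rmsd = float(np.sqrt((diff**2).sum() / n))
    angle = float(np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))
    return R, t, rmsd, angle


# ---------------------------------------------------------------------------
# lattice descriptors


def _dimer_center(model: StructureModel, ann: LatticeAnnotation, tubule: str,
                  pf: int, k: int, weighting: str = "mass") -> np.ndarray:
    cids = dict(ann.dimers(tubule, pf)).get(k)
    if not cids:
        raise ValueError(f"no dimer at pf {pf}, axial {k}")
    return chain_mass_center(model, cids, weighting)


def dimer_spacings(ann: LatticeAnnotation, model: StructureModel, pf_index: int,
                   tubule: str | None = None, weighting: str = "mass") -> np.ndarray:
    """Distances between mass centers of consecutive dimers along one
    protofilament: n dimers yield n - 1 measurements."""
    tubule = tubule or ann.primary_tubule
    dimers = ann.dimers(tubule, pf_index)
    if len(dimers) < 2:
        raise ValueError(f"pf {pf_index}: need >= 2 dimers for spacings")
    centers = np.array([chain_mass_center(model, cids, weighting) for _, cids in dimers])
    return np.linalg.norm(np.diff(centers, axis=0), axis=1)


def _paired_dimer_coords(model: StructureModel, ann: LatticeAnnotation, tubule: str,
                         pf_a: int, pf_b: int, k: int):
    """Atom-paired coordinate sets of the dimers at axial level k on two
    adjacent pfs, matched by monomer class, residue number and atom name."""
    da = dict(ann.dimers(tubule, pf_a)).get(k)
    db = dict(ann.dimers(tubule, pf_b)).get(k)
    if not da or not db:
        raise ValueError(f"no dimer pair at axial level {k} on pfs {pf_a},{pf_b}")
    xa, xb = [], []
    for role in ("alpha", "beta", "tubulin"):
        ca = [c for c in da if ann.chains[c].role == role]
        cb = [c for c in db if ann.chains[c].role == role]
        for c1, c2 in zip(ca, cb):
            a1 = {(a.res_seq, a.name): (a.x, a.y, a.z) for a in model.chains[c1]
                  if a.element.upper() not in ("H", "D")}
            a2 = {(a.res_seq, a.name): (a.x, a.y, a.z) for a in model.chains[c2]
                  if a.element.upper() not in ("H", "D")}
            keys = [key for key in a1 if key in a2]
            if not keys:
                raise ValueError(f"no residue correspondence between chains {c1} and {c2}")
            xa.extend(a1[key] for key in keys)
            xb.extend(a2[key] for key in keys)
    return np.array(xa), np.array(xb)


def interprotofilament_angle(ann: LatticeAnnotation, model: StructureModel,
                             interface: int, tubule: str | None = None,
                             axial_level: int | None = None) -> float:
    """Rotation angle (deg) of the rigid superposition mapping a tubulin
    dimer onto its lateral neighbor across the given interface; 360/N for an
    ideal N-protofilament tube."""
    tubule = tubule or ann.primary_tubule
    info = ann.tubules[tubule]
    pf_a, pf_b = info.interfaces[interface]
    if axial_level is None:
        ka = {k for k, _ in ann.dimers(tubule, pf_a)}
        kb = {k for k, _ in ann.dimers(tubule, pf_b)}
        common = sorted(ka & kb)
        if not common:
            raise ValueError(f"interface {interface}: no matched axial level")
        axial_level = common[len(common) // 2]
    xa, xb = _paired_dimer_coords(model, ann, tubule, pf_a, pf_b, axial_level)
    _, _, _, angle = kabsch_superpose(xa, xb)
    return angle


def tilt_angle(mip_coords: np.ndarray, dimer_a_coords: np.ndarray,
               dimer_b_coords: np.ndarray) -> float:
    """Angle (deg, in [0, 90]) between the MIP's long axis (largest-variance
    principal direction) and the least-squares plane over all atoms of the
    two flanking tubulin dimers."""
    mip = np.asarray(mip_coords, float).reshape(-1, 3)
    if mip.shape[0] < 3:
        raise ValueError("MIP needs >= 3 atoms for an axis fit")
    both = np.vstack([np.asarray(dimer_a_coords, float).reshape(-1, 3),
                      np.asarray(dimer_b_coords, float).reshape(-1, 3)])
    _, sp, vtp = np.linalg.svd(both - both.mean(axis=0), full_matrices=False)
    normal = vtp[-1]
    _, sm, vtm = np.linalg.svd(mip - mip.mean(axis=0), full_matrices=False)
    if sm[0] < 1e-9:
        raise ValueError("degenerate MIP geometry: no principal axis")
    axis = vtm[0]
    ang_to_normal = np.degrees(np.arccos(np.clip(abs(axis @ normal), 0.0, 1.0)))
    return float(90.0 - ang_to_normal)


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _vdw_radii(elements) -> np.ndarray:
    out = np.empty(len(elements))
    unknown = set()
    for i, e in enumerate(elements):
        key = e.capitalize() if len(e) > 1 else e.upper()
        r = VDW_RADII.get(e.upper(), VDW_RADII.get(key))
        if r is None:
            unknown.add(e)
            r = DEFAULT_VDW
        out[i] = r
    if unknown:
        warnings.warn(f"unknown elements {sorted(unknown)}: using default vdW radius {DEFAULT_VDW} Å")
    return out


def shrake_rupley_sasa(coords: np.ndarray, elements, probe_radius: float = 1.4,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²), Shrake–Rupley.

    For each atom, the fraction of quasi-uniform test points on the sphere
    of radius r_vdw + probe not buried inside any neighbor's expanded
    sphere, times that sphere's area.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("SASA of an empty selection")
    radii = _vdw_radii(elements) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.empty(n)
    for i in range(n):
        nbr = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        nbr = [j for j in nbr if np.dot(coords[j] - coords[i], coords[j] - coords[i])
               < (radii[i] + radii[j]) ** 2]
        full = 4.0 * np.pi * radii[i] ** 2
        if not nbr:
            areas[i] = full
            continue
        pts = coords[i] + radii[i] * sphere
        nc = coords[np.array(nbr)]
        nr2 = radii[np.array(nbr)] ** 2
        d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < nr2[None, :]).any(axis=1)
        areas[i] = full * float((~buried).mean())
    return areas


def interface_area(coords_a: np.ndarray, elements_a, coords_b: np.ndarray, elements_b,
                   probe_radius: float = 1.4, n_points: int = 960) -> float:
    """Buried interface area (Å²) between two parts, the ΔSASA/2 convention:
    (SASA(A) + SASA(B) - SASA(A ∪ B)) / 2."""
    coords_a = np.asarray(coords_a, float).reshape(-1, 3)
    coords_b = np.asarray(coords_b, float).reshape(-1, 3)
    if coords_a.shape[0] == 0 or coords_b.shape[0] == 0:
        raise ValueError("interface_area: both parts must be non-empty")
    sa = shrake_rupley_sasa(coords_a, elements_a, probe_radius, n_points).sum()
    sb = shrake_rupley_sasa(coords_b, elements_b, probe_radius, n_points).sum()
    sab = shrake_rupley_sasa(
        np.vstack([coords_a, coords_b]), list(elements_a) + list(elements_b),
        probe_radius, n_points,
    ).sum()
    return float((sa + sb - sab) / 2.0)


# ---------------------------------------------------------------------------
# decoration descriptors


def _mip_copy_geometry(ann: LatticeAnnotation, model: StructureModel, class_name: str):
    """(chain ids, centers, axial z, azimuth, column labels) of a MIP class.

    Columns are clusters of copies sharing a lateral position (projection
    perpendicular to their tubule's axis), linked at a 6-Å cutoff.
    """
    cids = ann.mip_chains(class_name)
    if not cids:
        return [], np.empty((0, 3)), np.empty(0), np.empty(0), np.empty(0, int)
    centers = np.array([model.coords([c]).mean(axis=0) for c in cids])
    tubules = [ann.chains[c].tubule for c in cids]
    tub = max(set(tubules), key=tubules.count)
    info = ann.tubules[tub]
    rel = centers - info.axis_point
    z = rel @ info.axis_dir
    perp = rel - np.outer(z, info.axis_dir)
    phi = np.arctan2(perp @ _perp2(info.axis_dir), perp @ _perp1(info.axis_dir))
    if len(cids) == 1:
        cols = np.zeros(1, int)
    else:
        cols = fcluster(linkage(perp, method="single"), t=6.0, criterion="distance") - 1
    return cids, centers, z, phi, cols


def _perp1(axis):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    return e1 / np.linalg.norm(e1)


def _perp2(axis):
    return np.cross(axis, _perp1(axis))


def axial_periodicity(ann: LatticeAnnotation, model: StructureModel, class_name: str) -> float:
    """Axial repeat of a decoration class in nm: the median consecutive
    axial spacing of copies within each lateral column."""
    cids, _, z, _, cols = _mip_copy_geometry(ann, model, class_name)
    diffs = []
    for c in np.unique(cols):
        zc = np.sort(z[cols == c])
        if len(zc) >= 2:
            diffs.extend(np.diff(zc))
    if not diffs:
        raise ValueError(f"{class_name}: periodicity undefined (fewer than 2 copies per column)")
    return float(np.median(diffs)) / 10.0


def copies_per_repeat(ann: LatticeAnnotation, model: StructureModel, class_name: str) -> int:
    """Number of copies of a decoration class whose axial centers fall in
    one periodicity-long window around the middle of the decorated span."""
    cids, _, z, _, cols = _mip_copy_geometry(ann, model, class_name)
    if len(cids) == 0:
        return 0
    if len(cids) == 1:
        return 1
    try:
        p = axial_periodicity(ann, model, class_name) * 10.0
    except ValueError:
        return len(cids)  # no axial repetition: all copies form one repeat
    mid = (z.min() + z.max()) / 2.0
    lo = mid - p / 2.0
    return int(np.sum((z >= lo) & (z < lo + p)))


def spiral_handedness(ann: LatticeAnnotation, model: StructureModel, class_name: str,
                      z_tolerance: float = 0.5) -> str:
    """Handedness of a lateral decoration path viewed from the plus end.

    For each pair of azimuthally adjacent columns, take the signed axial
    offset of the nearest copies and the signed azimuthal step; a negative
    median dz/dphi (rising while turning clockwise seen from +z) is a
    left-handed spiral, positive is right-handed, |dz| below ``z_tolerance``
    is no spiral at all.
    """
    cids, _, z, phi, cols = _mip_copy_geometry(ann, model, class_name)
    uniq = np.unique(cols)
    if len(uniq) < 3:
        raise ValueError(f"{class_name}: need copies on >= 3 interfaces to call handedness")
    col_phi = np.array([np.median(phi[cols == c]) for c in uniq])
    order = np.argsort(col_phi)
    slopes, dzs = [], []
    for a, b in zip(order, np.roll(order, -1)):
        dphi = (col_phi[b] - col_phi[a] + np.pi) % (2 * np.pi) - np.pi
        if abs(dphi) < 1e-9:
            continue
        za, zb = z[cols == uniq[a]], z[cols == uniq[b]]
        # nearest-copy signed axial offset between the two columns
        dz_all = zb[None, :] - za[:, None]
        dz = dz_all.flat[np.argmin(np.abs(dz_all))]
        slopes.append(dz / dphi)
        dzs.append(abs(dz))
    if float(np.median(dzs)) < z_tolerance:
        return "none"
    return "left" if float(np.median(slopes)) < 0 else "right"


# ---------------------------------------------------------------------------
# MIP copy comparison


def _associated_alpha(ann: LatticeAnnotation, model: StructureModel, mip_cid: str,
                      search_radius: float = 80.0, min_area: float = 1.0) -> str:
    """The α-tubulin associated with a MIP copy: the α sharing the largest
    ΔSASA/2 contact area (ties and zero-contact cases fall back to the
    nearest mass center; ties break to the lower pf then axial index)."""
    tub = ann.chains[mip_cid].tubule
    mc = model.coords([mip_cid]).mean(axis=0)
    cands = []
    for cid, a in ann.chains.items():
        if a.role == "alpha" and a.tubule == tub:
            d = float(np.linalg.norm(model.coords([cid]).mean(axis=0) - mc))
            if d < search_radius:
                cands.append((cid, d))
    if not cands:
        raise ValueError(f"{mip_cid}: no alpha-tubulin within {search_radius} Å")
    mip_xyz, mip_el = model.coords([mip_cid]), model.elements([mip_cid])
    scored = []
    for cid, d in cands:
        area = interface_area(mip_xyz, mip_el, model.coords([cid]), model.elements([cid]),
                              n_points=240)
        a = ann.chains[cid]
        scored.append((-area, d, a.pf_index or 0, a.axial_index or 0, cid))
    scored.sort()
    if -scored[0][0] >= min_area:
        return scored[0][4]
    return min(cands, key=lambda t: t[1])[0]


def _paired_chain_coords(model: StructureModel, c1: str, c2: str):
    a1 = {(a.res_seq, a.name): (a.x, a.y, a.z) for a in model.chains[c1]
          if a.element.upper() not in ("H", "D")}
    a2 = {(a.res_seq, a.name): (a.x, a.y, a.z) for a in model.chains[c2]
          if a.element.upper() not in ("H", "D")}
    keys = [k for k in a1 if k in a2]
    if len(keys) < 3:
        raise ValueError(f"chains {c1} and {c2}: no usable residue correspondence")
    return np.array([a1[k] for k in keys]), np.array([a2[k] for k in keys])


def mip_pairwise_rmsd(ann: LatticeAnnotation, model: StructureModel, class_name: str) -> tuple[list[str], np.ndarray]:
    """Pairwise RMSD matrix over MIP copies after superposing each copy's
    associated α-tubulin onto the other's.

    Returns (copy chain ids, matrix). Entry (i, j) superposes copy j's α
    onto copy i's, applies that transform to copy j, and measures the RMSD
    against copy i over correspondence-paired atoms.
    """
    cids = ann.mip_chains(class_name)
    if len(cids) < 2:
        raise ValueError(f"{class_name}: need >= 2 copies")
    alphas = {c: _associated_alpha(ann, model, c) for c in cids}
    n = len(cids)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aj, ai = _paired_chain_coords(model, alphas[cids[j]], alphas[cids[i]])
            R, t, _, _ = kabsch_superpose(aj, ai)
            mj, mi = _paired_chain_coords(model, cids[j], cids[i])
            diff = (mj @ R.T + t) - mi
            M[i, j] = M[j, i] = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return cids, M
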