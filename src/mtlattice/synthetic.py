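"""Idealized microtubule lattices with known ground truth.

Builds pseudo-atomic singlet and doublet microtubule models on an exact
helical lattice — protofilaments of stacked tubulin dimers with a 3-start
lateral stagger producing exactly one seam — and decorates them with
microtubule inner protein (MIP) markers in the binding modes seen in
ciliary microtubules: arcs or full non-seam spirals spanning lateral
interfaces, and longitudinal filaments running along protofilaments.

Coordinate convention: helical axis along z, plus end toward +z under
``plus_up`` polarity, azimuth counterclockwise viewed from +z.
``handedness_sign = -1`` (default) places protofilament i at azimuth
``-2*pi*i/n_pf``, so a decoration path that climbs in z advances clockwise
viewed from the plus end — a left-handed spiral.

Every generated chain is recorded in a :class:`GroundTruth` side-car so
downstream annotation and geometry can be validated exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .model_io import AtomRecord, StructureModel

__all__ = [
    "LatticeParams",
    "MIPDecoration",
    "GroundTruth",
    "build_dimer_template",
    "build_singlet",
    "build_doublet",
    "decorate_mips",
]

#: residue-name markers used by the generator; annotation recognizes them
ALPHA_RES = "TBA"
BETA_RES = "TBB"


def mip_res_code(class_name: str) -> str:
    """3-letter residue code for a MIP class ('tails' -> 'TAI')."""
    code = "".join(ch for ch in class_name.upper() if ch.isalnum())[:3]
    return (code + "XXX")[:3]


@dataclass
class LatticeParams:
    """Helical bookkeeping of an ideal microtubule lattice.

    Defaults describe a canonical 13-protofilament B-lattice: 80 Å (8 nm)
    dimer rise, 3-start lateral stagger (3 monomer lengths per turn, hence
    one seam), 105 Å wall radius.
    """

    n_pf: int = 13
    dimer_rise: float = 80.0
    monomer_len: float | None = None  # default dimer_rise / 2
    stagger: float | None = None  # default 3 * monomer_len / n_pf (3-start closure)
    radius: float = 105.0
    n_repeats: int = 6
    seam_index: int | None = None  # default n_pf - 1
    polarity: str = "plus_up"
    handedness_sign: int = -1
    n_starts: int = 3

    def __post_init__(self):
        if self.n_pf < 3:
            raise ValueError("n_pf must be >= 3")
        if self.dimer_rise <= 0:
            raise ValueError("dimer_rise must be positive")
        if self.monomer_len is None:
            self.monomer_len = self.dimer_rise / 2.0
        if self.seam_index is None:
            self.seam_index = self.n_pf - 1
        if not 0 <= self.seam_index < self.n_pf:
            raise ValueError("seam_index must lie in [0, n_pf)")
        if self.polarity not in ("plus_up", "plus_down"):
            raise ValueError("polarity must be plus_up or plus_down")
        if self.handedness_sign not in (1, -1):
            raise ValueError("handedness_sign must be +1 or -1")
        closure = self.n_starts * self.monomer_len / self.n_pf
        if self.stagger is None:
            self.stagger = closure
        elif abs(self.stagger * self.n_pf - self.n_starts * self.monomer_len) > 1e-6:
            warnings.warn(
                f"stagger {self.stagger:.4f} Å breaks {self.n_starts}-start seam "
                f"closure; adjusted to {closure:.4f} Å"
            )
            self.stagger = closure

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MIPDecoration:
    """One MIP class's binding mode and lattice footprint.

    ``pf_span`` is ``"all_non_seam"``, a list of interface indices, or a
    list of protofilament labels (e.g. ``["B02", "B03", "B04", "B05"]``,
    meaning the lateral interfaces among consecutive listed pfs). Lateral
    decorations never occupy the seam. ``tilt`` is measured between the rod
    axis and the least-squares plane of the two flanking tubulin dimers.
    """

    class_name: str = "tails"
    mode: str = "lateral_interface"  # or "longitudinal_filament"
    pf_span: object = "all_non_seam"
    periodicity: float | None = None  # Å; default = dimer rise
    tilt: float = 51.5  # degrees
    length: float = 45.0  # Å rod length
    inset: float = 15.0  # Å radial displacement toward the lumen
    n_atoms: int = 16
    placements: list = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in ("lateral_interface", "longitudinal_filament"):
            raise ValueError(f"unknown decoration mode {self.mode!r}")

    @property
    def res_code(self) -> str:
        return mip_res_code(self.class_name)


@dataclass
class GroundTruth:
    """Generator side-car: lattice parameters plus per-chain assignments."""

    lattice: LatticeParams
    decorations: list = field(default_factory=list)
    # chain_id -> {"role": alpha|beta|mip:<class>, "tubule": A|B|S,
    #              "pf_index": int, "axial_index": int}
    chain_labels: dict = field(default_factory=dict)
    n_pf_B: int | None = None

    def to_json(self, path: str) -> None:
        payload = {
            "lattice": self.lattice.to_dict(),
            "n_pf_B": self.n_pf_B,
            "decorations": [
                {
                    **{k: v for k, v in asdict(d).items() if k != "placements"},
                    "placements": [
                        {
                            "interface": int(p[0]),
                            "axial": int(p[1]),
                            "anchor": [float(v) for v in p[2]],
                            "axis": [float(v) for v in p[3]],
                        }
                        for p in d.placements
                    ],
                }
                for d in self.decorations
            ],
            "chain_labels": self.chain_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        decs = []
        for d in payload["decorations"]:
            pls = [
                (p["interface"], p["axial"], np.array(p["anchor"]), np.array(p["axis"]))
                for p in d.pop("placements")
            ]
            decs.append(MIPDecoration(**d, placements=pls))
        return cls(
            lattice=LatticeParams(**payload["lattice"]),
            decorations=decs,
            chain_labels=payload["chain_labels"],
            n_pf_B=payload.get("n_pf_B"),
        )


# ---------------------------------------------------------------------------
# dimer template


def _principal_frame(xyz: np.ndarray) -> np.ndarray:
    """Proper rotation whose rows map (2nd, 3rd, 1st) principal axes to x,y,z."""
    cov = np.cov(xyz.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    # rows: x <- middle axis, y <- smallest, z <- largest
    R = np.vstack([evecs[:, 1], evecs[:, 0], evecs[:, 2]])
    # fix signs: z axis toward +z of the input, keep det = +1
    if R[2] @ np.array([0.0, 0.0, 1.0]) < 0:
        R[2] = -R[2]
    if np.linalg.det(R) < 0:
        R[0] = -R[0]
    return R


def build_dimer_template(
    n_atoms_per_monomer: int = 80,
    seed: int = 0,
    monomer_len: float = 40.0,
) -> StructureModel:
    """Pseudo-atomic stand-in for an αβ-tubulin heterodimer.

    Two anisotropic ellipsoidal clouds of carbon pseudo-atoms, α centered at
    −monomer_len/2 and β at +monomer_len/2 along z (plus end up). The
    combined cloud is centered exactly at the origin with its longest
    principal axis exactly along z; α and β carry distinct residue names.
    """
    if n_atoms_per_monomer < 4:
        raise ValueError("n_atoms_per_monomer must be >= 4 (plane/axis fits undefined)")
    rng = np.random.default_rng(seed)
    sig = np.array([9.0, 6.5, monomer_len / 3.2])  # anisotropic in-plane too
    half = monomer_len / 2.0
    clouds = []
    for sign in (-1.0, +1.0):  # alpha below, beta above
        pts = rng.normal(scale=sig, size=(n_atoms_per_monomer, 3))
        pts -= pts.mean(axis=0)  # exact monomer centering
        pts[:, 2] += sign * half
        clouds.append(pts)
    xyz = np.vstack(clouds)
    xyz -= xyz.mean(axis=0)
    R = _principal_frame(xyz)
    xyz = xyz @ R.T
    xyz -= xyz.mean(axis=0)

    model = StructureModel(metadata={"generator": "dimer_template", "monomer_len": monomer_len, "seed": seed})
    serial = 0
    for mono, res in (("a", ALPHA_RES), ("b", BETA_RES)):
        atoms = []
        block = xyz[:n_atoms_per_monomer] if mono == "a" else xyz[n_atoms_per_monomer:]
        for p in block:
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, name="CA", element="C", res_name=res,
                    res_seq=serial, chain_id=mono,
                    x=float(p[0]), y=float(p[1]), z=float(p[2]),
                )
            )
        model.add_chain(mono, atoms)
    return model


def _template_blocks(template: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """(alpha_xyz, beta_xyz) from a dimer template, in template frame."""
    a = template.coords(["a"]) if "a" in template.chains else None
    b = template.coords(["b"]) if "b" in template.chains else None
    if a is None or b is None:
        raise ValueError("dimer template must contain chains 'a' (alpha) and 'b' (beta)")
    return a, b


def _rot_z(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# lattice builders


def _place_tubule(
    model: StructureModel,
    truth: GroundTruth,
    params: LatticeParams,
    template: StructureModel,
    tubule: str,
    center_xy: np.ndarray,
    phi0: float = 0.0,
    closed: bool = True,
    n_pf_arc: int | None = None,
    arc_step: float | None = None,
    serial0: int = 0,
) -> int:
    """Place one tubule's protofilaments; returns the next free serial."""
    a_xyz, b_xyz = _template_blocks(template)
    n_pf = params.n_pf if closed else int(n_pf_arc)
    step = params.handedness_sign * 2.0 * np.pi / params.n_pf if arc_step is None else arc_step
    serial = serial0
    for geom in range(n_pf):
        # pf labels rotate with the requested seam position (closed tube only)
        label = (geom + params.seam_index + 1) % params.n_pf if closed else geom
        phi = phi0 + step * geom
        R = _rot_z(phi)
        pf_origin = center_xy + params.radius * np.array([np.cos(phi), np.sin(phi)])
        for k in range(params.n_repeats):
            center = np.array([pf_origin[0], pf_origin[1], geom * params.stagger + k * params.dimer_rise])
            for mono, block, res in (("a", a_xyz, ALPHA_RES), ("b", b_xyz, BETA_RES)):
                cid = f"{tubule}{label + 1:02d}{mono}{k:02d}"
                xyz = block @ R.T + center
                atoms = []
                for p in xyz:
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=serial, name="CA", element="C", res_name=res,
                            res_seq=len(atoms) + 1, chain_id=cid,
                            x=float(p[0]), y=float(p[1]), z=float(p[2]),
                        )
                    )
                model.add_chain(cid, atoms)
                truth.chain_labels[cid] = {
                    "role": "alpha" if mono == "a" else "beta",
                    "tubule": tubule,
                    "pf_index": int(label),
                    "axial_index": int(k),
                }
    return serial


def build_singlet(
    params: LatticeParams | None = None,
    template: StructureModel | None = None,
) -> tuple[StructureModel, GroundTruth]:
    """Closed singlet microtubule with exactly one seam.

    Protofilament ``i`` sits at azimuth ``handedness_sign * 2*pi*i/n_pf`` and
    axial offset ``i * stagger``; the closure interface carries the residual
    3-monomer offset, making its nearest lateral contacts heterotypic (the
    seam) while all other interfaces are homotypic.
    """
    params = params or LatticeParams()
    template = template or build_dimer_template(monomer_len=params.monomer_len)
    model = StructureModel(metadata={"generator": "singlet", "lattice": params.to_dict()})
    truth = GroundTruth(lattice=params)
    _place_tubule(model, truth, params, template, "S", np.zeros(2), closed=True)
    return model, truth


def build_doublet(
    params_A: LatticeParams | None = None,
    n_pf_B: int = 10,
    template: StructureModel | None = None,
) -> tuple[StructureModel, GroundTruth]:
    """Doublet: a closed A tubule plus an open B-tubule arc (B01..Bnn).

    The B tubule is a geometric stand-in — an open arc of protofilaments on
    a second cylinder tangent to A with the same rise and stagger; junction
    architecture is intentionally not modeled.
    """
    if n_pf_B < 4:
        raise ValueError("n_pf_B must be >= 4")
    params_A = params_A or LatticeParams()
    template = template or build_dimer_template(monomer_len=params_A.monomer_len)
    model = StructureModel(
        metadata={"generator": "doublet", "lattice": params_A.to_dict(), "n_pf_B": n_pf_B}
    )
    truth = GroundTruth(lattice=params_A, n_pf_B=n_pf_B)
    serial = _place_tubule(model, truth, params_A, template, "A", np.zeros(2), closed=True)

    r_B = params_A.radius
    center_B = np.array([2.0 * r_B + 10.0, 0.0])
    model.metadata["b_center"] = [float(center_B[0]), float(center_B[1])]
    step = params_A.handedness_sign * 2.0 * np.pi / params_A.n_pf
    # arc centered on the azimuth facing the A tubule
    phi0 = np.pi - step * (n_pf_B - 1) / 2.0
    serial = _place_tubule(
        model, truth, params_A, template, "B", center_B,
        phi0=phi0, closed=False, n_pf_arc=n_pf_B, arc_step=step, serial0=serial,
    )
    # clash diagnostic between tubules (warning only)
    a_pts = model.coords([c for c in model.chains if c.startswith("A")])
    b_pts = model.coords([c for c in model.chains if c.startswith("B")])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(a_pts).query(b_pts, k=1)
    if float(d.min()) < 2.0:
        warnings.warn(f"A/B tubule clash: minimum interatomic distance {d.min():.2f} Å")
    return model, truth


# ---------------------------------------------------------------------------
# MIP decoration


def _ls_plane_normal(xyz: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane (smallest principal direction)."""
    c = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - c, full_matrices=False)
    return vt[-1]


def _dimer_chain_ids(truth: GroundTruth, tubule: str, pf: int, k: int) -> list[str]:
    return [
        cid
        for cid, lab in truth.chain_labels.items()
        if lab["tubule"] == tubule and lab["pf_index"] == pf and lab["axial_index"] == k
        and lab["role"] in ("alpha", "beta")
    ]


def _rod_atoms(anchor: np.ndarray, axis: np.ndarray, normal: np.ndarray,
               length: float, n_atoms: int) -> np.ndarray:
    """Rod of pseudo-atoms along ``axis`` with a small equivariant thickness."""
    t = np.linspace(-length / 2.0, length / 2.0, n_atoms)
    side = np.cross(normal, axis)
    side /= np.linalg.norm(side)
    # 1-Å lateral weave defined in the local frame so lattice symmetry is exact
    off = np.where(np.arange(n_atoms) % 2 == 0, 1.0, -1.0)
    return anchor + t[:, None] * axis + off[:, None] * side


def _resolve_lateral_interfaces(truth: GroundTruth, pf_span) -> tuple[str, list[int]]:
    """Map a pf_span request to (tubule, list of interface indices)."""
    lat = truth.lattice
    tubule = "A" if truth.n_pf_B is not None else "S"
    if isinstance(pf_span, str) and pf_span == "all_non_seam":
        return tubule, [j for j in range(lat.n_pf) if j != lat.seam_index]
    span = list(pf_span)
    if span and isinstance(span[0], str):
        # pf labels like "B02": consecutive pairs among the listed pfs
        tub = span[0][0]
        idx = sorted(int(s[1:]) - 1 for s in span)
        return tub, [idx[i] for i in range(len(idx) - 1) if idx[i + 1] == idx[i] + 1]
    return tubule, [int(j) for j in span]


def decorate_mips(
    model: StructureModel,
    truth: GroundTruth,
    decoration: MIPDecoration,
) -> tuple[StructureModel, GroundTruth]:
    """Add one MIP class to a generated lattice, recording ground truth.

    Lateral-interface mode places, at every decorated interface and axial
    repeat, a pseudo-atom rod anchored at the lumen-ward midpoint of the two
    flanking dimers' mass centers, tilted by ``decoration.tilt`` degrees out
    of the flanking dimers' least-squares plane. Longitudinal mode places
    rods along each listed protofilament. The seam interface is excluded
    automatically; asking for it explicitly is an error.
    """
    lat = truth.lattice
    period = decoration.periodicity if decoration.periodicity is not None else lat.dimer_rise
    if period <= 0 or abs(period / lat.monomer_len - round(period / lat.monomer_len)) > 1e-9:
        raise ValueError("periodicity must be a positive multiple of the monomer length")
    step_k = max(1, int(round(period / lat.dimer_rise)))
    model = model.copy()
    decoration = MIPDecoration(**{**{k: v for k, v in asdict(decoration).items() if k != "placements"}},
                               placements=[])
    res = decoration.res_code
    serial = max((a.serial for a in model.atoms()), default=0)
    copy_idx = 0

    if decoration.mode == "lateral_interface":
        tubule, interfaces = _resolve_lateral_interfaces(truth, decoration.pf_span)
        closed = tubule in ("A", "S")
        if closed and lat.seam_index in interfaces:
            raise ValueError(
                f"interface {lat.seam_index} is the seam; lateral-interface MIPs "
                "cannot bind the heterotypic seam contacts"
            )
        for j in interfaces:
            pf_a, pf_b = j, (j + 1) % lat.n_pf
            for k in range(0, lat.n_repeats, step_k):
                ca = model.coords(_dimer_chain_ids(truth, tubule, pf_a, k))
                cb = model.coords(_dimer_chain_ids(truth, tubule, pf_b, k))
                if ca.size == 0 or cb.size == 0:
                    continue
                mid = (ca.mean(axis=0) + cb.mean(axis=0)) / 2.0
                axis_pt = np.array([0.0, 0.0, mid[2]]) if tubule != "B" else None
                if tubule == "B":
                    # lumen-ward for the arc: toward its own cylinder axis
                    center_B = np.array(model.metadata.get("b_center", [2.0 * lat.radius + 10.0, 0.0]))
                    axis_pt = np.array([center_B[0], center_B[1], mid[2]])
                inward = axis_pt - mid
                inward[2] = 0.0
                inward /= np.linalg.norm(inward)
                anchor = mid + decoration.inset * inward
                both = np.vstack([ca, cb])
                nrm = _ls_plane_normal(both)
                if nrm @ inward < 0:
                    nrm = -nrm
                zhat = np.array([0.0, 0.0, 1.0])
                in_plane = zhat - (zhat @ nrm) * nrm
                in_plane /= np.linalg.norm(in_plane)
                tau = np.deg2rad(decoration.tilt)
                rod_axis = np.cos(tau) * in_plane + np.sin(tau) * nrm
                xyz = _rod_atoms(anchor, rod_axis, nrm, decoration.length, decoration.n_atoms)
                copy_idx += 1
                cid = f"{res}{copy_idx:04d}"
                atoms = []
                for p in xyz:
                    serial += 1
                    atoms.append(AtomRecord(serial=serial, name="CA", element="C",
                                            res_name=res, res_seq=len(atoms) + 1, chain_id=cid,
                                            x=float(p[0]), y=float(p[1]), z=float(p[2])))
                model.add_chain(cid, atoms)
                truth.chain_labels[cid] = {
                    "role": f"mip:{decoration.class_name}", "tubule": tubule,
                    "pf_index": int(j), "axial_index": int(k),
                }
                decoration.placements.append((j, k, anchor, rod_axis))
    else:  # longitudinal_filament
        tubule = "A" if truth.n_pf_B is not None else "S"
        span = decoration.pf_span
        if isinstance(span, str):
            raise ValueError("longitudinal decorations need an explicit pf list")
        pfs = [int(s[1:]) - 1 if isinstance(s, str) else int(s) for s in span]
        zhat = np.array([0.0, 0.0, 1.0])
        for pf in pfs:
            for k in range(0, lat.n_repeats, step_k):
                c = model.coords(_dimer_chain_ids(truth, tubule, pf, k)).mean(axis=0)
                inward = -np.array([c[0], c[1], 0.0])
                inward /= np.linalg.norm(inward)
                anchor = c + decoration.inset * inward
                xyz = _rod_atoms(anchor, zhat, inward, decoration.length, decoration.n_atoms)
                copy_idx += 1
                cid = f"{res}{copy_idx:04d}"
                atoms = []
                for p in xyz:
                    serial += 1
                    atoms.append(AtomRecord(serial=serial, name="CA", element="C",
                                            res_name=res, res_seq=len(atoms) + 1, chain_id=cid,
                                            x=float(p[0]), y=float(p[1]), z=float(p[2])))
                model.add_chain(cid, atoms)
                truth.chain_labels[cid] = {
                    "role": f"mip:{decoration.class_name}", "tubule": tubule,
                    "pf_index": int(pf), "axial_index": int(k),
                }
                decoration.placements.append((pf, k, anchor, zhat.copy()))

    truth.decorations.append(decoration)
    model.metadata.setdefault("decorations", []).append(decoration.class_name)
    return model, truth
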