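"""Symbolic annotation of a microtubule model: axis, protofilaments, seam.

Assigns every chain of a (real or synthetic) model a role (alpha, beta,
MIP, other), a tubule (A, B, or S for a singlet), a protofilament index and
an axial index, fits the helical axis, enumerates lateral interfaces and
finds the seam — the unique lateral interface whose nearest contacts are
heterotypic (alpha against beta).

Protofilament numbering follows chain labels when they encode it (the
generator's ``S05b03`` style, or ``A01``/``B01`` prefixes of curated
models); otherwise numbering starts just after the seam and increases in
the direction of rising lateral stagger. The numbering origin used is
recorded in the annotation so reports are reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from .model_io import StructureModel
from .synthetic import ALPHA_RES, BETA_RES

__all__ = [
    "ChainAssignment",
    "TubuleInfo",
    "LatticeAnnotation",
    "AnnotationError",
    "classify_chains",
    "fit_axis",
    "assign_protofilaments",
    "detect_seam",
    "annotate",
]

_CHAIN_LABEL_RE = re.compile(r"^([ABS])(\d{2})(?:([ab])(\d{2}))?$")

#: chains with at least this many residues are tubulin candidates
TUBULIN_MIN_RESIDUES = 300


class AnnotationError(ValueError):
    """Raised when the lattice cannot be annotated unambiguously."""


@dataclass
class ChainAssignment:
    role: str  # alpha | beta | tubulin | mip | other
    tubule: str | None = None  # A | B | S
    pf_index: int | None = None
    axial_index: int | None = None
    mip_class: str | None = None


@dataclass
class TubuleInfo:
    """Per-tubule lattice facts: axis, protofilament count, interfaces, seam."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    n_pf: int
    closed: bool
    interfaces: list = field(default_factory=list)  # list of (pf_i, pf_j)
    seam_interface: int | None = None


@dataclass
class LatticeAnnotation:
    chains: dict = field(default_factory=dict)  # chain_id -> ChainAssignment
    tubules: dict = field(default_factory=dict)  # tubule -> TubuleInfo
    numbering_origin: str = "chain-labels"

    @property
    def primary_tubule(self) -> str:
        for t in ("A", "S", "B"):
            if t in self.tubules:
                return t
        raise AnnotationError("no tubule annotated")

    @property
    def n_pf(self) -> int:
        return self.tubules[self.primary_tubule].n_pf

    @property
    def seam_interface(self) -> int | None:
        return self.tubules[self.primary_tubule].seam_interface

    @property
    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.tubules[self.primary_tubule]
        return t.axis_point, t.axis_dir

    def tubulin_chains(self, tubule: str | None = None) -> list[str]:
        return [
            cid
            for cid, a in self.chains.items()
            if a.role in ("alpha", "beta", "tubulin") and (tubule is None or a.tubule == tubule)
        ]

    def mip_chains(self, class_name: str | None = None) -> list[str]:
        return [
            cid
            for cid, a in self.chains.items()
            if a.role == "mip" and (class_name is None or a.mip_class == class_name)
        ]

    def mip_classes(self) -> list[str]:
        return sorted({a.mip_class for a in self.chains.values() if a.role == "mip"})

    def pf_chains(self, tubule: str, pf_index: int, roles=("alpha", "beta", "tubulin")) -> list[str]:
        out = [
            cid
            for cid, a in self.chains.items()
            if a.tubule == tubule and a.pf_index == pf_index and a.role in roles
        ]
        return sorted(out, key=lambda c: (self.chains[c].axial_index, self.chains[c].role))

    def dimers(self, tubule: str, pf_index: int) -> list[tuple[int, list[str]]]:
        """[(axial_index, [chain ids of the dimer])] sorted by axial index."""
        by_k: dict[int, list[str]] = {}
        for cid in self.pf_chains(tubule, pf_index):
            by_k.setdefault(self.chains[cid].axial_index, []).append(cid)
        return sorted(by_k.items())


# ---------------------------------------------------------------------------
# classification


def classify_chains(model: StructureModel, chain_map: dict | None = None) -> dict[str, ChainAssignment]:
    """Assign a role to every chain.

    Priority: explicit ``chain_map`` (chain_id -> {role, tubule, pf_index,
    mip_class}), then the generator's residue-name markers, then a uniform
    single residue name (pseudo-atom MIP chain), then a residue count
    threshold (>= 300 residues is a tubulin candidate, smaller chains are
    MIP candidates).
    """
    out: dict[str, ChainAssignment] = {}
    for cid in model.chains:
        if chain_map and cid in chain_map:
            e = chain_map[cid]
            out[cid] = ChainAssignment(
                role=e.get("role", "other"),
                tubule=e.get("tubule"),
                pf_index=e.get("pf_index"),
                mip_class=e.get("mip_class"),
            )
            continue
        res_names = model.chain_res_names(cid)
        if res_names == {ALPHA_RES}:
            out[cid] = ChainAssignment(role="alpha")
        elif res_names == {BETA_RES}:
            out[cid] = ChainAssignment(role="beta")
        elif len(res_names) == 1:
            # a single uniform residue name marks a pseudo-atom chain; real
            # protein chains carry many residue types
            out[cid] = ChainAssignment(role="mip", mip_class=next(iter(res_names)))
        elif model.n_residues(cid) >= TUBULIN_MIN_RESIDUES:
            out[cid] = ChainAssignment(role="tubulin")
        else:
            out[cid] = ChainAssignment(role="mip", mip_class="mip")
    return out


# ---------------------------------------------------------------------------
# axis


def _chain_centers(model: StructureModel, cids: list[str]) -> np.ndarray:
    return np.array([model.coords([c]).mean(axis=0) for c in cids])


def _axis_from_centers(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis (point, unit direction) of a tube of chain centers.

    Starts from the principal direction, then refines it with the mean of
    nearest-neighbor steps: each monomer's nearest neighbor is its
    longitudinal neighbor on the same protofilament, so the sign-aligned
    mean of those steps points along the tube even when the lateral stagger
    correlates azimuth with height and skews the raw principal axis.
    """
    centroid = centers.mean(axis=0)
    _, s, vt = np.linalg.svd(centers - centroid, full_matrices=False)
    if s[1] < 1e-6:
        raise AnnotationError("degenerate (collinear) chain centers: axis undefined")
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    if len(centers) >= 6:
        from scipy.spatial import cKDTree

        _, idx = cKDTree(centers).query(centers, k=2)
        vecs = centers[idx[:, 1]] - centers
        signs = np.sign(vecs @ axis)
        vecs = vecs[signs != 0] * signs[signs != 0, None]
        m = vecs.mean(axis=0)
        if np.linalg.norm(m) > 1e-9:
            axis = m / np.linalg.norm(m)
    return centroid, axis


def fit_axis(model: StructureModel, roles: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Helical axis as (point, unit direction) fitted to the tubulin-chain
    mass centers, oriented toward +z."""
    roles = roles or classify_chains(model)
    cids = [c for c, a in roles.items() if a.role in ("alpha", "beta", "tubulin")]
    if len(cids) < 3:
        raise AnnotationError("axis fit needs at least 3 tubulin chains")
    return _axis_from_centers(_chain_centers(model, cids))


# ---------------------------------------------------------------------------
# protofilament assignment


def _circular_clusters(angles: np.ndarray, n_hint: int | None) -> np.ndarray:
    """Cluster angles on the circle by gap splitting; returns labels 0..k-1
    in increasing-angle order."""
    order = np.argsort(angles)
    srt = angles[order]
    gaps = np.diff(np.concatenate([srt, [srt[0] + 2 * np.pi]]))
    if n_hint is not None:
        k = n_hint
        boundary_idx = np.sort(np.argsort(gaps)[-k:])
    else:
        thr = gaps.max() * 0.5
        boundary_idx = np.flatnonzero(gaps > thr)
        k = len(boundary_idx)
    labels = np.empty(len(angles), dtype=int)
    lab = 0
    boundaries = set(boundary_idx.tolist())
    for i, oi in enumerate(order):
        labels[oi] = lab
        if i in boundaries:
            lab += 1
    labels[labels == k] = 0  # wraparound joins the first cluster
    return labels


def _perp_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _azimuths(centers: np.ndarray, point: np.ndarray, axis: np.ndarray) -> np.ndarray:
    e1, e2 = _perp_frame(axis)
    rel = centers - point
    return np.arctan2(rel @ e2, rel @ e1)


def _labels_encode_pf(cids: list[str]) -> bool:
    return all(_CHAIN_LABEL_RE.match(c) for c in cids)


def assign_protofilaments(
    model: StructureModel,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    n_pf_hint: int | None = None,
    chain_map: dict | None = None,
) -> LatticeAnnotation:
    """Cluster tubulin chains into protofilaments and index them axially.

    Chains are split into tubules by label prefix when present (A../B..),
    geometrically otherwise; each tubule gets its own axis. Protofilaments
    are azimuthal clusters (count from ``n_pf_hint`` or the circular gap
    statistic); axial indices sort each protofilament along the axis and
    pair each alpha with the nearest plus-ward beta.
    """
    roles = classify_chains(model, chain_map)
    ann = LatticeAnnotation(chains=roles)
    tub_cids = [c for c, a in roles.items() if a.role in ("alpha", "beta", "tubulin")]
    if not tub_cids:
        raise AnnotationError("no tubulin chains found")

    labeled = _labels_encode_pf(tub_cids)
    groups: dict[str, list[str]] = {}
    if labeled:
        for cid in tub_cids:
            groups.setdefault(_CHAIN_LABEL_RE.match(cid).group(1), []).append(cid)
    else:
        for cid in tub_cids:
            t = roles[cid].tubule or "S"
            groups.setdefault(t, []).append(cid)

    for tubule, cids in groups.items():
        centers = _chain_centers(model, cids)
        try:
            centroid, axis_dir = _axis_from_centers(centers)
        except AnnotationError as exc:
            raise AnnotationError(f"tubule {tubule}: {exc}") from exc

        phis = _azimuths(centers, centroid, axis_dir)
        zs = (centers - centroid) @ axis_dir
        closed = tubule in ("A", "S")

        if labeled:
            pf_of = {cid: int(_CHAIN_LABEL_RE.match(cid).group(2)) - 1 for cid in cids}
            clusters = np.array([pf_of[c] for c in cids])
            n_pf = int(clusters.max()) + 1
            ann.numbering_origin = "chain-labels"
        else:
            clusters = _circular_clusters(phis, n_pf_hint)
            n_pf = int(clusters.max()) + 1
            ann.numbering_origin = "seam-anchored (pf 0 follows the seam in the rising-stagger direction)"

        counts = np.bincount(clusters, minlength=n_pf)
        if counts.max() - counts.min() > 2:
            raise AnnotationError(
                f"tubule {tubule}: protofilament populations differ by more than one "
                f"dimer: {counts.tolist()}"
            )

        for cid, pf in zip(cids, clusters):
            ann.chains[cid].tubule = tubule
            ann.chains[cid].pf_index = int(pf)

        # axial indexing: sort alphas along the axis; betas join the nearest
        # plus-ward alpha to form dimers
        for pf in range(n_pf):
            pf_cids = [c for c, lab in zip(cids, clusters) if lab == pf]
            pf_z = {c: float((model.coords([c]).mean(axis=0) - centroid) @ axis_dir) for c in pf_cids}
            alphas = sorted((c for c in pf_cids if ann.chains[c].role == "alpha"), key=pf_z.get)
            betas = sorted((c for c in pf_cids if ann.chains[c].role == "beta"), key=pf_z.get)
            if alphas and len(alphas) == len(betas):
                for k, (a, b) in enumerate(zip(alphas, betas)):
                    ann.chains[a].axial_index = k
                    ann.chains[b].axial_index = k
            else:  # unknown monomer classes: rank all chains pairwise
                for k, c in enumerate(sorted(pf_cids, key=pf_z.get)):
                    ann.chains[c].axial_index = k // 2 if not alphas else k

        info = TubuleInfo(axis_point=centroid, axis_dir=axis_dir, n_pf=n_pf, closed=closed)
        if closed:
            info.interfaces = [(j, (j + 1) % n_pf) for j in range(n_pf)]
        else:
            info.interfaces = [(j, j + 1) for j in range(n_pf - 1)]
        ann.tubules[tubule] = info

    # MIP chains inherit the tubule of the nearest tubulin chain
    for cid, a in ann.chains.items():
        if a.role == "mip" and a.tubule is None:
            c = model.coords([cid]).mean(axis=0)
            best, bd = None, np.inf
            for tid in tub_cids:
                d = float(np.linalg.norm(model.coords([tid]).mean(axis=0) - c))
                if d < bd:
                    bd, best = d, tid
            a.tubule = ann.chains[best].tubule
    return ann


# ---------------------------------------------------------------------------
# seam detection


def _interface_heterotypic_fraction(
    model: StructureModel, ann: LatticeAnnotation, tubule: str, pf_a: int, pf_b: int,
    max_axial_offset: float | None = None,
) -> float:
    info = ann.tubules[tubule]
    cids_a = ann.pf_chains(tubule, pf_a, roles=("alpha", "beta"))
    cids_b = ann.pf_chains(tubule, pf_b, roles=("alpha", "beta"))
    if not cids_a or not cids_b:
        raise AnnotationError(f"interface ({pf_a},{pf_b}): missing monomer classes")
    ca = _chain_centers(model, cids_a)
    cb = _chain_centers(model, cids_b)
    za = (ca - info.axis_point) @ info.axis_dir
    zb = (cb - info.axis_point) @ info.axis_dir
    het = []
    for i, cid in enumerate(cids_a):
        j = int(np.argmin(np.linalg.norm(cb - ca[i], axis=1)))
        if max_axial_offset is not None and abs(zb[j] - za[i]) > max_axial_offset:
            continue  # pf-end monomer with no true lateral partner
        het.append(ann.chains[cid].role != ann.chains[cids_b[j]].role)
    if not het:
        raise AnnotationError(f"interface ({pf_a},{pf_b}): no lateral contacts within range")
    return float(np.mean(het))


def detect_seam(ann: LatticeAnnotation, model: StructureModel, tubule: str | None = None) -> int | None:
    """Find the seam: the unique lateral interface whose nearest monomer
    contacts are predominantly heterotypic. Returns None for an open arc."""
    tubule = tubule or ann.primary_tubule
    info = ann.tubules[tubule]
    if not info.closed:
        info.seam_interface = None
        return None
    # gate out pf-end monomers lacking a lateral partner
    zs = [(model.coords([c]).mean(axis=0) - info.axis_point) @ info.axis_dir
          for c in ann.pf_chains(tubule, 0, roles=("alpha", "beta"))]
    gate = 0.75 * float(np.median(np.diff(sorted(zs)))) if len(zs) > 2 else None
    fractions = {}
    for idx, (pf_a, pf_b) in enumerate(info.interfaces):
        fractions[idx] = _interface_heterotypic_fraction(model, ann, tubule, pf_a, pf_b, gate)
    seams = [idx for idx, f in fractions.items() if f > 0.5]
    if len(seams) != 1:
        detail = ", ".join(f"{i}:{f:.2f}" for i, f in sorted(fractions.items()))
        raise AnnotationError(
            f"expected exactly one heterotypic interface, found {len(seams)} "
            f"(heterotypic fractions per interface: {detail})"
        )
    info.seam_interface = seams[0]
    return seams[0]


def _renumber_from_seam(ann: LatticeAnnotation, model: StructureModel, tubule: str) -> None:
    """Rotate pf numbering of an unlabeled closed tubule so pf 0 follows the
    seam in the rising-stagger direction (seam interface becomes n_pf - 1)."""
    info = ann.tubules[tubule]
    s = info.seam_interface
    n = info.n_pf
    if s is None:
        return
    # rising-stagger direction probed on a non-seam interface
    pf_a, pf_b = (s + 1) % n, (s + 2) % n
    ca = _chain_centers(model, ann.pf_chains(tubule, pf_a, roles=("alpha", "beta")))
    cb = _chain_centers(model, ann.pf_chains(tubule, pf_b, roles=("alpha", "beta")))
    za = (ca - info.axis_point) @ info.axis_dir
    zb = (cb - info.axis_point) @ info.axis_dir
    deltas = [zb[int(np.argmin(np.linalg.norm(cb - ca[i], axis=1)))] - za[i] for i in range(len(ca))]
    rising_forward = float(np.median(deltas)) > 0
    if rising_forward:
        remap = {old: (old - (s + 1)) % n for old in range(n)}
    else:
        remap = {old: (s - old) % n for old in range(n)}
    for a in ann.chains.values():
        if a.tubule == tubule and a.pf_index is not None and a.role in ("alpha", "beta", "tubulin"):
            a.pf_index = remap[a.pf_index]
    info.seam_interface = n - 1


def annotate(
    model: StructureModel,
    n_pf_hint: int | None = None,
    chain_map: dict | None = None,
) -> LatticeAnnotation:
    """One-call pipeline: classify, fit axes, assign protofilaments, and
    detect the seam of every closed tubule."""
    ann = assign_protofilaments(model, n_pf_hint=n_pf_hint, chain_map=chain_map)
    for tubule, info in ann.tubules.items():
        if info.closed:
            roles = {ann.chains[c].role for c in ann.tubulin_chains(tubule)}
            if roles <= {"alpha", "beta"}:
                detect_seam(ann, model, tubule)
                if ann.numbering_origin.startswith("seam-anchored"):
                    _renumber_from_seam(ann, model, tubule)
    return ann


def load_chain_map(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
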