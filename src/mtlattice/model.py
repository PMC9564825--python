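"""Fit a helical-lattice description to a microtubule model.

:class:`MicrotubuleLatticeModel` wraps a structure plus annotation options;
:meth:`~MicrotubuleLatticeModel.fit` produces a
:class:`LatticeResults` carrying every geometric descriptor — per-pf dimer
spacings, interprotofilament angles, the seam, and per-MIP-class copy
counts, periodicity, handedness, tilt angles, interface areas and pairwise
RMSD — with ``summary()``, JSON and TSV export.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .annotate import LatticeAnnotation, annotate
from .model_io import StructureModel, read_structure
from . import geometry as geo

__all__ = ["MicrotubuleLatticeModel", "LatticeResults"]


@dataclass
class LatticeResults:
    """Fitted lattice descriptors. Angles deg, distances Å, periodicity nm."""

    annotation: LatticeAnnotation
    n_pf: int
    seam_interface: int | None
    spacings: dict = field(default_factory=dict)  # (tubule, pf) -> list of d (Å)
    ipf_angles: dict = field(default_factory=dict)  # (tubule, interface) -> deg
    mip: dict = field(default_factory=dict)  # class -> descriptor dict
    meta: dict = field(default_factory=dict)

    # -- aggregate accessors -------------------------------------------
    def mean_spacing(self, tubule: str | None = None) -> float:
        vals = [d for (t, _), ds in self.spacings.items() for d in ds
                if tubule is None or t == tubule]
        return float(np.mean(vals))

    def mean_ipf_angle(self, tubule: str | None = None, exclude_seam: bool = True) -> float:
        vals = [a for (t, i), a in self.ipf_angles.items()
                if (tubule is None or t == tubule)
                and not (exclude_seam and t == self.annotation.primary_tubule
                         and i == self.seam_interface)]
        return float(np.mean(vals))

    def summary(self) -> str:
        lines = []
        ann = self.annotation
        lines.append("Microtubule lattice fit")
        lines.append("=" * 54)
        lines.append(f"chains: {len(ann.chains)}   tubules: {', '.join(sorted(ann.tubules))}")
        for t, info in sorted(ann.tubules.items()):
            seam = info.seam_interface if info.closed else "n/a (open arc)"
            lines.append(f"tubule {t}: n_pf={info.n_pf} closed={info.closed} seam_interface={seam}")
        lines.append(f"pf numbering: {ann.numbering_origin}")
        if self.spacings:
            lines.append(f"mean dimer spacing: {self.mean_spacing():.3f} Å "
                         f"({self.mean_spacing() / 10:.3f} nm rise)")
        if self.ipf_angles:
            lines.append(f"mean interprotofilament angle (non-seam): "
                         f"{self.mean_ipf_angle():.3f} deg")
        for cls, d in sorted(self.mip.items()):
            lines.append("-" * 54)
            lines.append(f"MIP class {cls}: {d['n_copies']} copies")
            lines.append(f"  copies per repeat: {d['copies_per_repeat']}")
            if d.get("periodicity_nm") is not None:
                lines.append(f"  axial periodicity: {d['periodicity_nm']:.2f} nm")
            if d.get("handedness"):
                lines.append(f"  spiral handedness: {d['handedness']}")
            if d.get("tilt_deg"):
                tv = np.asarray(d["tilt_deg"])
                lines.append(f"  tilt angle: {tv.mean():.1f} deg "
                             f"(range {tv.min():.1f}-{tv.max():.1f})")
            if d.get("interface_area_A2"):
                av = np.asarray(d["interface_area_A2"])
                lines.append(f"  tubulin interface area: {av.mean():.0f} Å² per copy")
            if d.get("rmsd_matrix") is not None:
                M = np.asarray(d["rmsd_matrix"])
                off = M[~np.eye(len(M), dtype=bool)]
                lines.append(f"  pairwise RMSD after α-tubulin superposition: "
                             f"{off.min():.2f}-{off.max():.2f} Å")
        return "\n".join(lines)

    # -- export --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "n_pf": self.n_pf,
            "seam_interface": self.seam_interface,
            "numbering_origin": self.annotation.numbering_origin,
            "tubules": {
                t: {"n_pf": i.n_pf, "closed": i.closed, "seam_interface": i.seam_interface}
                for t, i in self.annotation.tubules.items()
            },
            "spacings": {f"{t}:{pf}": [float(v) for v in ds]
                         for (t, pf), ds in self.spacings.items()},
            "ipf_angles": {f"{t}:{i}": float(a) for (t, i), a in self.ipf_angles.items()},
            "mip": {
                cls: {k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, list)) else v)
                      for k, v in d.items()}
                for cls, d in self.mip.items()
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_tsv(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "spacings.tsv"), "w") as fh:
            fh.write("tubule\tpf\tstep\tspacing_A\n")
            for (t, pf), ds in sorted(self.spacings.items()):
                for k, d in enumerate(ds):
                    fh.write(f"{t}\t{pf}\t{k}\t{d:.4f}\n")
        with open(os.path.join(out_dir, "ipf_angles.tsv"), "w") as fh:
            fh.write("tubule\tinterface\tangle_deg\tis_seam\n")
            for (t, i), a in sorted(self.ipf_angles.items()):
                seam = self.annotation.tubules[t].seam_interface == i
                fh.write(f"{t}\t{i}\t{a:.4f}\t{int(bool(seam))}\n")
        with open(os.path.join(out_dir, "mip.tsv"), "w") as fh:
            fh.write("class\tcopy\ttilt_deg\tinterface_area_A2\n")
            for cls, d in sorted(self.mip.items()):
                tilts = d.get("tilt_deg") or []
                areas = d.get("interface_area_A2") or []
                for k, cid in enumerate(d.get("copies", [])):
                    tv = f"{tilts[k]:.3f}" if k < len(tilts) else "NA"
                    av = f"{areas[k]:.2f}" if k < len(areas) else "NA"
                    fh.write(f"{cls}\t{cid}\t{tv}\t{av}\n")


class MicrotubuleLatticeModel:
    """Helical-lattice model of a microtubule structure.

    Parameters
    ----------
    structure : StructureModel
        Atomic model (real or synthetic).
    n_pf_hint : int, optional
        Expected protofilament count; estimated from azimuthal gaps if None.
    chain_map : dict, optional
        chain_id -> {role, tubule, pf_index, mip_class} overrides.
    compute_interface_areas, compute_rmsd : bool
        Toggle the SASA-based and superposition-based MIP descriptors.
    sasa_points : int
        Shrake–Rupley quadrature points for interface areas.
    """

    def __init__(
        self,
        structure: StructureModel,
        n_pf_hint: int | None = None,
        chain_map: dict | None = None,
        compute_interface_areas: bool = True,
        compute_rmsd: bool = True,
        contact_area_cutoff: float = 50.0,
        sasa_points: int = 240,
        max_rmsd_copies: int = 24,
    ):
        self.structure = structure
        self.n_pf_hint = n_pf_hint
        self.chain_map = chain_map
        self.compute_interface_areas = compute_interface_areas
        self.compute_rmsd = compute_rmsd
        self.contact_area_cutoff = contact_area_cutoff
        self.sasa_points = sasa_points
        self.max_rmsd_copies = max_rmsd_copies

    @classmethod
    def from_file(cls, path: str, format: str = "auto", **kw) -> "MicrotubuleLatticeModel":
        return cls(read_structure(path, format=format), **kw)

    # -- helpers -------------------------------------------------------
    def _flanking_dimers(self, ann: LatticeAnnotation, cid: str):
        """The two nearest tubulin dimers (distinct pfs preferred) of a MIP copy."""
        model = self.structure
        tub = ann.chains[cid].tubule
        mc = model.coords([cid]).mean(axis=0)
        entries = []
        for pf in range(ann.tubules[tub].n_pf):
            for k, cids in ann.dimers(tub, pf):
                c = geo.chain_mass_center(model, cids)
                entries.append((float(np.linalg.norm(c - mc)), pf, k, cids))
        entries.sort(key=lambda e: (e[0], e[1], e[2]))
        first = entries[0]
        second = next((e for e in entries[1:] if e[1] != first[1]), entries[1])
        return first[3], second[3]

    def _mip_interface_area(self, ann: LatticeAnnotation, cid: str) -> float:
        """ΔSASA/2 between a MIP copy and its contacting tubulin chains
        (those individually burying >= contact_area_cutoff Å²)."""
        model = self.structure
        from scipy.spatial import cKDTree

        mip_xyz, mip_el = model.coords([cid]), model.elements([cid])
        tree = cKDTree(mip_xyz)
        cands = []
        for tc in ann.tubulin_chains():
            xyz = model.coords([tc])
            if tree.query(xyz.mean(axis=0).reshape(1, 3))[0][0] < 80.0:
                d, _ = tree.query(xyz, k=1)
                if d.min() < 8.0:
                    cands.append(tc)
        contacting = []
        for tc in cands:
            a = geo.interface_area(mip_xyz, mip_el, model.coords([tc]), model.elements([tc]),
                                   n_points=self.sasa_points)
            if a >= self.contact_area_cutoff:
                contacting.append(tc)
        if not contacting:
            return 0.0
        return geo.interface_area(mip_xyz, mip_el, model.coords(contacting),
                                  model.elements(contacting), n_points=self.sasa_points)

    # -- fit -----------------------------------------------------------
    def fit(self) -> LatticeResults:
        model = self.structure
        ann = annotate(model, n_pf_hint=self.n_pf_hint, chain_map=self.chain_map)
        res = LatticeResults(
            annotation=ann,
            n_pf=ann.n_pf,
            seam_interface=ann.seam_interface,
            meta={"package_version": __version__, "n_atoms": model.n_atoms},
        )
        for t, info in sorted(ann.tubules.items()):
            for pf in range(info.n_pf):
                try:
                    res.spacings[(t, pf)] = list(map(float, geo.dimer_spacings(ann, model, pf, t)))
                except ValueError:
                    pass
            for i in range(len(info.interfaces)):
                try:
                    res.ipf_angles[(t, i)] = geo.interprotofilament_angle(ann, model, i, t)
                except ValueError:
                    pass
        for cls in ann.mip_classes():
            copies = ann.mip_chains(cls)
            d: dict = {"n_copies": len(copies), "copies": copies}
            d["copies_per_repeat"] = geo.copies_per_repeat(ann, model, cls)
            try:
                d["periodicity_nm"] = geo.axial_periodicity(ann, model, cls)
            except ValueError:
                d["periodicity_nm"] = None
            try:
                d["handedness"] = geo.spiral_handedness(ann, model, cls)
            except ValueError:
                d["handedness"] = None
            tilts = []
            for cid in copies:
                try:
                    da, db = self._flanking_dimers(ann, cid)
                    tilts.append(geo.tilt_angle(model.coords([cid]), model.coords(da),
                                                model.coords(db)))
                except (ValueError, IndexError):
                    tilts.append(float("nan"))
            d["tilt_deg"] = tilts
            if self.compute_interface_areas:
                d["interface_area_A2"] = [self._mip_interface_area(ann, cid) for cid in copies]
            if self.compute_rmsd and 2 <= len(copies) <= self.max_rmsd_copies:
                try:
                    _, M = geo.mip_pairwise_rmsd(ann, model, cls)
                    d["rmsd_matrix"] = M
                except ValueError:
                    d["rmsd_matrix"] = None
            else:
                d["rmsd_matrix"] = None
            res.mip[cls] = d
        return res
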