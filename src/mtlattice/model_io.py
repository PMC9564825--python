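"""Atomic-structure input/output and the in-memory structure container.

The container is deliberately minimal: an ordered mapping of chain id to a
list of atom records, with author (auth) chain ids and residue numbers used
throughout. Reading and writing of PDB and mmCIF goes through gemmi; the
round trip preserves coordinates to 0.001 Å, chain order, and residue
numbering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "StructureParseError",
    "StructureFormatError",
    "read_structure",
    "write_structure",
]


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class StructureFormatError(ValueError):
    """Raised for an unknown format or a model not representable in a format."""


@dataclass
class AtomRecord:
    """One atom: identity, position (Å), occupancy and B-factor (Å²)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_factor: float = 0.0

    def validate(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")


@dataclass
class StructureModel:
    """Hierarchical atom container: ordered chains of ordered atom records.

    ``metadata`` carries free-form provenance (title, generator parameters
    for synthetic models). Chain ids are unique; dict insertion order is the
    chain order.
    """

    chains: dict[str, list[AtomRecord]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def add_chain(self, chain_id: str, atoms: list[AtomRecord]) -> None:
        if chain_id in self.chains:
            raise ValueError(f"duplicate chain id {chain_id!r}")
        self.chains[chain_id] = list(atoms)

    # -- queries -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return sum(len(a) for a in self.chains.values())

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def atoms(self, chain_ids=None):
        """Iterate atom records, optionally restricted to given chains."""
        ids = self.chain_ids() if chain_ids is None else chain_ids
        for cid in ids:
            yield from self.chains[cid]

    def coords(self, chain_ids=None, exclude_hydrogens: bool = True) -> np.ndarray:
        """(n, 3) array of coordinates in Å."""
        pts = [
            (a.x, a.y, a.z)
            for a in self.atoms(chain_ids)
            if not (exclude_hydrogens and a.element.upper() in ("H", "D"))
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def elements(self, chain_ids=None, exclude_hydrogens: bool = True) -> list[str]:
        return [
            a.element
            for a in self.atoms(chain_ids)
            if not (exclude_hydrogens and a.element.upper() in ("H", "D"))
        ]

    def chain_res_names(self, chain_id: str) -> set[str]:
        return {a.res_name for a in self.chains[chain_id]}

    def n_residues(self, chain_id: str) -> int:
        return len({a.res_seq for a in self.chains[chain_id]})

    def validate(self) -> None:
        seen = set()
        for cid, atoms in self.chains.items():
            for a in atoms:
                a.validate()
                if a.serial in seen:
                    raise ValueError(f"duplicate atom serial {a.serial}")
                seen.add(a.serial)

    def copy(self) -> "StructureModel":
        return StructureModel(
            chains={cid: [AtomRecord(**vars(a)) for a in atoms] for cid, atoms in self.chains.items()},
            metadata=dict(self.metadata),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy: x -> R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for atoms in out.chains.values():
            xyz = np.array([[a.x, a.y, a.z] for a in atoms])
            xyz = xyz @ R.T + t
            for a, p in zip(atoms, xyz):
                a.x, a.y, a.z = map(float, p)
        return out


# ---------------------------------------------------------------------------
# gemmi-backed file I/O


def _detect_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("pdb", "mmcif"):
            raise StructureFormatError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    raise StructureFormatError(f"cannot infer format from extension of {path!r}; pass format=")


def read_structure(path: str, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM and HETATM records are retained, chain order is preserved, and
    auth chain ids / residue numbers are used.
    """
    fmt = _detect_format(path, format)
    if not os.path.exists(path):
        raise StructureParseError(f"no such file: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    model = StructureModel(metadata={"source_path": path, "format": fmt, "title": st.name})
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found (empty or non-coordinate file)")
    serial = 0
    gm = st[0]
    for chain in gm:
        atoms: list[AtomRecord] = []
        for res in chain:
            for at in res:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain_id=chain.name,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                    )
                )
        if chain.name in model.chains:
            model.chains[chain.name].extend(atoms)
        else:
            model.chains[chain.name] = atoms
    if model.n_atoms == 0:
        raise StructureParseError(f"{path}: parsed but contains no atoms")
    return model


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(model.metadata.get("title", "mtlattice model"))
    gm = gemmi.Model("1")
    for cid, atoms in model.chains.items():
        chain = gemmi.Chain(cid)
        cur_res = None
        cur_key = None
        for a in atoms:
            key = (a.res_name, a.res_seq)
            if key != cur_key:
                cur_res = gemmi.Residue()
                cur_res.name = a.res_name
                cur_res.seqid = gemmi.SeqId(a.res_seq, " ")
                cur_res.het_flag = "A"
                # gemmi copies on add; keep the reference to the stored residue
                cur_res = chain.add_residue(cur_res)
                cur_key = key
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(a.x, a.y, a.z)
            at.occ = a.occupancy
            at.b_iso = a.b_factor
            at.serial = a.serial
            cur_res.add_atom(at)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str, format: str = "auto") -> None:
    """Write a :class:`StructureModel` to PDB or mmCIF.

    The written file is re-readable by :func:`read_structure` with chain
    order and coordinates (to 0.001 Å) preserved. PDB fixed columns limit
    chain ids to ~2 characters and coordinates to |x| < 10000 Å; violations
    raise :class:`StructureFormatError` advising mmCIF.
    """
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        for cid in model.chains:
            if len(cid) > 2:
                raise StructureFormatError(
                    f"chain id {cid!r} does not fit PDB fixed columns; write mmCIF instead"
                )
        for a in model.atoms():
            if not (-999.999 <= a.x <= 9999.999 and -999.999 <= a.y <= 9999.999 and -999.999 <= a.z <= 9999.999):
                raise StructureFormatError(
                    f"coordinate of atom {a.serial} overflows PDB columns; write mmCIF instead"
                )
    st = _to_gemmi(model)
    if fmt == "pdb":
        try:
            st.write_pdb(path)
        except RuntimeError as exc:
            raise StructureFormatError(f"{exc}; write mmCIF instead") from exc
    else:
        doc = st.make_mmcif_document()
        doc.write_file(path)
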