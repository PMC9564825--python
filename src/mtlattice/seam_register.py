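"""Seam-register realignment of microtubule particle orientations.

Microtubule particles refined under pseudo-helical symmetry come out of 3D
classification in arbitrary lattice registers: rotated by multiples of
360/n_pf about the helical axis and shifted by multiples of one tubulin
monomer (half the dimer rise, 40 Å by default) along it. This module
re-expresses per-class register corrections as orientation updates so that
every particle shares a common seam register.

Orientations use the ZYZ Euler convention of cryo-EM particle tables:
``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` — intrinsic rotations by ``rot`` about
z, ``tilt`` about the new y, ``psi`` about the final z. A correction
``(delta_phi, delta_shift)`` post-composes the particle matrix with a
rotation by ``delta_phi`` about the reference helical axis (z by default)
and moves the particle origin by ``delta_shift`` along the particle's
helical axis as seen in the image frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrientationTable",
    "RegisterCorrection",
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_about_axis",
    "apply_register_correction",
    "read_orientation_table",
    "write_orientation_table",
    "load_corrections",
]

ANGLE_COLS = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
ORIGIN_COLS = ("rlnOriginXAngst", "rlnOriginYAngst", "rlnOriginZAngst")
CLASS_COL = "rlnClassNumber"


# ---------------------------------------------------------------------------
# Euler algebra


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ Euler triplet (degrees) to a 3x3 rotation matrix."""
    a, b, g = np.deg2rad([rot, tilt, psi])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    Ry = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return Rz1 @ Ry @ Rz2


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; angles in (-180, 180].

    Near the gimbal case (tilt ≈ 0 or 180) all in-plane rotation is put into
    psi and rot is set to 0.
    """
    R = np.asarray(R, float)
    cb = np.clip(R[2, 2], -1.0, 1.0)
    tilt = np.degrees(np.arccos(cb))
    if abs(cb) > 1.0 - 1e-12:
        rot = 0.0
        if cb > 0:
            psi = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        else:
            psi = np.degrees(np.arctan2(R[1, 0], -R[0, 0]))
            tilt = 180.0
    else:
        rot = np.degrees(np.arctan2(R[1, 2], R[0, 2]))
        psi = np.degrees(np.arctan2(R[2, 1], -R[2, 0]))

    def wrap(x):
        x = (x + 180.0) % 360.0 - 180.0
        return 180.0 if x == -180.0 else x

    return wrap(rot), wrap(tilt), wrap(psi)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation by ``angle_deg`` about a (unit) axis."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


# ---------------------------------------------------------------------------
# orientation tables (STAR format)


@dataclass
class OrientationTable:
    """Particle orientations: a DataFrame with ZYZ Euler angles (deg),
    origin shifts (Å) and class ids; unhandled columns ride along verbatim."""

    df: pd.DataFrame
    block_name: str = "particles"

    def __post_init__(self):
        missing = [c for c in (*ANGLE_COLS, *ORIGIN_COLS, CLASS_COL) if c not in self.df.columns]
        if missing:
            raise ValueError(f"orientation table missing required columns: {missing}")

    def matrices(self) -> np.ndarray:
        ang = self.df[list(ANGLE_COLS)].astype(float).to_numpy()
        return np.array([euler_to_matrix(*row) for row in ang])

    def origins(self) -> np.ndarray:
        return self.df[list(ORIGIN_COLS)].astype(float).to_numpy()

    def classes(self) -> np.ndarray:
        return self.df[CLASS_COL].astype(int).to_numpy()

    def copy(self) -> "OrientationTable":
        return OrientationTable(self.df.copy(), self.block_name)


def read_orientation_table(path: str) -> OrientationTable:
    """Read a STAR particle table (first data block containing a loop).

    Values are kept as strings so that unhandled columns round-trip
    byte-identically; handled columns are converted on access.
    """
    block_name = "particles"
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                if cols:
                    break  # only the first loop block
                block_name = line[5:] or "particles"
                continue
            if line == "loop_":
                in_loop = True
                continue
            if in_loop and line.startswith("_"):
                cols.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and cols:
                fields = line.split()
                if len(fields) != len(cols):
                    raise ValueError(
                        f"{path}: row has {len(fields)} fields, header names {len(cols)} columns"
                    )
                rows.append(fields)
    if not cols or not rows:
        raise ValueError(f"{path}: no loop_ data block found")
    df = pd.DataFrame(rows, columns=cols)
    return OrientationTable(df, block_name)


def write_orientation_table(table: OrientationTable, path: str) -> None:
    df = table.df
    with open(path, "w") as fh:
        fh.write(f"data_{table.block_name}\n\nloop_\n")
        for i, c in enumerate(df.columns, 1):
            fh.write(f"_{c} #{i}\n")
        for _, row in df.iterrows():
            fh.write(" ".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# corrections


@dataclass
class RegisterCorrection:
    """Per-class register correction: rotation (deg) about the reference
    helical axis, axial shift (Å) in monomer quanta."""

    class_id: int
    delta_phi: float = 0.0
    delta_shift: float = 0.0

    def __post_init__(self):
        self.delta_phi = (self.delta_phi + 180.0) % 360.0 - 180.0
        if self.delta_phi == -180.0:
            self.delta_phi = 180.0


def load_corrections(path: str) -> list[RegisterCorrection]:
    with open(path) as fh:
        payload = json.load(fh)
    return [RegisterCorrection(**e) for e in payload]


def normalize_to_largest_class(corrections: list[RegisterCorrection],
                               classes: np.ndarray) -> list[RegisterCorrection]:
    """Re-express corrections relative to the most populous class, which
    becomes the common reference (identity correction)."""
    vals, counts = np.unique(classes, return_counts=True)
    ref = int(vals[np.argmax(counts)])
    by_id = {c.class_id: c for c in corrections}
    ref_c = by_id.get(ref, RegisterCorrection(ref))
    return [
        RegisterCorrection(c.class_id, c.delta_phi - ref_c.delta_phi,
                           c.delta_shift - ref_c.delta_shift)
        for c in corrections
    ]


def apply_register_correction(
    table: OrientationTable,
    corrections: list[RegisterCorrection],
    axis: np.ndarray = (0.0, 0.0, 1.0),
) -> OrientationTable:
    """Apply per-class register corrections to an orientation table.

    Each particle's orientation matrix M becomes ``M @ R_axis(delta_phi)``
    and its origin moves by ``delta_shift`` along the particle's helical
    axis in the image frame (``M @ axis``, unchanged by the rotation since
    the rotation fixes the axis). Every class present must have a correction
    (identity corrections are fine).
    """
    by_id = {c.class_id: c for c in corrections}
    classes = table.classes()
    missing = sorted(set(int(c) for c in classes) - set(by_id))
    if missing:
        raise ValueError(f"no correction supplied for classes: {missing}")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    out = table.copy()
    mats = table.matrices()
    origins = table.origins()
    new_ang = np.empty((len(classes), 3))
    new_org = np.empty((len(classes), 3))
    for i, cls in enumerate(classes):
        corr = by_id[int(cls)]
        M = mats[i] @ rotation_about_axis(axis, corr.delta_phi)
        new_ang[i] = matrix_to_euler(M)
        new_org[i] = origins[i] + corr.delta_shift * (M @ axis)
    for j, c in enumerate(ANGLE_COLS):
        out.df[c] = [f"{v:.6f}" for v in new_ang[:, j]]
    for j, c in enumerate(ORIGIN_COLS):
        out.df[c] = [f"{v:.6f}" for v in new_org[:, j]]
    return out
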