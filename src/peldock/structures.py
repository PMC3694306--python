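"""Atomic coordinate sets and rigid-body geometry.

Coordinates are in angstroms everywhere.  Structures are read and written as
fixed-column PDB; only heavy atoms are kept (hydrogens are dropped on read,
alternate locations are resolved to the highest-occupancy conformer).  Sites
are addressed as ``(chain id, author residue number)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "RigidTransform",
    "StructureModel",
    "read_structure",
    "write_structure",
    "apply_transform",
    "superpose",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t with R a rotation matrix."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("transform contains non-finite entries")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, axis, angle: float, point=None) -> "RigidTransform":
        """Rotation by ``angle`` (radians) about the line through ``point``
        with direction ``axis``."""
        n = np.asarray(axis, dtype=float)
        n = n / np.linalg.norm(n)
        K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        p = np.zeros(3) if point is None else np.asarray(point, dtype=float)
        t = p - R @ p
        return cls(R, t)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_involution(self, tol: float = 1e-6) -> bool:
        """True when applying the transform twice is the identity (a C2)."""
        sq = self.compose(self)
        return bool(
            np.allclose(sq.rotation, np.eye(3), atol=tol)
            and np.allclose(sq.translation, 0.0, atol=tol)
        )


@dataclass
class StructureModel:
    """A labeled set of heavy atoms (one coordinate model).

    Wraps a :class:`biotite.structure.AtomArray` for identities and I/O, but
    keeps a float64 coordinate array as the source of truth (the AtomArray
    stores float32, which is too coarse for rigid-geometry invariants).
    ``(chain, residue number, atom name)`` identifies each atom uniquely.
    """

    array: bst.AtomArray
    metadata: str = ""
    coord64: np.ndarray | None = None

    def __post_init__(self):
        if self.array.array_length() == 0:
            raise ValueError("empty coordinate set")
        if self.coord64 is None:
            self.coord64 = np.asarray(self.array.coord, dtype=np.float64)
        else:
            self.coord64 = np.asarray(self.coord64, dtype=np.float64)
            if self.coord64.shape != (self.array.array_length(), 3):
                raise ValueError("coordinate array does not match atom count")
        if not np.all(np.isfinite(self.coord64)):
            raise ValueError("non-finite coordinates")
        keys = list(
            zip(self.array.chain_id, self.array.res_id, self.array.atom_name)
        )
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom name) triple")

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.array.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.coord64

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.array.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def chain(self, chain_id: str) -> "StructureModel":
        mask = self.array.chain_id == chain_id
        if not mask.any():
            raise KeyError(f"no chain {chain_id!r}")
        return StructureModel(
            self.array[mask], metadata=self.metadata, coord64=self.coord64[mask]
        )

    def atom_coord(self, chain_id: str, res_id: int, atom_name: str) -> np.ndarray:
        a = self.array
        mask = (
            (a.chain_id == chain_id)
            & (a.res_id == res_id)
            & (a.atom_name == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"atom {atom_name} of {chain_id}{res_id} not found")
        return self.coord64[idx[0]]

    def residue_mask(self, chain_id: str, res_id: int) -> np.ndarray:
        a = self.array
        return (a.chain_id == chain_id) & (a.res_id == res_id)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=np.float64)
        arr = self.array.copy()
        arr.coord = coords  # float32 view for I/O
        return StructureModel(arr, metadata=self.metadata, coord64=coords)


def _drop_hydrogens(arr: bst.AtomArray) -> bst.AtomArray:
    elem = np.char.upper(arr.element.astype("U2"))
    return arr[(elem != "H") & (elem != "D")]


def read_structure(path, model_index: int = 1) -> StructureModel:
    """Read one model from a PDB file (hydrogens dropped, highest-occupancy
    altloc kept)."""
    path = Path(path)
    try:
        pdb = bpdb.PDBFile.read(str(path))
    except (OSError, UnicodeDecodeError) as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    try:
        arr = bpdb.get_structure(pdb, model=model_index, altloc="occupancy")
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    arr = _drop_hydrogens(arr)
    if arr.array_length() == 0:
        raise ValueError(f"no heavy-atom coordinates in {path}")
    return StructureModel(arr, metadata=f"read from {path.name}")


def write_structure(model: StructureModel, path) -> None:
    """Write fixed-column PDB, coordinates rounded to 3 decimals."""
    pdb = bpdb.PDBFile()
    bpdb.set_structure(pdb, model.array)
    pdb.write(str(path))


def apply_transform(model: StructureModel, T: RigidTransform) -> StructureModel:
    """Map every coordinate through the rigid transform; identities kept."""
    return model.with_coords(T.apply(model.coords))


def superpose(
    a: StructureModel | np.ndarray,
    b: StructureModel | np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``a`` onto ``b`` (Kabsch).

    Returns the transform T minimizing ``|T(a) - b|`` over paired points and
    the residual RMSD in angstroms.  ``selection`` is a boolean or index array
    applied to both coordinate sets; the points must correspond one-to-one.
    """
    xa = a.coords if isinstance(a, StructureModel) else np.asarray(a, float)
    xb = b.coords if isinstance(b, StructureModel) else np.asarray(b, float)
    if selection is not None:
        xa, xb = xa[selection], xb[selection]
    if xa.shape != xb.shape:
        raise ValueError("selections do not map one-to-one")
    if xa.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    A, B = xa - ca, xb - cb
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(A, tol=1e-8) < 2:
        raise ValueError("points are collinear; superposition is degenerate")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    T = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((T.apply(xa) - xb) ** 2, axis=1))))
    return T, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without refitting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
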