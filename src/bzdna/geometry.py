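"""Coordinate containers and geometric primitives for nucleic-acid analysis.

Angles are plain floats in degrees, wrapped to [0, 360); signed angular
differences are taken only at comparison time via :func:`periodic_diff`.
Distances are in Angstrom. Chain and residue indexing is 1-based per chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "DuplexTopology",
    "wrap_angle",
    "periodic_diff",
    "dihedral",
    "angle_between",
    "superpose",
    "rmsd",
    "parse_selection",
]

#: residue id: (chain_id, residue_index)
ResidueId = tuple[str, int]


def wrap_angle(a):
    """Wrap angle(s) in degrees into [0, 360)."""
    w = np.asarray(a, dtype=float) % 360.0
    # float rounding of tiny negatives can yield exactly 360.0
    return np.where(w >= 360.0, 0.0, w)[()]


def periodic_diff(a, b):
    """Minimal signed image of ``a - b`` in degrees, in (-180, 180].

    Works element-wise on arrays. ``periodic_diff(350, 10) == -20``.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if d.ndim == 0:
        return float(d)
    return d


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, planar ring, empty selection...)."""


@dataclass(frozen=True)
class Atom:
    """One labeled atom of a snapshot.

    ``name`` uses PDB v3 nucleic-acid nomenclature; primes are stored with
    the ASCII apostrophe (O5', C1' ...).
    """

    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be nonempty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.name}: {self.position}")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.name)


class Frame:
    """One snapshot of labeled atoms with Cartesian coordinates (Angstrom).

    Atom order is preserved; the (chain, residue, name) triple is unique
    within a frame and indexes constant-time lookup.
    """

    def __init__(self, atoms: Iterable[Atom], model_index: int = 1):
        atoms = list(atoms)
        self.model_index = int(model_index)
        self.names = [a.name for a in atoms]
        self.residue_indices = np.array([a.residue_index for a in atoms], dtype=int)
        self.residue_names = [a.residue_name for a in atoms]
        self.chain_ids = [a.chain_id for a in atoms]
        self.coords = (
            np.array([a.position for a in atoms], dtype=float)
            if atoms
            else np.zeros((0, 3))
        )
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(atoms):
            if a.key in self._index:
                raise ValueError(f"duplicate atom {a.key} in frame")
            self._index[a.key] = i

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(
                self.names[i],
                int(self.residue_indices[i]),
                self.residue_names[i],
                self.chain_ids[i],
                self.coords[i],
            )

    def atom_index(self, chain_id: str, residue_index: int, name: str) -> int:
        key = (chain_id, int(residue_index), name)
        if key not in self._index:
            raise KeyError(
                f"atom {name} of residue {chain_id}:{residue_index} not found"
            )
        return self._index[key]

    def has_atom(self, chain_id: str, residue_index: int, name: str) -> bool:
        return (chain_id, int(residue_index), name) in self._index

    def position(self, chain_id: str, residue_index: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(chain_id, residue_index, name)]

    def residue_atom_names(self, chain_id: str, residue_index: int) -> list[str]:
        return [
            n
            for (c, r, n) in self._index
            if c == chain_id and r == residue_index
        ]

    def residue_name(self, chain_id: str, residue_index: int) -> str:
        for i in range(len(self)):
            if self.chain_ids[i] == chain_id and self.residue_indices[i] == residue_index:
                return self.residue_names[i]
        raise KeyError(f"residue {chain_id}:{residue_index} not found")

    def residues(self) -> list[ResidueId]:
        """Residue ids in order of first appearance."""
        seen: dict[ResidueId, None] = {}
        for i in range(len(self)):
            seen.setdefault((self.chain_ids[i], int(self.residue_indices[i])), None)
        return list(seen)

    def select(self, selections: Sequence[str]) -> np.ndarray:
        """Indices for 'chain:resnum:atomname' selection strings.

        A '*' atom name matches every atom of the residue.
        """
        idx: list[int] = []
        for sel in selections:
            chain, resnum, name = parse_selection(sel)
            if name == "*":
                hits = [
                    i
                    for i in range(len(self))
                    if self.chain_ids[i] == chain
                    and self.residue_indices[i] == resnum
                ]
                if not hits:
                    raise KeyError(f"no atoms match selection {sel!r}")
                idx.extend(hits)
            else:
                idx.append(self.atom_index(chain, resnum, name))
        return np.array(idx, dtype=int)

    def with_coords(self, coords: np.ndarray, model_index: int | None = None) -> "Frame":
        """Copy of this frame with replaced coordinates (same labeling)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        new = Frame.__new__(Frame)
        new.model_index = self.model_index if model_index is None else int(model_index)
        new.names = self.names
        new.residue_indices = self.residue_indices
        new.residue_names = self.residue_names
        new.chain_ids = self.chain_ids
        new.coords = coords.copy()
        new._index = self._index
        return new


def parse_selection(sel: str) -> tuple[str, int, str]:
    parts = sel.split(":")
    if len(parts) != 3:
        raise ValueError(f"selection {sel!r} is not 'chain:resnum:atomname'")
    chain, resnum, name = parts
    return chain, int(resnum), name


@dataclass
class DuplexTopology:
    """Strand layout, base pairing and mismatch annotation of a duplex.

    ``pairing`` is a bijection between equal-length antiparallel strands:
    strand_a is listed 5'->3', strand_b 5'->3', and strand_a[i] pairs with
    strand_b[-(i+1)].
    """

    strand_a: list[ResidueId]
    strand_b: list[ResidueId]
    pairing: dict[ResidueId, ResidueId]
    mismatch_pairs: list[tuple[ResidueId, ResidueId]] = field(default_factory=list)
    sequence: dict[ResidueId, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.strand_a) != len(self.strand_b):
            raise ValueError("strands must be of equal length")
        if set(self.pairing) != set(self.strand_a):
            raise ValueError("pairing keys must be exactly strand_a")
        if set(self.pairing.values()) != set(self.strand_b):
            raise ValueError("pairing values must be exactly strand_b (bijection)")
        for i, res in enumerate(self.strand_a):
            if self.pairing[res] != self.strand_b[-(i + 1)]:
                raise ValueError(
                    f"pairing of {res} violates antiparallel strand order"
                )
        for a, b in self.mismatch_pairs:
            if self.pairing.get(a) != b:
                raise ValueError(f"mismatch pair ({a}, {b}) not in pairing")

    @property
    def n_pairs(self) -> int:
        return len(self.strand_a)

    def partner(self, res: ResidueId) -> ResidueId:
        if res in self.pairing:
            return self.pairing[res]
        for a, b in self.pairing.items():
            if b == res:
                return a
        raise KeyError(f"residue {res} not in pairing")

    def strand_of(self, res: ResidueId) -> str:
        if res in self.strand_a:
            return "a"
        if res in self.strand_b:
            return "b"
        raise KeyError(f"residue {res} not in topology")

    def is_mismatch(self, res_a: ResidueId, res_b: ResidueId) -> bool:
        return (res_a, res_b) in self.mismatch_pairs or (
            res_b,
            res_a,
        ) in self.mismatch_pairs


# ---------------------------------------------------------------------------
# geometric primitives


def angle_between(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4, *, degenerate_tol: float = 1e-8) -> float:
    """Torsion angle of the four points, IUPAC sign convention, in [0, 360).

    cis (eclipsed) = 0, trans = 180; positive rotations are clockwise
    looking from p2 to p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p2 - p1
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < degenerate_tol or np.linalg.norm(n2) < degenerate_tol:
        raise GeometryError("degenerate dihedral: three points are collinear")
    b1u = b1 / np.linalg.norm(b1)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1u)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares (Kabsch) superposition of mobile onto reference.

    Returns ``(transformed_mobile, rmsd)``. Both inputs are (N, 3) arrays
    with rows in 1:1 correspondence.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose expects matching (N, 3) arrays")
    if len(mobile) == 0:
        raise GeometryError("empty selection")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T + rc
    dev = moved - reference
    return moved, float(np.sqrt((dev * dev).sum() / len(mobile)))


def rmsd(
    frame_a: Frame,
    frame_b: Frame,
    selection: Sequence[str] | None = None,
    *,
    superposition: bool = True,
) -> float:
    """RMSD between two frames after optimal superposition (Angstrom).

    ``selection`` is a list of 'chain:resnum:atomname' strings evaluated
    on both frames (atoms map 1:1 by identity); default: all atoms shared
    by identity, in frame_a order.
    """
    if selection is None:
        keys = [a.key for a in frame_a if a.key in frame_b._index]
        if not keys:
            raise GeometryError("empty selection")
        ia = np.array([frame_a._index[k] for k in keys])
        ib = np.array([frame_b._index[k] for k in keys])
    else:
        if len(selection) == 0:
            raise GeometryError("empty selection")
        ia = frame_a.select(selection)
        ib = frame_b.select(selection)
    A = frame_a.coords[ia]
    B = frame_b.coords[ib]
    if not superposition:
        dev = A - B
        return float(np.sqrt((dev * dev).sum() / len(A)))
    return superpose(A, B)[1]
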