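"""Hydrogen-depleted molecular graphs and topological distance matrices.

The graph model deliberately keeps only what 2-D (topological) descriptors
need: element, aromaticity, Kekulé bond orders and implicit hydrogen counts.
Stereochemistry is discarded on parsing. SMILES handling is delegated to
RDKit; the graph itself is a plain adjacency structure so that descriptor
code stays independent of the toolkit.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse errors are surfaced as exceptions


class ParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a valid graph."""


@dataclass(frozen=True)
class Atom:
    element: str
    aromatic: bool
    charge: int
    n_h: int  # implicit + explicit hydrogens


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # Kekulé order: 1, 2 or 3
    aromatic: bool


@dataclass
class MolecularGraph:
    """Connected hydrogen-depleted molecular graph."""

    atoms: list[Atom]
    bonds: list[Bond]
    smiles: str = ""
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        if not smiles or not smiles.strip():
            raise ParseError("empty SMILES string")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"unparseable SMILES: {smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ParseError(f"disconnected structure rejected: {smiles!r}")
        Chem.RemoveStereochemistry(mol)
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        atoms = [
            Atom(
                element=a.GetSymbol(),
                aromatic=a.GetIsAromatic(),
                charge=a.GetFormalCharge(),
                n_h=a.GetTotalNumHs(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            kb = kek.GetBondBetweenAtoms(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            bonds.append(
                Bond(
                    i=b.GetBeginAtomIdx(),
                    j=b.GetEndAtomIdx(),
                    order=int(kb.GetBondTypeAsDouble()),
                    aromatic=b.GetIsAromatic(),
                )
            )
        return cls(atoms=atoms, bonds=bonds,
                   smiles=Chem.MolToSmiles(mol), _rdmol=mol)

    # -- basic views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_rings(self) -> int:
        """Cyclomatic number (independent cycles) of the connected graph."""
        return self.n_bonds - self.n_atoms + 1

    def neighbors(self, i: int) -> list[int]:
        return self._adjacency()[i]

    def degree(self, i: int) -> int:
        return len(self._adjacency()[i])

    def degrees(self) -> np.ndarray:
        adj = self._adjacency()
        return np.array([len(adj[i]) for i in range(self.n_atoms)], dtype=int)

    def _adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def rdmol(self) -> Chem.Mol:
        """RDKit molecule (re-parsed from canonical SMILES if needed)."""
        if self._rdmol is None:
            self._rdmol = Chem.MolFromSmiles(self.smiles)
        return self._rdmol

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol())

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        n = self.n_atoms
        seen = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError(f"self-loop at atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"parallel bond {key}")
            seen.add(key)
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond index out of range: {b}")
        if n > 1 and not self._connected():
            raise ValueError("graph is disconnected")
        for idx, a in enumerate(self.atoms):
            if a.element == "C" and a.charge == 0:
                order_sum = sum(b.order for b in self.bonds
                                if idx in (b.i, b.j))
                if a.n_h != 4 - order_sum:
                    raise ValueError(
                        f"carbon {idx}: H count {a.n_h} != 4 - {order_sum}")

    def _connected(self) -> bool:
        adj = self._adjacency()
        seen = {0}
        queue = deque([0])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_atoms


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path bond counts with distance-degree views."""

    d: np.ndarray  # (n, n) int

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def s(self) -> np.ndarray:
        """Distance degrees: row sums of the distance matrix."""
        return self.d.sum(axis=1)

    @property
    def two_w(self) -> int:
        """Twice the Wiener number: grand sum of the distance matrix."""
        return int(self.d.sum())

    def eccentricities(self) -> np.ndarray:
        return self.d.max(axis=1)


def distance_matrix(g: MolecularGraph) -> DistanceMatrix:
    """BFS all-pairs topological distances (unit bond lengths).

    Bond orders are ignored: the graph metric is the number of bonds on the
    shortest path, which makes distance-based indices identical for
    skeleton-isomorphic molecules regardless of unsaturation pattern.
    """
    n = g.n_atoms
    adj = g._adjacency()
    d = np.full((n, n), -1, dtype=int)
    for src in range(n):
        d[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if d[src, v] < 0:
                    d[src, v] = d[src, u] + 1
                    queue.append(v)
    if (d < 0).any():
        raise ValueError("graph is disconnected")
    return DistanceMatrix(d=d)
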