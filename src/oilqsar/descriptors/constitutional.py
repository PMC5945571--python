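"""Constitutional (functional-group count) descriptors.

Carbon classes follow the carbon-neighbour convention: a secondary carbon
has exactly two carbon neighbours, a tertiary one exactly three, regardless
of heteroatom substitution (so the carbinol carbon of a secondary alcohol is
still a secondary carbon).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from ..graph import MolecularGraph

__all__ = ["ConstitutionalCounts", "constitutional_counts", "ether_count"]


@dataclass(frozen=True)
class ConstitutionalCounts:
    nCs: int     # secondary sp3 carbons
    nCt: int     # tertiary sp3 carbons
    nCconj: int  # non-aromatic conjugated sp2 carbons
    nRdCp: int   # terminal =CH2 carbons
    nRdCs: int   # =CH- carbons
    nRdCt: int   # fully substituted =C< carbons
    nRCO: int    # aliphatic ketones
    nArOH: int   # phenolic hydroxyls
    nOH: int     # non-phenolic hydroxyls
    nHDon: int   # H-bond donor hydrogens (OH + NH)
    nHAcc: int   # H-bond acceptor atoms (N, O, F)

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _carbon_neighbors(g: MolecularGraph, adj: list[list[int]], i: int) -> int:
    return sum(1 for j in adj[i] if g.atoms[j].element == "C")


def _double_bonds(g: MolecularGraph):
    return [b for b in g.bonds if b.order >= 2 and not b.aromatic]


def _conjugated_cc_bonds(g: MolecularGraph) -> set[int]:
    """Indices of non-aromatic multiple bonds conjugated with another
    multiple bond (non-aromatic or aromatic) across one single bond."""
    multi = {idx for idx, b in enumerate(g.bonds)
             if b.aromatic or b.order >= 2}
    atom_multi: dict[int, set[int]] = {}
    for idx in multi:
        b = g.bonds[idx]
        atom_multi.setdefault(b.i, set()).add(idx)
        atom_multi.setdefault(b.j, set()).add(idx)
    conj: set[int] = set()
    for idx, b in enumerate(g.bonds):
        if b.order == 1 and not b.aromatic:
            left = atom_multi.get(b.i, set())
            right = atom_multi.get(b.j, set())
            if left and right and (left | right) - (left & right):
                conj |= left | right
    return {idx for idx in conj if not g.bonds[idx].aromatic}


def constitutional_counts(g: MolecularGraph) -> ConstitutionalCounts:
    adj = g._adjacency()
    atoms = g.atoms

    def is_sp3_c(i: int) -> bool:
        if atoms[i].element != "C" or atoms[i].aromatic:
            return False
        return all(b.order == 1 for b in g.bonds if i in (b.i, b.j))

    ncs = sum(1 for i in range(g.n_atoms)
              if is_sp3_c(i) and _carbon_neighbors(g, adj, i) == 2)
    nct = sum(1 for i in range(g.n_atoms)
              if is_sp3_c(i) and _carbon_neighbors(g, adj, i) == 3)

    # carbons of conjugated non-aromatic multiple bonds
    conj_atoms: set[int] = set()
    for idx in _conjugated_cc_bonds(g):
        b = g.bonds[idx]
        for a in (b.i, b.j):
            if atoms[a].element == "C":
                conj_atoms.add(a)
    nconj = len(conj_atoms)

    # C=C carbons classified by hydrogen count
    nrdcp = nrdcs = nrdct = 0
    cc_atoms: set[int] = set()
    for b in _double_bonds(g):
        if atoms[b.i].element == "C" and atoms[b.j].element == "C":
            cc_atoms |= {b.i, b.j}
    for a in cc_atoms:
        h = atoms[a].n_h
        if h >= 2:
            nrdcp += 1
        elif h == 1:
            nrdcs += 1
        else:
            nrdct += 1

    nrco = 0
    for b in _double_bonds(g):
        pair = (atoms[b.i].element, atoms[b.j].element)
        c, o = (b.i, b.j) if pair == ("C", "O") else (
            (b.j, b.i) if pair == ("O", "C") else (None, None))
        if c is None or atoms[c].aromatic:
            continue
        if _carbon_neighbors(g, adj, c) == 2:  # ketone, not aldehyde/acid
            nrco += 1

    naroh = noh = 0
    for i, a in enumerate(atoms):
        if a.element == "O" and a.n_h >= 1 and len(adj[i]) == 1:
            if atoms[adj[i][0]].aromatic:
                naroh += 1
            else:
                noh += 1

    nhdon = sum(a.n_h for a in atoms if a.element in ("O", "N"))
    nhacc = sum(1 for a in atoms if a.element in ("N", "O", "F"))

    return ConstitutionalCounts(ncs, nct, nconj, nrdcp, nrdcs, nrdct,
                                nrco, naroh, noh, nhdon, nhacc)


def ether_count(g: MolecularGraph) -> int:
    """nROR: oxygens bonded to two carbons by single bonds (epoxides count,
    ester/acid oxygens do not arise in this chemotype set)."""
    adj = g._adjacency()
    n = 0
    for i, a in enumerate(g.atoms):
        if a.element != "O" or len(adj[i]) != 2:
            continue
        if all(g.atoms[j].element == "C" for j in adj[i]) and all(
                b.order == 1 for b in g.bonds if i in (b.i, b.j)):
            n += 1
    return n
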