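"""Topological indices computed on the hydrogen-depleted graph.

All indices here are functions of the unit-length bond graph only (plus, for
the electrotopological-state family, element valences), so skeleton-isomorphic
molecules get identical distance-based values.
"""

from __future__ import annotations

import math

import numpy as np

from ..graph import DistanceMatrix, MolecularGraph, distance_matrix

__all__ = [
    "balaban_j",
    "distance_sum_indices",
    "eccentricity_indices",
    "centric_indices",
    "kier_phi",
    "estate_values",
    "tie_index",
    "topological_profile",
]


def balaban_j(g: MolecularGraph, dm: DistanceMatrix | None = None) -> float:
    """Distance-connectivity index J = q/(mu+1) * sum_edges (s_i*s_j)^-1/2.

    q is the bond count and mu the cyclomatic number; s are the distance
    degrees.  Defined as 0 for a single-atom graph.
    """
    if g.n_atoms < 2:
        return 0.0
    dm = dm or distance_matrix(g)
    s = dm.s
    q = g.n_bonds
    mu = q - g.n_atoms + 1
    total = sum(1.0 / math.sqrt(s[b.i] * s[b.j]) for b in g.bonds)
    return q / (mu + 1.0) * total


def distance_sum_indices(dm: DistanceMatrix) -> tuple[int, int, int]:
    """(UNIP, CENT, VAR): unipolarity, centralization, variation."""
    s = dm.s
    unip = int(s.min())
    cent = int(dm.two_w - dm.n * unip)
    var = int(s.max() - unip)
    return unip, cent, var


def eccentricity_indices(
    g: MolecularGraph, dm: DistanceMatrix | None = None
) -> tuple[int, int, float]:
    """(ECC, CSI, ICR).

    ECC is the eccentricity sum, CSI the eccentric connectivity index
    sum(deg_i * ecc_i), and ICR the radial centric information index: the
    Shannon entropy (bits) of the partition of vertices into classes of
    equal eccentricity.
    """
    dm = dm or distance_matrix(g)
    ecc = dm.eccentricities()
    deg = g.degrees()
    ecc_sum = int(ecc.sum())
    csi = int((deg * ecc).sum())
    n = dm.n
    icr = 0.0
    for cls in np.unique(ecc):
        p = (ecc == cls).sum() / n
        icr -= p * math.log2(p)
    return ecc_sum, csi, icr


def _pruning_partition(g: MolecularGraph) -> list[int]:
    """Terminal-vertex pruning classes.

    Iteratively delete all degree<=1 vertices; each sweep is one class.  A
    non-empty 2-connected remnant (the ring core) counts as a single class
    of size 1, a convention calibrated against the reference tables for the
    monocyclic/bicyclic chemotypes in scope.
    """
    adj = {i: set(g.neighbors(i)) for i in range(g.n_atoms)}
    classes: list[int] = []
    while adj:
        leaves = [v for v, nb in adj.items() if len(nb) <= 1]
        if not leaves:
            classes.append(-1)  # ring core sentinel
            break
        classes.append(len(leaves))
        for v in leaves:
            for u in adj[v]:
                adj[u].discard(v)
            del adj[v]
    return [1 if c == -1 else c for c in classes]


def centric_indices(g: MolecularGraph) -> tuple[int, float]:
    """(BAC, Lop): Balaban centric index and lopping centric information.

    BAC = sum_k n_k^2 over the pruning partition; Lop is the Shannon entropy
    (bits) of the same partition relative to the total atom count.
    """
    n = g.n_atoms
    classes = _pruning_partition(g)
    bac = sum(c * c for c in classes)
    lop = -sum((c / n) * math.log2(c / n) for c in classes)
    return bac, lop


# Kier alpha modifiers: covalent-radius ratios relative to sp3 carbon.
_KIER_ALPHA = {
    ("C", "sp3"): 0.0,
    ("C", "sp2"): -0.13,
    ("C", "sp"): -0.22,
    ("N", "sp3"): -0.04,
    ("N", "sp2"): -0.20,
    ("O", "sp3"): -0.04,
    ("O", "sp2"): -0.20,
    ("S", "sp3"): 0.35,
}


def _hybridization(g: MolecularGraph, i: int) -> str:
    orders = [b.order for b in g.bonds if i in (b.i, b.j)]
    aromatic = g.atoms[i].aromatic
    if aromatic or 2 in orders:
        return "sp2"
    if 3 in orders:
        return "sp"
    return "sp3"


def kier_alpha(g: MolecularGraph) -> float:
    """Sum of Kier hybridization/covalent-radius alpha contributions."""
    total = 0.0
    for i, atom in enumerate(g.atoms):
        key = (atom.element, _hybridization(g, i))
        try:
            total += _KIER_ALPHA[key]
        except KeyError:
            raise ValueError(f"no Kier alpha contribution for {key}") from None
    return total


def kier_phi(g: MolecularGraph) -> float:
    """Kier molecular flexibility Phi = (1-kappa_a * 2-kappa_a) / A."""
    a = g.n_atoms
    if a < 3:
        raise ValueError("flexibility index needs at least 3 atoms")
    alpha = kier_alpha(g)
    p1 = g.n_bonds
    deg = g.degrees()
    p2 = int(sum(d * (d - 1) // 2 for d in deg))
    k1 = (a + alpha) * (a + alpha - 1.0) ** 2 / (p1 + alpha) ** 2
    k2 = (a + alpha - 1.0) * (a + alpha - 2.0) ** 2 / (p2 + alpha) ** 2
    return k1 * k2 / a


# valence electrons for the E-state delta-v
_VALENCE = {"C": 4, "N": 5, "O": 6, "S": 6, "F": 7, "Cl": 7, "Br": 7, "I": 7}
_PRINCIPAL = {"C": 2, "N": 2, "O": 2, "F": 2, "S": 3, "Cl": 3, "Br": 4, "I": 5}


def estate_values(g: MolecularGraph, dm: DistanceMatrix | None = None) -> np.ndarray:
    """Kier-Hall electrotopological states S_i.

    Intrinsic state I_i = ((2/L_i)^2 * delta_v + 1) / delta with the
    field perturbation S_i = I_i + sum_j (I_i - I_j) / (d_ij + 1)^2.
    """
    dm = dm or distance_matrix(g)
    deg = g.degrees()
    intrinsic = np.empty(g.n_atoms)
    for i, atom in enumerate(g.atoms):
        delta = deg[i]
        delta_v = _VALENCE[atom.element] - atom.n_h
        l_q = _PRINCIPAL[atom.element]
        intrinsic[i] = ((2.0 / l_q) ** 2 * delta_v + 1.0) / delta
    diff = intrinsic[:, None] - intrinsic[None, :]
    damp = 1.0 / (dm.d + 1.0) ** 2
    np.fill_diagonal(damp, 0.0)
    return intrinsic + (diff * damp).sum(axis=1)


def tie_index(g: MolecularGraph, dm: DistanceMatrix | None = None) -> float:
    """E-state topological parameter.

    Pairwise aggregation of electrotopological-state contrasts damped by the
    squared topological distance:  TIE = sum_{i<j} |S_i - S_j| / d_ij^2.
    """
    dm = dm or distance_matrix(g)
    s = estate_values(g, dm)
    total = 0.0
    n = g.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            total += abs(s[i] - s[j]) / dm.d[i, j] ** 2
    return total


def topological_profile(g: MolecularGraph) -> dict[str, float]:
    """All Table-style topological indices as a flat mapping."""
    dm = distance_matrix(g)
    unip, cent, var = distance_sum_indices(dm)
    ecc, csi, icr = eccentricity_indices(g, dm)
    bac, lop = centric_indices(g)
    return {
        "J": balaban_j(g, dm),
        "TIE": tie_index(g, dm),
        "UNIP": unip,
        "CENT": cent,
        "VAR": var,
        "BAC": bac,
        "Lop": lop,
        "ICR": icr,
        "CSI": csi,
        "ECC": ecc,
        "PHI": kier_phi(g),
    }
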