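"""Physicochemical descriptors: unsaturation, hydrophilicity, polar surface
area, partition coefficients, molar refractivity and charge aggregates.

TPSA and the Ghose-Crippen logP/MR come from RDKit's published fragment
tables; the Moriguchi logP regression is implemented here (13 structural
parameters, of which the amphoteric/quaternary-N/nitro/isothiocyanate/
beta-lactam terms are retained for completeness but vanish on terpenes).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import rdMolDescriptors

from ..graph import MolecularGraph, distance_matrix

__all__ = [
    "unsaturation_index",
    "hydrophilic_factor",
    "tpsa",
    "moriguchi_logp",
    "ghose_crippen",
    "charge_descriptors",
    "physchem_profile",
    "ChargeSummary",
]

_HALOGEN_WEIGHT = {"F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}


def unsaturation_index(g: MolecularGraph) -> float:
    """Ui = log2(1 + nMB); every double, triple or aromatic bond counts."""
    n_mb = sum(1 for b in g.bonds if b.aromatic or b.order >= 2)
    return math.log2(1 + n_mb)


def hydrophilic_factor(g: MolecularGraph) -> float:
    """Todeschini hydrophilic factor from heavy-atom and polar-H counts."""
    a = g.n_atoms
    if a < 1:
        raise ValueError("empty graph")
    n_hy = sum(at.n_h for at in g.atoms if at.element in ("O", "N", "S"))
    n_c = sum(1 for at in g.atoms if at.element == "C")
    denom = math.log2(1.0 + a)
    if denom == 0.0:
        return 0.0
    num = (1.0 + n_hy) * math.log2(1.0 + n_hy)
    num += n_c * (1.0 / a) * math.log2(1.0 / a)
    num += math.sqrt(n_hy / a**2)
    return num / denom


def tpsa(g: MolecularGraph) -> float:
    """Ertl fragment-contribution topological polar surface area (A^2)."""
    return float(rdMolDescriptors.CalcTPSA(g.rdmol()))


def ghose_crippen(g: MolecularGraph) -> tuple[float, float]:
    """(AlogP, AMR) from the Wildman-Crippen atomic contributions."""
    logp, mr = rdMolDescriptors.CalcCrippenDescriptors(g.rdmol())
    return float(logp), float(mr)


def _moriguchi_parameters(g: MolecularGraph) -> dict[str, float]:
    atoms = g.atoms
    adj = g._adjacency()

    cx = sum(1.0 for a in atoms if a.element == "C")
    cx += sum(_HALOGEN_WEIGHT.get(a.element, 0.0) for a in atoms)

    hetero = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
    no = float(len(hetero))

    prx = 0.0
    if len(hetero) > 1:
        d = distance_matrix(g).d
        for ii, hi in enumerate(hetero):
            for hj in hetero[ii + 1:]:
                if d[hi, hj] == 1:
                    prx += 2.0
                elif d[hi, hj] == 2:
                    prx += 1.0

    # unsaturated bonds; aromatic rings enter through their Kekulé doubles
    ub = float(sum(1 for b in g.bonds if b.order >= 2))

    # intramolecular H-bond dummy: donor and acceptor on adjacent aromatic
    # carbons (salicyl-type); never fires on the terpene set
    hb = 0.0
    donors = {i for i, a in enumerate(atoms)
              if a.element in ("N", "O") and a.n_h > 0}
    acceptors = set(hetero)
    for i in donors:
        ci = [j for j in adj[i] if atoms[j].aromatic]
        for c in ci:
            for c2 in adj[c]:
                if atoms[c2].aromatic:
                    for x in adj[c2]:
                        if x in acceptors and x != i:
                            hb = 1.0
    # polar substituents on aromatic rings
    pol = 0.0
    for i, a in enumerate(atoms):
        if a.aromatic:
            continue
        aromatic_anchor = any(atoms[j].aromatic for j in adj[i])
        if not aromatic_anchor:
            continue
        if a.element in ("N", "O"):
            pol += 1.0
        elif a.element == "C" and any(
                atoms[j].element in ("N", "O") for j in adj[i]):
            pol += 1.0

    hydrocarbon = all(a.element == "C" for a in atoms)
    saturated = all(b.order == 1 for b in g.bonds)
    alk = 1.0 if hydrocarbon and saturated and g.n_rings == 0 else 0.0
    # RNG: any ring beyond the aromatic ones
    rng = 1.0 if g.n_rings - _aromatic_ring_count(g) > 0 else 0.0

    qn = sum(1.0 for i, a in enumerate(atoms)
             if a.element == "N" and (a.charge > 0 or len(adj[i]) == 4))
    return {
        "CX": cx, "NO": no, "PRX": prx, "UB": ub, "HB": hb, "POL": pol,
        "AMP": 0.0, "ALK": alk, "RNG": rng, "QN": qn,
        "NO2": 0.0, "NCS": 0.0, "BLM": 0.0,
    }


def _aromatic_ring_count(g: MolecularGraph) -> int:
    """Independent cycles consisting purely of aromatic bonds."""
    n_arom_bonds = sum(1 for b in g.bonds if b.aromatic)
    arom_atoms = {b.i for b in g.bonds if b.aromatic} | {
        b.j for b in g.bonds if b.aromatic}
    if not arom_atoms:
        return 0
    return n_arom_bonds - len(arom_atoms) + 1


def moriguchi_logp(g: MolecularGraph) -> float:
    """Moriguchi 13-parameter octanol/water logP regression."""
    p = _moriguchi_parameters(g)
    return (
        1.244 * p["CX"] ** 0.6
        - 1.017 * p["NO"] ** 0.9
        + 0.406 * p["PRX"]
        - 0.145 * p["UB"] ** 0.8
        + 0.511 * p["HB"]
        + 0.268 * p["POL"]
        - 2.215 * p["AMP"]
        + 0.912 * p["ALK"]
        - 0.392 * p["RNG"]
        - 3.684 * p["QN"]
        + 0.474 * p["NO2"]
        + 1.582 * p["NCS"]
        + 0.773 * p["BLM"]
        - 1.041
    )


@dataclass(frozen=True)
class ChargeSummary:
    qpos: float
    qneg: float
    qtot: float


def charge_descriptors(q: Sequence[float]) -> ChargeSummary:
    """Aggregate an externally supplied per-atom charge vector.

    Charges are never computed here; any charge model can feed this.
    """
    arr = np.asarray(q, dtype=float)
    if arr.size == 0:
        raise ValueError("empty charge vector")
    qpos = float(arr[arr > 0].sum())
    qneg = float(arr[arr < 0].sum())
    return ChargeSummary(qpos=qpos, qneg=qneg, qtot=float(np.abs(arr).sum()))


def physchem_profile(g: MolecularGraph) -> dict[str, float]:
    alogp, amr = ghose_crippen(g)
    return {
        "Ui": unsaturation_index(g),
        "Hy": hydrophilic_factor(g),
        "AMR": amr,
        "TPSA": tpsa(g),
        "MlogP": moriguchi_logp(g),
        "AlogP": alogp,
    }
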