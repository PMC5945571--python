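"""Frontier-orbital (Koopmans-theorem) chemical reactivity descriptors.

All quantities are closed-form arithmetic on the HOMO/LUMO energies in eV:

    I = -E_HOMO          A = -E_LUMO         gap = E_LUMO - E_HOMO
    chi = (I + A) / 2    mu = -chi           eta = gap / 2
    sigma = 1 / eta      omega = mu^2 / (2 eta)

The standard conceptual-DFT sign convention is used (mu <= 0 for bound
molecules); validators against legacy tables compare magnitudes, since some
published tables flip the chi/mu signs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .library import data_path

__all__ = [
    "OrbitalEnergies",
    "ReactivityProfile",
    "koopmans_profile",
    "load_reactivity_table",
    "validate_reactivity_table",
]


@dataclass(frozen=True)
class OrbitalEnergies:
    e_homo: float  # eV
    e_lumo: float  # eV

    def __post_init__(self):
        if not self.e_lumo > self.e_homo:
            raise ValueError(
                f"degenerate or crossed frontier orbitals: "
                f"E_LUMO={self.e_lumo} <= E_HOMO={self.e_homo}")


@dataclass(frozen=True)
class ReactivityProfile:
    i: float      # ionization potential (eV)
    a: float      # electron affinity (eV)
    gap: float    # eV
    chi: float    # electronegativity (eV)
    mu: float     # chemical potential (eV)
    eta: float    # hardness (eV)
    sigma: float  # softness (1/eV)
    omega: float  # global electrophilicity (eV)

    def as_dict(self) -> dict[str, float]:
        return {
            "I": self.i, "A": self.a, "GAP": self.gap, "chi": self.chi,
            "mu": self.mu, "eta": self.eta, "sigma": self.sigma,
            "omega": self.omega,
        }


def koopmans_profile(orb: OrbitalEnergies) -> ReactivityProfile:
    i = -orb.e_homo
    a = -orb.e_lumo
    gap = orb.e_lumo - orb.e_homo
    chi = (i + a) / 2.0
    eta = gap / 2.0
    mu = -chi
    sigma = 1.0 / eta
    omega = mu * mu / (2.0 * eta)
    return ReactivityProfile(i=i, a=a, gap=gap, chi=chi, mu=mu,
                             eta=eta, sigma=sigma, omega=omega)


def load_reactivity_table() -> list[dict[str, float]]:
    """Packaged fixture: printed orbital energies + reactivity descriptors."""
    with data_path("table6_reactivity.csv").open(newline="") as fh:
        return [{k: float(v) for k, v in row.items()}
                for row in csv.DictReader(fh)]


def validate_reactivity_table(
    rows: list[dict[str, float]] | None = None, tol: float = 0.005
) -> list[dict]:
    """Recompute each row from its orbital energies and report deviations.

    Printed chi/mu are compared by magnitude (legacy sign convention).
    Returns one report entry per row with per-field absolute deviations and
    a ``flagged`` marker for any deviation above ``tol``.
    """
    rows = rows if rows is not None else load_reactivity_table()
    report = []
    for row in rows:
        prof = koopmans_profile(OrbitalEnergies(row["E_HOMO"], row["E_LUMO"]))
        dev = {
            "I": abs(prof.i - row["I"]),
            "A": abs(prof.a - row["A"]),
            "GAP": abs(prof.gap - row["GAP"]),
            "chi": abs(abs(prof.chi) - abs(row["chi"])),
            "mu": abs(abs(prof.mu) - abs(row["mu"])),
            "eta": abs(prof.eta - row["eta"]),
            "sigma": abs(prof.sigma - row["sigma"]),
        }
        report.append({
            "id": int(row["id"]),
            "deviations": dev,
            "max_deviation": max(dev.values()),
            "flagged": max(dev.values()) > tol,
        })
    return report
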