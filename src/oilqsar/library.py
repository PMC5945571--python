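"""The packaged 50-compound essential-oil library with experimental LC50s."""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

from .graph import MolecularGraph

__all__ = ["CompoundRecord", "load_library", "validate_library", "data_path"]


@dataclass(frozen=True)
class CompoundRecord:
    """One tested molecule: identity, structure and LC50 endpoints (µg/mL).

    Each endpoint is (point, lower, upper) for the 95% CI; an endpoint is
    None when censored (reported only as a lower bound).
    """

    id: int
    name: str
    chemclass: str
    smiles: str
    lc50_iii: tuple[float, float, float] | None
    lc50_iv: tuple[float, float, float] | None
    lc50_pupae: tuple[float, float, float] | None
    pupae_censored: bool = False
    note: str = ""

    def graph(self) -> MolecularGraph:
        return MolecularGraph.from_smiles(self.smiles)

    def lc50(self, endpoint: str) -> float | None:
        triplet = {
            "III": self.lc50_iii, "IV": self.lc50_iv, "pupae": self.lc50_pupae
        }.get(endpoint)
        if triplet is None and endpoint not in ("III", "IV", "pupae"):
            raise KeyError(f"unknown endpoint {endpoint!r}")
        if endpoint == "pupae" and self.pupae_censored:
            return None
        return triplet[0] if triplet else None


def data_path(name: str):
    """Path-like handle to a packaged data file."""
    return resources.files("oilqsar.data").joinpath(name)


def _triplet(row: dict, prefix: str) -> tuple[float, float, float] | None:
    try:
        return (float(row[prefix]), float(row[prefix + "_lo"]),
                float(row[prefix + "_hi"]))
    except (ValueError, KeyError):
        return None


def load_library() -> list[CompoundRecord]:
    """Load the 50 packaged compound records."""
    records = []
    with data_path("compounds.csv").open(newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                CompoundRecord(
                    id=int(row["id"]),
                    name=row["name"],
                    chemclass=row["chemclass"],
                    smiles=row["smiles"],
                    lc50_iii=_triplet(row, "lc50_iii"),
                    lc50_iv=_triplet(row, "lc50_iv"),
                    lc50_pupae=_triplet(row, "lc50_pupae"),
                    pupae_censored=row["pupae_censored"] == "1",
                    note=row.get("note", ""),
                )
            )
    if [r.id for r in records] != list(range(1, 51)):
        raise ValueError("library must contain ids 1..50 in order")
    return records


def validate_library(records: list[CompoundRecord] | None = None) -> list[str]:
    """Flag (without rejecting) internally inconsistent confidence intervals.

    The source table contains transcription anomalies; they are preserved
    verbatim and surfaced here as warnings.
    """
    records = records if records is not None else load_library()
    problems = []
    for rec in records:
        for label, trip in (("III", rec.lc50_iii), ("IV", rec.lc50_iv),
                            ("pupae", rec.lc50_pupae)):
            if trip is None:
                continue
            point, lo, hi = trip
            if not (lo <= point <= hi):
                problems.append(
                    f"compound {rec.id} ({rec.name}) {label}: "
                    f"CI ({lo}-{hi}) inconsistent with point {point}")
    for msg in problems:
        warnings.warn(msg, stacklevel=2)
    return problems
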