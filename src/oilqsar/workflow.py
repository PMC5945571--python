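"""End-to-end reproduction workflow: regenerates every verification table."""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptors import physchem_profile, topological_profile
from .ga import GaConfig, ga_search, exhaustive_search
from .io import write_report
from .library import load_library, validate_library
from .probit import fit_probit
from .published import descriptor_table, evaluate_all
from .reactivity import validate_reactivity_table
from .simulate import BioassaySimSpec, QsarSimSpec, gen_bioassay, gen_qsar

VERIFY_COMPOUNDS = (15, 30, 34, 50)


def descriptor_verification(ids=VERIFY_COMPOUNDS) -> pd.DataFrame:
    """Computed vs printed descriptors for the curated verification subset."""
    lib = {r.id: r for r in load_library()}
    printed = descriptor_table()
    rows = []
    for i in ids:
        g = lib[i].graph()
        values = {**topological_profile(g), **physchem_profile(g)}
        for name, val in values.items():
            if name not in printed.columns:
                continue
            p = printed.loc[i, name]
            rows.append({
                "id": i, "name": lib[i].name, "descriptor": name,
                "computed": round(float(val), 4), "printed": float(p),
                "abs_dev": round(abs(float(val) - float(p)), 4),
            })
    return pd.DataFrame(rows)


def probit_simulation_summary(seed: int, replicates: int = 200) -> dict:
    spec = BioassaySimSpec(lc50=50.0, slope=2.5, replicates=replicates,
                           seed=seed)
    estimates, covered = [], 0
    for ds in gen_bioassay(spec):
        try:
            fit = fit_probit(ds)
        except Exception:
            continue
        estimates.append(fit.lc50)
        lo, hi = fit.lc50_ci
        covered += int(lo <= spec.lc50 <= hi)
    return {
        "true_lc50": spec.lc50,
        "replicates": replicates,
        "fitted": len(estimates),
        "mean_lc50": float(np.mean(estimates)),
        "ci_coverage": covered / len(estimates),
    }


def ga_simulation_summary(seed: int) -> dict:
    spec = QsarSimSpec(noise_sd=0.66, seed=seed)
    X, y, truth = gen_qsar(spec)
    cfg = GaConfig(population=60, generations=40, max_subset=3, seed=seed)
    top = ga_search(X, y, cfg)[0]
    oracle = exhaustive_search(X, y, max_subset=3)
    return {
        "planted": list(truth.planted_names),
        "realized_r2": truth.realized_r2,
        "ga_top": list(top.descriptors),
        "ga_q2": top.q2,
        "oracle": list(oracle.descriptors),
        "oracle_q2": oracle.q2,
        "ga_matches_oracle": set(top.descriptors) == set(oracle.descriptors),
        "recovered_planted": set(top.descriptors) == set(truth.planted_names),
    }


def run_reproduce(endpoint: str = "IV", seed: int = 0,
                  outdir: str | Path = "reproduce_out") -> dict[str, Path]:
    """Emit the full report bundle; every file stamped with config + seed."""
    react = validate_reactivity_table()
    refits = [
        {k: v for k, v in rep.items() if k != "fitted"}
        for rep in evaluate_all(endpoint=endpoint)
    ]
    refit_df = pd.DataFrame([
        {
            "model": r["model"], "n": r["n"],
            "descriptors": "+".join(r["descriptors"]),
            "printed_R2": r["printed"]["R2"], "refit_R2": r["refit"]["R2"],
            "printed_Q2": r["printed"]["Q2"], "refit_Q2": r["refit"]["Q2"],
            "signs_all_match": r["signs_all_match"],
            "suspect": ",".join(r["suspect"]),
        }
        for r in refits
    ]).set_index("model")

    bundle = {
        "config": {
            "version": __version__, "endpoint": endpoint, "seed": seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "tolerances": {"reactivity_eV": 0.005, "model_stat": 0.02},
        },
        "library_warnings": validate_library(),
        "reactivity_flagged": [r["id"] for r in react if r["flagged"]],
        "reactivity_max_dev": max(r["max_deviation"] for r in react),
        "model_refits": refit_df,
        "descriptor_verification": descriptor_verification(),
        "probit_simulation": probit_simulation_summary(seed),
        "ga_simulation": ga_simulation_summary(seed),
    }
    return write_report(bundle, outdir, stem="reproduce")
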