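"""Schema-checked CSV I/O and report writing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_report", "SchemaError"]


class SchemaError(ValueError):
    """CSV header does not match the declared schema."""


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a CSV whose header must contain the schema's columns.

    ``schema`` maps column name -> dtype (int, float or str).  Extra columns
    are preserved untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        raise SchemaError(f"{path}: empty file")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: expected columns {sorted(schema)}, "
            f"found {list(df.columns)} (missing {missing})")
    for col, typ in schema.items():
        if typ in (int, float):
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}: column {col} is not {typ.__name__}"
                                  ) from exc
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k))
                for k in obj.__dataclass_fields__}
    return obj


def write_report(bundle: dict, outdir: str | Path,
                 stem: str = "report") -> dict[str, Path]:
    """Write a report bundle as JSON plus any DataFrame members as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {k: v for k, v in bundle.items() if isinstance(v, pd.DataFrame)}
    for name, df in tables.items():
        p = outdir / f"{stem}_{name}.csv"
        df.to_csv(p, index=True)
        paths[name] = p
    jpath = outdir / f"{stem}.json"
    with open(jpath, "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2, default=str)
    paths["json"] = jpath
    return paths
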