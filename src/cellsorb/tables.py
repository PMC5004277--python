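"""CSV readers/writers and run-report serialisation.

CSV dialect is fixed: comma separator, ``.`` decimal point, UTF-8, header
row mandatory.  Schemas are small declarative column lists; unknown extra
columns are ignored with a warning, missing or non-numeric cells are
rejected with the offending row and column named.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["SCHEMAS", "read_table", "write_table", "write_report"]

log = logging.getLogger("cellsorb")

#: required (and known optional) columns per dataset kind
SCHEMAS: Mapping[str, dict] = {
    "equilibrium": {"required": ["C_f_mg_per_mL", "q_b_mg_per_g"],
                    "optional": ["replicate", "loading_mg_per_g"]},
    "kinetics": {"required": ["t_min", "q_obs_mg_per_g"],
                 "optional": ["replicate"]},
    "dye": {"required": ["C_residual_g_per_L", "q_dye"],
            "optional": ["replicate", "C0_g_per_L"]},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV against a named schema with strict numeric validation."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"table {path} does not exist") from None
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: header lacks required column(s) {missing}; "
                          f"found {list(df.columns)}")
    known = spec["required"] + spec["optional"]
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)
        df = df.drop(columns=extra)
    for col in [c for c in known if c in df.columns]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"data row(s) {[int(i) + 1 for i in bad[:5]]}"
            )
        df[col] = vals
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(reports: Sequence | Mapping, path: str | Path,
                 meta: Mapping | None = None) -> dict:
    """Serialise fit/simulation reports as JSON plus a readable text digest.

    ``reports`` may be a mapping of name -> report (dataclass or dict) or a
    sequence of such pairs.  ``meta`` (seed, solver settings, config hash,
    package version ...) is stored alongside under ``"meta"``.  Returns the
    JSON-ready payload.  The text digest lands next to the JSON file with a
    ``.txt`` suffix.
    """
    from . import __version__

    if isinstance(reports, Mapping):
        items = list(reports.items())
    else:
        items = list(reports)
    payload = {"meta": {"package": "cellsorb", "version": __version__,
                        **_jsonable(dict(meta or {}))},
               "reports": {str(k): _jsonable(v) for k, v in items}}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    lines = [f"cellsorb {__version__} run report"]
    for k, v in payload["meta"].items():
        if k not in ("package", "version"):
            lines.append(f"  {k}: {v}")
    for name, rep in payload["reports"].items():
        lines.append(f"\n[{name}]")
        if isinstance(rep, dict):
            for k, v in rep.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {rep}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return payload
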