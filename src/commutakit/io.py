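"""CSV and JSON interfaces for the four input kinds and the reports.

All tabular files are plain CSV with a header row; concentrations are
mg/dL throughout.  Schemas:

- homogeneity: material_id, vial_id, replicate_index, value_mg_dl
- stability:   material_id, day, vial_id, value_mg_dl
- pairs:       sample_id, x_value, y_value
- materials:   material_id, method, replicate_index, value
- pt results:  scheme_id, material_id, meter_group, participant_id,
               value_mg_dl
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (PairedSampleSet, PTResultSet, ReplicateTable,
                        StabilitySeries)

__all__ = [
    "read_replicate_tables", "read_stability_series", "read_paired_samples",
    "read_material_replicates", "read_pt_results", "write_csv",
    "write_json_report",
]

_SCHEMAS = {
    "homogeneity": ["material_id", "vial_id", "replicate_index",
                    "value_mg_dl"],
    "stability": ["material_id", "day", "vial_id", "value_mg_dl"],
    "pairs": ["sample_id", "x_value", "y_value"],
    "materials": ["material_id", "method", "replicate_index", "value"],
    "pt": ["scheme_id", "material_id", "meter_group", "participant_id",
           "value_mg_dl"],
}


def _load(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing} for a {kind} file "
            f"(expected {_SCHEMAS[kind]})")
    return df


def read_replicate_tables(path) -> list[ReplicateTable]:
    """All homogeneity tables in the file, one per material."""
    df = _load(path, "homogeneity")
    return [ReplicateTable.from_frame(df, m)
            for m in df["material_id"].unique()]


def read_stability_series(path) -> list[StabilitySeries]:
    df = _load(path, "stability")
    return [StabilitySeries.from_frame(df, m)
            for m in df["material_id"].unique()]


def read_paired_samples(path, **kw) -> PairedSampleSet:
    return PairedSampleSet.from_frame(_load(path, "pairs"), **kw)


def read_material_replicates(path) -> pd.DataFrame:
    """Tidy material x method replicate frame for characterisation."""
    return _load(path, "materials")


def read_pt_results(path) -> list[PTResultSet]:
    df = _load(path, "pt")
    keys = ["scheme_id", "material_id", "meter_group"]
    return [PTResultSet.from_frame(grp) for _, grp in df.groupby(keys)]


def write_csv(df: pd.DataFrame, path) -> Path:
    """Deterministic CSV write (fixed column order, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj or obj in
                                   (float("inf"), float("-inf"))):
        return str(obj)
    return obj


def write_json_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=2,
                               sort_keys=True) + "\n")
    return path
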