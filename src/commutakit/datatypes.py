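"""Core containers for material-qualification data.

All concentrations are in mg/dL throughout the package.  The containers
validate their structural invariants on construction; statistical
preconditions (balance, minimum replication) are checked by the models
that consume them, so a table can be loaded first and criticised later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: grams-per-mole based conversion factor between mg/dL and mmol/L glucose.
MGDL_PER_MMOLL = 18.016


def mgdl_to_mmoll(value_mgdl: float) -> float:
    """Convert a glucose concentration from mg/dL to mmol/L."""
    return value_mgdl / MGDL_PER_MMOLL


def mmoll_to_mgdl(value_mmoll: float) -> float:
    """Convert a glucose concentration from mmol/L to mg/dL."""
    return value_mmoll * MGDL_PER_MMOLL


@dataclass(frozen=True)
class ReplicateTable:
    """Vial-structured replicate measurements for a homogeneity study.

    Parameters
    ----------
    material_id : str
        Identifier of the batch under test.
    rows : sequence of (vial_id, values)
        One entry per vial; ``values`` are the replicate concentrations
        in mg/dL.
    """

    material_id: str
    rows: tuple[tuple[str, tuple[float, ...]], ...]
    units: str = "mg/dL"

    def __init__(self, material_id: str,
                 rows: Sequence[tuple[str, Sequence[float]]],
                 units: str = "mg/dL"):
        object.__setattr__(self, "material_id", str(material_id))
        frozen = tuple((str(v), tuple(float(x) for x in vals))
                       for v, vals in rows)
        object.__setattr__(self, "rows", frozen)
        object.__setattr__(self, "units", units)
        if len(frozen) < 2:
            raise ValueError("a replicate table needs at least 2 vials")
        for vial, vals in frozen:
            if len(vals) < 1:
                raise ValueError(f"vial {vial!r} has no replicates")
            if any(x <= 0 for x in vals):
                raise ValueError(f"vial {vial!r} has non-positive values")

    @property
    def n_vials(self) -> int:
        return len(self.rows)

    @property
    def replicate_counts(self) -> tuple[int, ...]:
        return tuple(len(vals) for _, vals in self.rows)

    @property
    def is_balanced(self) -> bool:
        counts = self.replicate_counts
        return len(set(counts)) == 1

    def values(self) -> np.ndarray:
        """All measurements as a flat array (vial-major order)."""
        return np.concatenate([np.asarray(v, float) for _, v in self.rows])

    def value_matrix(self) -> np.ndarray:
        """(a, n) matrix for a balanced design; raises if unbalanced."""
        if not self.is_balanced:
            bad = self._unbalanced_vial()
            raise ValueError(
                f"unbalanced replicate table: vial {bad!r} breaks balance")
        return np.array([v for _, v in self.rows], float)

    def _unbalanced_vial(self) -> str:
        from collections import Counter
        counts = Counter(self.replicate_counts)
        majority = counts.most_common(1)[0][0]
        for vial, vals in self.rows:
            if len(vals) != majority:
                return vial
        return self.rows[0][0]

    def drop_vials(self, vial_ids: Sequence[str]) -> "ReplicateTable":
        drop = set(vial_ids)
        kept = [(v, vals) for v, vals in self.rows if v not in drop]
        return ReplicateTable(self.material_id, kept, self.units)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"material_id": self.material_id, "vial_id": vial,
             "replicate_index": i + 1, "value_mg_dl": x}
            for vial, vals in self.rows for i, x in enumerate(vals)
        ]
        return pd.DataFrame.from_records(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   material_id: str | None = None) -> "ReplicateTable":
        if material_id is not None:
            df = df[df["material_id"] == material_id]
        elif df["material_id"].nunique() == 1:
            material_id = str(df["material_id"].iloc[0])
        else:
            raise ValueError("frame holds several materials; pass material_id")
        rows = []
        for vial, grp in df.groupby("vial_id", sort=False):
            grp = grp.sort_values("replicate_index")
            rows.append((str(vial), grp["value_mg_dl"].tolist()))
        return cls(material_id, rows)


@dataclass(frozen=True)
class StabilitySeries:
    """Time-stamped stability measurements, (day, vial, value) records."""

    material_id: str
    records: tuple[tuple[float, str, float], ...]
    storage_conditions: str = ""

    def __init__(self, material_id: str,
                 records: Sequence[tuple[float, str, float]],
                 storage_conditions: str = ""):
        object.__setattr__(self, "material_id", str(material_id))
        canon = tuple(sorted(((float(d), str(v), float(x))
                              for d, v, x in records),
                             key=lambda r: (r[0], r[1])))
        object.__setattr__(self, "records", canon)
        object.__setattr__(self, "storage_conditions", storage_conditions)
        if len({d for d, _, _ in canon}) < 2:
            raise ValueError("stability series needs >= 2 distinct days")
        if any(d < 0 for d, _, _ in canon):
            raise ValueError("days must be nonnegative")
        if any(x <= 0 for _, _, x in canon):
            raise ValueError("values must be positive")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(sorted({d for d, _, _ in self.records}))

    def window(self, day_set: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """(days, values) arrays restricted to the given checkpoint days."""
        keep = set(float(d) for d in day_set)
        pts = [(d, x) for d, _, x in self.records if d in keep]
        t = np.array([d for d, _ in pts], float)
        y = np.array([x for _, x in pts], float)
        return t, y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"material_id": self.material_id, "day": d, "vial_id": v,
              "value_mg_dl": x} for d, v, x in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   material_id: str | None = None) -> "StabilitySeries":
        if material_id is not None:
            df = df[df["material_id"] == material_id]
        elif df["material_id"].nunique() == 1:
            material_id = str(df["material_id"].iloc[0])
        else:
            raise ValueError("frame holds several materials; pass material_id")
        recs = list(zip(df["day"].astype(float),
                        df["vial_id"].astype(str),
                        df["value_mg_dl"].astype(float)))
        return cls(material_id, recs)


@dataclass(frozen=True)
class PairedSampleSet:
    """Native clinical samples measured by a reference and a field method."""

    samples: tuple[tuple[str, float, float], ...]
    x_method: str = "reference"
    y_method: str = "field"

    def __init__(self, samples: Sequence[tuple[str, float, float]],
                 x_method: str = "reference", y_method: str = "field"):
        canon = tuple((str(s), float(x), float(y)) for s, x, y in samples)
        object.__setattr__(self, "samples", canon)
        object.__setattr__(self, "x_method", x_method)
        object.__setattr__(self, "y_method", y_method)
        if any(x <= 0 or y <= 0 for _, x, y in canon):
            raise ValueError("paired values must be positive")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def x(self) -> np.ndarray:
        return np.array([x for _, x, _ in self.samples], float)

    @property
    def y(self) -> np.ndarray:
        return np.array([y for _, _, y in self.samples], float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples,
                            columns=["sample_id", "x_value", "y_value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "PairedSampleSet":
        return cls(list(zip(df["sample_id"].astype(str),
                            df["x_value"].astype(float),
                            df["y_value"].astype(float))), **kw)


@dataclass(frozen=True)
class MaterialPoint:
    """Candidate material characterised by both methods (mean, SD)."""

    material_id: str
    x_mean: float
    x_sd: float
    y_mean: float
    y_sd: float
    x_n: int = 0
    y_n: int = 0

    def __post_init__(self):
        if self.x_mean <= 0 or self.y_mean <= 0:
            raise ValueError("material means must be positive")
        if self.x_sd < 0 or self.y_sd < 0:
            raise ValueError("material SDs must be nonnegative")


@dataclass(frozen=True)
class PTResultSet:
    """Proficiency-testing results for one meter group on one material."""

    scheme_id: str
    material_id: str
    meter_group: str
    results: tuple[tuple[str, float], ...]

    def __init__(self, scheme_id: str, material_id: str, meter_group: str,
                 results: Sequence[tuple[str, float]]):
        canon = tuple((str(p), float(v)) for p, v in results)
        object.__setattr__(self, "scheme_id", str(scheme_id))
        object.__setattr__(self, "material_id", str(material_id))
        object.__setattr__(self, "meter_group", str(meter_group))
        object.__setattr__(self, "results", canon)
        if len(canon) < 1:
            raise ValueError("result set is empty")
        if any(v <= 0 for _, v in canon):
            raise ValueError("participant values must be positive")
        ids = [p for p, _ in canon]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant_id in result set")

    @property
    def n(self) -> int:
        return len(self.results)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.results], float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"scheme_id": self.scheme_id, "material_id": self.material_id,
              "meter_group": self.meter_group, "participant_id": p,
              "value_mg_dl": v} for p, v in self.results])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PTResultSet":
        for col in ("scheme_id", "material_id", "meter_group"):
            if df[col].nunique() != 1:
                raise ValueError(f"frame mixes several values of {col}")
        return cls(df["scheme_id"].iloc[0], df["material_id"].iloc[0],
                   df["meter_group"].iloc[0],
                   list(zip(df["participant_id"].astype(str),
                            df["value_mg_dl"].astype(float))))


@dataclass(frozen=True)
class TargetSpec:
    """Scoring target: assigned reference value or robust consensus."""

    source: str  # "reference" | "consensus"
    value: float
    sd: float = 0.0

    def __post_init__(self):
        if self.source not in ("reference", "consensus"):
            raise ValueError("source must be 'reference' or 'consensus'")
        if self.value <= 0:
            raise ValueError("target value must be positive")
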