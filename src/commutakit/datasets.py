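"""Bundled example data from a glucose-meter commutability study.

Two processed blood materials (BG62-001 at a hyperglycaemic level,
BG62-002 near the diagnostic threshold) were characterised by a
mass-spectrometry reference method and five point-of-care glucose
meters of different chemistries; the same materials were then used as
proficiency-testing items for two large meter groups.  The printed
characterisation means/SDs and satisfaction tallies are reproduced here
so the reporting paths (mean differences, compatibility letters,
percentage formatting) can be exercised on realistic numbers without
any download.

Values are summary statistics, not raw measurements: the replicate-
level data behind them are not public.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import MaterialPoint

__all__ = [
    "example_characterization", "example_material_points",
    "example_pt_tallies", "EXAMPLE_REFERENCE_METHOD",
]

EXAMPLE_REFERENCE_METHOD = "LC-ID-MS/MS"

# method -> {material_id: (mean mg/dL, SD mg/dL)}
_CHARACTERIZATION: dict[str, dict[str, tuple[float, float]]] = {
    "LC-ID-MS/MS": {"BG62-001": (154.0, 0.9), "BG62-002": (106.0, 1.4)},
    "meter1_Amp-GDH-PQQ": {"BG62-001": (147.0, 1.7),
                           "BG62-002": (92.0, 1.2)},
    "meter2_Amp-GDH-FAD": {"BG62-001": (136.0, 4.4),
                           "BG62-002": (88.0, 2.7)},
    "meter3_Amp-GOD": {"BG62-001": (179.0, 6.7), "BG62-002": (111.0, 8.2)},
    "meter4_Pho-GOD": {"BG62-001": (153.0, 7.8), "BG62-002": (109.0, 2.9)},
    "meter5_Amp-GDH-FAD": {"BG62-001": (123.0, 3.2),
                           "BG62-002": (71.0, 2.7)},
}

# (material_id, meter_group, n, n_satisfied_reference,
#  n_satisfied_consensus, value_range)
_PT_TALLIES = [
    ("BG62-001", "meter1_Amp-GDH-PQQ", 767, 761, 761, (79.0, 157.0)),
    ("BG62-001", "meter2_Amp-GDH-FAD", 266, 17, 266, (113.0, 138.0)),
    ("BG62-002", "meter1_Amp-GDH-PQQ", 743, 741, 739, (91.0, 127.0)),
    ("BG62-002", "meter2_Amp-GDH-FAD", 246, 112, 245, (79.0, 109.0)),
]


def example_characterization() -> pd.DataFrame:
    """Characterisation table: one row per method x material."""
    rows = [
        {"method": method, "material_id": mat, "mean": m, "sd": s}
        for method, mats in _CHARACTERIZATION.items()
        for mat, (m, s) in mats.items()
    ]
    return pd.DataFrame(rows)


def example_material_points(
    reference_method: str = EXAMPLE_REFERENCE_METHOD,
) -> dict[str, list[MaterialPoint]]:
    """Material points per field method, paired against the reference.

    Returns a mapping ``method -> [MaterialPoint, ...]`` covering the
    ten method x material pairs of the study.
    """
    ref = _CHARACTERIZATION[reference_method]
    out: dict[str, list[MaterialPoint]] = {}
    for method, mats in _CHARACTERIZATION.items():
        if method == reference_method:
            continue
        pts = []
        for mat, (ym, ys) in sorted(mats.items()):
            xm, xs = ref[mat]
            pts.append(MaterialPoint(material_id=mat, x_mean=xm, x_sd=xs,
                                     y_mean=ym, y_sd=ys))
        out[method] = pts
    return out


def example_pt_tallies() -> pd.DataFrame:
    """Proficiency-testing satisfaction tallies per meter group."""
    rows = [
        {"material_id": mat, "meter_group": grp, "n": n,
         "n_satisfied_reference": n_ref, "n_satisfied_consensus": n_con,
         "range_low": lo, "range_high": hi}
        for mat, grp, n, n_ref, n_con, (lo, hi) in _PT_TALLIES
    ]
    return pd.DataFrame(rows)
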