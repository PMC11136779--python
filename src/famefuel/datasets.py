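"""Bundled reference datasets.

The package ships a transcription of a published heavy-metal-stress study on
*Chlorella vulgaris*: the fatty-acid profiles of 11 cultures (untreated
control plus Zn/Co/Mn doses), the class totals and predicted fuel properties
as printed there, and the per-treatment carbohydrate/lipid yields.  Cells
that are garbled or internally inconsistent in the source are transcribed
as-is, flagged ``low_confidence`` with a note, and the printed class-total
rows are kept alongside the per-acid values (they disagree for a few
columns; the printed rows are treated as authoritative where downstream
printed values follow them).

Carbohydrate yields are numeric only for the cultures whose values the
source states in text (including both per-compound extremes); the rest are
figure-only and left missing.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .fame_profile import ClassTotals, FAProfile, read_profiles
from .reec import EnergyYields

__all__ = [
    "load_table1_profiles",
    "load_table1_class_totals",
    "load_table2_properties",
    "load_energy_yields",
    "SAMPLE_ORDER",
]

SAMPLE_ORDER = [
    "control",
    "Zn-0.2", "Zn-0.4", "Zn-0.6", "Zn-0.8",
    "Co-1", "Co-2", "Co-3",
    "Mn-2", "Mn-4", "Mn-6",
]


def _data_text(name: str) -> str:
    return resources.files("famefuel").joinpath(f"data/{name}").read_text()


def load_table1_class_totals() -> pd.DataFrame:
    """Printed class-total rows (sum SFA/MUFA/PUFA/TFA) with flags."""
    return pd.read_csv(io.StringIO(_data_text("table1_class_totals.csv")))


def load_table1_profiles() -> list[FAProfile]:
    """The 11 reference profiles, with printed class totals attached."""
    profiles = read_profiles(io.StringIO(_data_text("table1_profiles.csv")))
    totals = load_table1_class_totals().set_index("sample_id")
    for p in profiles:
        row = totals.loc[p.sample_id]
        p.reported_totals = ClassTotals(
            sfa=float(row["sfa"]), mufa=float(row["mufa"]), pufa=float(row["pufa"])
        )
        p.low_confidence = bool(row["low_confidence"])
        p.provenance = str(row["note"] or "")
    order = {s: i for i, s in enumerate(SAMPLE_ORDER)}
    return sorted(profiles, key=lambda p: order[p.sample_id])


def load_table2_properties() -> pd.DataFrame:
    """Fuel properties as printed in the source (one row per culture)."""
    df = pd.read_csv(io.StringIO(_data_text("table2_properties.csv")))
    return df.set_index("sample_id").loc[SAMPLE_ORDER].reset_index()


def load_energy_yields() -> list[EnergyYields]:
    """Per-treatment carbohydrate and lipid yields, mg per g CDW."""
    df = pd.read_csv(io.StringIO(_data_text("energy_yields.csv")))
    out = []
    for _, r in df.iterrows():
        carb = None if pd.isna(r["carbohydrate"]) else float(r["carbohydrate"])
        lip = None if pd.isna(r["lipid"]) else float(r["lipid"])
        out.append(
            EnergyYields(
                treatment=str(r["treatment"]),
                carbohydrate=carb,
                lipid=lip,
                is_control=bool(r["is_control"]),
            )
        )
    return out


def load_energy_yields_frame() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(_data_text("energy_yields.csv")))
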