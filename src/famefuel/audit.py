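"""Internal-consistency audit of a printed property table.

Literature tables of predicted fuel properties are not always reproducible
from their own inputs: some cells follow the stated equations, others do not
(typos, silent renormalizations, stale intermediate values).  Rather than
curve-fitting to such a table, this audit recomputes every cell from its
*authoritative upstream inputs* and flags the deviations:

* base properties (SV, IV, DU, LCSF, CP, PP, FP) are recomputed from the
  fatty-acid profile — DU from the table's printed class totals when the
  profile carries them, since printed DU values follow the printed sums;
* chained properties are checked against the equation applied to the printed
  value of their own upstream column: CN from the printed SV/IV, CFPP from
  the printed LCSF, OS from the printed DU.

A cell is flagged when |recomputed - printed| exceeds a per-property
tolerance sized to cover transcription rounding but not genuine
inconsistency.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .fame_profile import FAProfile
from . import fuel_properties as fp

__all__ = ["audit_table", "DEFAULT_TOLERANCES"]

#: absolute tolerance unless the value is a ("rel", fraction) pair
DEFAULT_TOLERANCES: dict[str, object] = {
    "SV": ("rel", 0.005),
    "IV": ("rel", 0.005),
    "CN": 0.5,
    "DU": 0.25,
    "LCSF": 0.25,
    "CFPP": 0.25,
    "CP": 0.25,
    "PP": 0.25,
    "OS": 0.05,
    "FP": 1.0,
}


def _within(printed: float, recomputed: float, tol: object) -> bool:
    if isinstance(tol, tuple):
        _, frac = tol
        return abs(recomputed - printed) <= abs(printed) * frac
    return abs(recomputed - printed) <= float(tol)


def audit_table(
    profiles: Iterable[FAProfile],
    reference: pd.DataFrame,
    tolerances: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Audit a printed property table against recomputation.

    ``reference`` needs a ``sample_id`` column plus the standard property
    columns.  Returns one row per (sample, property) with the printed value,
    the recomputed one, the basis of the recomputation, and a ``flagged``
    boolean.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    ref = reference.set_index("sample_id")
    rows = []
    for profile in profiles:
        if profile.sample_id not in ref.index:
            continue
        printed = ref.loc[profile.sample_id]
        engine = fp.predict_all(profile, use_reported_totals=True)

        recomputed = {
            "SV": (engine.sv, "profile"),
            "IV": (engine.iv, "profile"),
            "DU": (engine.du, "printed class totals"),
            "LCSF": (engine.lcsf, "profile"),
            "CP": (engine.cp, "profile"),
            "PP": (engine.pp, "profile"),
            "FP": (engine.fp, "profile"),
            "CN": (
                fp.compute_cn(float(printed["SV"]), float(printed["IV"])),
                "printed SV/IV",
            ),
            "CFPP": (fp.compute_cfpp(float(printed["LCSF"])), "printed LCSF"),
            "OS": (fp.compute_os(float(printed["DU"])), "printed DU"),
        }
        for prop in fp.PROPERTY_COLUMNS:
            value, basis = recomputed[prop]
            pv = float(printed[prop])
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "property": prop,
                    "printed": pv,
                    "recomputed": value,
                    "deviation": value - pv,
                    "basis": basis,
                    "flagged": not _within(pv, value, tol[prop]),
                }
            )
    return pd.DataFrame(rows)
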