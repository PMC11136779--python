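"""Relative increase in energy compounds (REEC) — ranking treatments.

A stress treatment is worth applying only if it raises the energy content of
the biomass.  REEC scores each treatment by the relative gains of its two
energy compounds over the worst-performing treated culture:

    REEC (%) = [ (P_H - P_L)/P_L |carb  +  (P_H - P_L)/P_L |lipid ] * 100

where P_H is the treatment's own productivity of the compound and P_L the
lowest productivity recorded among the *treated* cultures (the control is
scored but excluded from the baseline minima).  The score is unit-free:
rescaling all carbohydrate yields, or all lipid yields, by a common factor
leaves every score unchanged, so mg/g CDW and % DW inputs are equivalent —
as long as one dataset does not mix them.

Source tables sometimes print a compound's yield for only a subset of
treatments (the rest living in a figure); a missing carbohydrate or lipid is
therefore allowed, excluded from the baseline minima, and makes that
treatment's score undefined rather than wrong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EnergyYields",
    "REECResult",
    "compute_reec",
    "rank_treatments",
    "reec_table",
    "REECError",
]


class REECError(ValueError):
    """Invalid yields or degenerate baseline."""


@dataclass(frozen=True)
class EnergyYields:
    """Per-treatment carbohydrate and lipid yields (mass per g cell dry
    weight).  ``None`` marks a yield the source does not report numerically."""

    treatment: str
    carbohydrate: float | None
    lipid: float | None
    is_control: bool = False

    def __post_init__(self) -> None:
        for name in ("carbohydrate", "lipid"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise REECError(f"{self.treatment}: {name} must be > 0, got {v}")


@dataclass(frozen=True)
class REECResult:
    treatment: str
    carb_term: float | None
    lipid_term: float | None
    reec_percent: float | None
    baseline: tuple[str, str]  # (lowest-carb treatment, lowest-lipid treatment)

    @property
    def reec_thousands(self) -> float | None:
        """The score in the x10^3 % presentation."""
        return None if self.reec_percent is None else self.reec_percent / 1000.0


def _baseline(values: list[tuple[str, float]], compound: str) -> tuple[str, float]:
    if len(values) < 2:
        raise REECError(
            f"need >= 2 treated cultures with a {compound} yield to set a baseline"
        )
    label, low = min(values, key=lambda kv: kv[1])
    return label, low


def compute_reec(yields: Sequence[EnergyYields]) -> list[REECResult]:
    """Score every culture by REEC.

    Baselines are the per-compound minima over treated (non-control) cultures
    with a reported value; the control is excluded from the minima but still
    scored.  A culture missing either compound gets an undefined score
    (``None`` terms propagate), never a fabricated one.
    """
    treated_carb = [
        (y.treatment, y.carbohydrate)
        for y in yields
        if not y.is_control and y.carbohydrate is not None
    ]
    treated_lip = [
        (y.treatment, y.lipid) for y in yields if not y.is_control and y.lipid is not None
    ]
    carb_label, carb_low = _baseline(treated_carb, "carbohydrate")
    lip_label, lip_low = _baseline(treated_lip, "lipid")

    results = []
    for y in yields:
        carb_term = (
            None
            if y.carbohydrate is None
            else (y.carbohydrate - carb_low) / carb_low
        )
        lipid_term = None if y.lipid is None else (y.lipid - lip_low) / lip_low
        reec = (
            None
            if carb_term is None or lipid_term is None
            else (carb_term + lipid_term) * 100.0
        )
        results.append(
            REECResult(
                treatment=y.treatment,
                carb_term=carb_term,
                lipid_term=lipid_term,
                reec_percent=reec,
                baseline=(carb_label, lip_label),
            )
        )
    return results


def rank_treatments(results: Iterable[REECResult]) -> list[REECResult]:
    """Descending by score; ties broken by lipid term, then label.

    Cultures with an undefined score sort last (alphabetically), so the
    ranking is a permutation of the input regardless of input order.
    """
    def key(r: REECResult):
        defined = r.reec_percent is not None
        return (
            0 if defined else 1,
            -(r.reec_percent or 0.0),
            -(r.lipid_term or 0.0),
            r.treatment,
        )

    return sorted(results, key=key)


def reec_table(results: Iterable[REECResult], thousands: bool = False) -> pd.DataFrame:
    """Ranked results as a DataFrame; ``thousands`` switches the score to the
    x10^3 % presentation some reports use."""
    rows = []
    for r in rank_treatments(results):
        rows.append(
            {
                "treatment": r.treatment,
                "carb_term": r.carb_term,
                "lipid_term": r.lipid_term,
                ("reec_x1000_percent" if thousands else "reec_percent"): (
                    r.reec_thousands if thousands else r.reec_percent
                ),
                "carb_baseline": r.baseline[0],
                "lipid_baseline": r.baseline[1],
            }
        )
    return pd.DataFrame(rows)
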