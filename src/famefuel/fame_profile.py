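"""Fatty-acid profiles: shorthand parsing, the profile container, and I/O.

A fatty acid is written in the standard ``Cx:y n-z`` shorthand: ``x`` carbons,
``y`` double bonds, and (optionally) the position ``z`` of the first double
bond counted from the methyl end.  A profile maps fatty acids to their percent
of total fatty acids (percent of total FAME peak area), the form in which
GC-MS composition tables are reported.  Acids reported as "ND" (not detected)
are treated as exactly zero and carry no entry in the composition map.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FattyAcid",
    "FAProfile",
    "ClassTotals",
    "Treatment",
    "ProfileError",
    "parse_fatty_acid",
    "read_profiles",
    "write_profiles",
    "class_totals",
    "normalize_peak_areas",
]

#: Percent values below which an acid counts as absent when writing tables.
ND_VALUES = {"", "ND", "nd", "n.d.", "NA", "na", None}

#: Profiles may overshoot 100 % by at most this much (printed tables round).
TFA_SLACK = 0.5


class ProfileError(ValueError):
    """Malformed shorthand, table, or profile."""


_SHORTHAND = re.compile(
    r"^\s*[Cc]\s*(?P<carbons>\d+)\s*:\s*(?P<bonds>\d+)"
    r"(?:\s*n\s*-\s*(?P<omega>\d+))?\s*$"
)


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A fatty-acid species identified by chain length and unsaturation.

    ``omega`` is descriptive metadata (double-bond position from the methyl
    end); it never enters any property equation.  Saturation class is a pure
    function of ``double_bonds``.
    """

    carbons: int
    double_bonds: int
    omega: int | None = None
    common_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ProfileError(f"carbons must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise ProfileError(f"double_bonds must be >= 0, got {self.double_bonds}")
        if self.omega is not None:
            if self.double_bonds == 0:
                raise ProfileError(
                    f"C{self.carbons}:0 is saturated and cannot carry an "
                    f"omega position (got n-{self.omega})"
                )
            if self.omega <= 0:
                raise ProfileError(f"omega must be positive, got {self.omega}")

    @property
    def shorthand(self) -> str:
        """Canonical ``Cx:y`` / ``Cx:y n-z`` notation."""
        base = f"C{self.carbons}:{self.double_bonds}"
        return f"{base} n-{self.omega}" if self.omega is not None else base

    @property
    def saturation_class(self) -> str:
        """SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
        if self.double_bonds == 0:
            return "SFA"
        return "MUFA" if self.double_bonds == 1 else "PUFA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.shorthand


def parse_fatty_acid(shorthand: str) -> FattyAcid:
    """Parse ``Cx:y [n-z]`` shorthand into a :class:`FattyAcid`.

    Whitespace-tolerant and case-insensitive in the leading ``C``.  Raises
    :class:`ProfileError` naming the offending token on malformed input or
    when an omega position is given for a saturated acid.
    """
    if not isinstance(shorthand, str):
        raise ProfileError(f"expected shorthand text, got {shorthand!r}")
    m = _SHORTHAND.match(shorthand)
    if m is None:
        raise ProfileError(f"cannot parse fatty-acid shorthand {shorthand!r}")
    omega = m.group("omega")
    return FattyAcid(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("bonds")),
        omega=int(omega) if omega is not None else None,
    )


@dataclass(frozen=True)
class ClassTotals:
    """Per-class percent sums.  ``tfa`` is their grand total by construction."""

    sfa: float = 0.0
    mufa: float = 0.0
    pufa: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sfa", "mufa", "pufa"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} total must be >= 0")

    @property
    def tfa(self) -> float:
        return self.sfa + self.mufa + self.pufa


@dataclass(frozen=True)
class Treatment:
    """Heavy-metal treatment applied to a culture (``none`` for the control)."""

    metal: str = "none"
    dose: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.metal not in {"Mn", "Co", "Zn", "none"}:
            raise ProfileError(f"unknown metal {self.metal!r}")


@dataclass
class FAProfile:
    """One culture's fatty-acid composition.

    ``composition`` maps :class:`FattyAcid` to percent of total fatty acids;
    absent acids are exactly zero.  ``reported_totals`` optionally carries
    class totals as printed in the source table, which may differ from the
    re-summed composition when the source itself is internally inconsistent
    (see ``provenance``).
    """

    sample_id: str
    composition: dict[FattyAcid, float]
    treatment: Treatment | None = None
    reported_totals: ClassTotals | None = None
    provenance: str = ""
    low_confidence: bool = False

    def __post_init__(self) -> None:
        for acid, pct in self.composition.items():
            if pct < 0:
                raise ProfileError(
                    f"{self.sample_id}: negative percent {pct} for {acid.shorthand}"
                )
        tfa = sum(self.composition.values())
        if tfa > 100.0 + TFA_SLACK:
            raise ProfileError(
                f"{self.sample_id}: total fatty acids {tfa:.2f} exceeds 100 %"
            )

    def percent(self, shorthand_or_acid: str | FattyAcid) -> float:
        """Percent of one acid; 0.0 when absent."""
        acid = (
            parse_fatty_acid(shorthand_or_acid)
            if isinstance(shorthand_or_acid, str)
            else shorthand_or_acid
        )
        return self.composition.get(acid, 0.0)

    def percent_of_species(self, carbons: int, double_bonds: int) -> float:
        """Total percent of all acids with the given chain/unsaturation,
        summed across omega isomers."""
        return sum(
            pct
            for acid, pct in self.composition.items()
            if acid.carbons == carbons and acid.double_bonds == double_bonds
        )

    def totals(self, reported: bool = False) -> ClassTotals:
        """Class totals; ``reported=True`` prefers the printed totals when
        the profile carries them."""
        if reported and self.reported_totals is not None:
            return self.reported_totals
        return class_totals(self)


def class_totals(profile: FAProfile) -> ClassTotals:
    """Sum the composition by saturation class (always recomputed)."""
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for acid, pct in profile.composition.items():
        sums[acid.saturation_class] += pct
    return ClassTotals(sfa=sums["SFA"], mufa=sums["MUFA"], pufa=sums["PUFA"])


def normalize_peak_areas(
    areas: Mapping[FattyAcid | str, float], sample_id: str = "sample"
) -> FAProfile:
    """Turn integrated peak areas into a percent-of-total profile.

    Each percent is ``100 * area / total_area``, so the result always sums to
    exactly 100 (scale-invariant in the areas).  All-zero input is an error.
    """
    parsed: dict[FattyAcid, float] = {}
    for key, area in areas.items():
        acid = parse_fatty_acid(key) if isinstance(key, str) else key
        if area < 0:
            raise ProfileError(f"negative peak area {area} for {acid.shorthand}")
        parsed[acid] = parsed.get(acid, 0.0) + float(area)
    total = sum(parsed.values())
    if total <= 0:
        raise ProfileError("all peak areas are zero; cannot normalize")
    composition = {a: 100.0 * v / total for a, v in parsed.items() if v > 0}
    return FAProfile(sample_id=sample_id, composition=composition)


def _treatment_from_row(row: pd.Series) -> Treatment | None:
    metal = str(row.get("metal", "") or "").strip()
    if not metal:
        return None
    dose_raw = row.get("dose", "")
    dose = None
    if dose_raw not in ND_VALUES and not pd.isna(dose_raw):
        try:
            dose = float(dose_raw)
        except (TypeError, ValueError):
            dose = None
    return Treatment(metal=metal, dose=dose, unit=str(row.get("dose_unit", "") or ""))


def read_profiles(source: str | Path | io.IOBase) -> list[FAProfile]:
    """Read long-format profiles (``sample_id, fatty_acid, percent``).

    Comma- or tab-delimited UTF-8 with a header row.  "ND", empty, or missing
    percents mean zero and are omitted from the composition.  Duplicate
    (sample, acid) rows and negative or unparseable entries raise
    :class:`ProfileError` with the offending row number.  Unknown columns are
    tolerated; ``metal``/``dose``/``dose_unit`` columns populate the
    treatment.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = {"sample_id", "fatty_acid", "percent"}
    missing = required - set(df.columns)
    if missing:
        raise ProfileError(f"missing required column(s): {sorted(missing)}")

    profiles: dict[str, dict[FattyAcid, float]] = {}
    treatments: dict[str, Treatment | None] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sample = str(row["sample_id"]).strip()
        if not sample:
            raise ProfileError(f"row {line}: empty sample_id")
        try:
            acid = parse_fatty_acid(row["fatty_acid"])
        except ProfileError as exc:
            raise ProfileError(f"row {line}: {exc}") from exc
        raw = str(row["percent"]).strip()
        pct = 0.0 if raw in ND_VALUES else None
        if pct is None:
            try:
                pct = float(raw)
            except ValueError:
                raise ProfileError(f"row {line}: unreadable percent {raw!r}") from None
        if pct < 0:
            raise ProfileError(f"row {line}: negative percent {pct}")
        comp = profiles.setdefault(sample, {})
        if acid in comp:
            raise ProfileError(
                f"row {line}: duplicate entry for {acid.shorthand} in sample {sample!r}"
            )
        if pct > 0:
            comp[acid] = pct
        else:
            comp.setdefault(acid, 0.0)  # remember the key to catch duplicates
        treatments.setdefault(sample, _treatment_from_row(row))

    out = []
    for sample, comp in profiles.items():
        comp = {a: v for a, v in comp.items() if v > 0}
        out.append(
            FAProfile(sample_id=sample, composition=comp, treatment=treatments[sample])
        )
    return out


def write_profiles(profiles: Iterable[FAProfile], path: str | Path) -> None:
    """Write profiles in the same long format :func:`read_profiles` accepts."""
    rows = []
    for p in profiles:
        t = p.treatment or Treatment()
        for acid in sorted(p.composition):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "metal": t.metal,
                    "dose": "" if t.dose is None else t.dose,
                    "dose_unit": t.unit,
                    "fatty_acid": acid.shorthand,
                    "percent": p.composition[acid],
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "metal", "dose", "dose_unit", "fatty_acid", "percent"]
    ).to_csv(path, index=False)


def merge_compositions(
    parts: Iterable[Mapping[FattyAcid, float]]
) -> dict[FattyAcid, float]:
    """Element-wise sum of several composition maps (test/oracle helper)."""
    merged: dict[FattyAcid, float] = {}
    for part in parts:
        for acid, pct in part.items():
            merged[acid] = merged.get(acid, 0.0) + pct
    return merged
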