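"""Biodiesel standard limits and compliance grading.

Encodes the property limits of the European (EN 14214), American (ASTM
D6751) and Indian (IS 15607) biodiesel standards — only for the properties
this package predicts — and grades a :class:`~famefuel.fuel_properties.FuelProperties`
against them.  Limits live in a versioned YAML file packaged with the code so
new standard editions can be added without code changes.

Boundary values pass: the comparators are inclusive (>= / <=), matching the
glyphs the standards print.  Cold-flow limits are seasonal; winter limits are
at least as strict as summer ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .fuel_properties import FuelProperties, PROPERTY_COLUMNS

__all__ = [
    "Limit",
    "StandardSpec",
    "ComplianceReport",
    "load_standards",
    "get_standard",
    "check_compliance",
    "compliance_matrix",
    "StandardsError",
]

SEASONS = ("summer", "winter")


class StandardsError(ValueError):
    """Unknown standard, season, or malformed limit table."""


@dataclass(frozen=True)
class Limit:
    comparator: str  # "ge" or "le"
    threshold: float | None = None
    seasonal: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.comparator not in ("ge", "le"):
            raise StandardsError(f"comparator must be ge/le, got {self.comparator!r}")
        if (self.threshold is None) == (self.seasonal is None):
            raise StandardsError("exactly one of threshold/seasonal must be set")

    def resolve(self, season: str | None) -> float:
        if self.seasonal is None:
            return float(self.threshold)  # type: ignore[arg-type]
        if season not in SEASONS:
            raise StandardsError(
                f"seasonal limit requires season in {SEASONS}, got {season!r}"
            )
        return float(self.seasonal[season])

    def passes(self, value: float, season: str | None = None) -> bool:
        t = self.resolve(season)
        return value >= t if self.comparator == "ge" else value <= t


@dataclass(frozen=True)
class StandardSpec:
    name: str
    limits: Mapping[str, Limit]
    aliases: tuple[str, ...] = ()

    def limit_for(self, prop: str) -> Limit | None:
        return self.limits.get(prop)


@dataclass(frozen=True)
class PropertyVerdict:
    prop: str
    verdict: str  # "pass" / "fail" / "not-specified"
    limit: str = ""
    value: float | None = None


@dataclass(frozen=True)
class ComplianceReport:
    sample_id: str
    standard: str
    season: str | None
    verdicts: tuple[PropertyVerdict, ...]

    @property
    def overall(self) -> str:
        """Pass iff every specified property passes."""
        return (
            "pass"
            if all(v.verdict != "fail" for v in self.verdicts)
            else "fail"
        )

    def failed_properties(self) -> list[str]:
        return [v.prop for v in self.verdicts if v.verdict == "fail"]


def _parse_limit(raw: Mapping) -> Limit:
    return Limit(
        comparator=raw["comparator"],
        threshold=raw.get("threshold"),
        seasonal=dict(raw["seasonal"]) if "seasonal" in raw else None,
    )


def load_standards(path: str | Path | None = None) -> dict[str, StandardSpec]:
    """Load the standards registry (packaged YAML unless a path is given)."""
    if path is None:
        text = (
            resources.files("famefuel").joinpath("data/standards.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    registry: dict[str, StandardSpec] = {}
    for name, entry in raw["standards"].items():
        spec = StandardSpec(
            name=name,
            limits={p: _parse_limit(l) for p, l in entry["limits"].items()},
            aliases=tuple(entry.get("aliases", ())),
        )
        registry[name] = spec
    return registry


def get_standard(name: str, registry: Mapping[str, StandardSpec] | None = None) -> StandardSpec:
    """Look a standard up by canonical name or alias (case/space tolerant)."""
    registry = registry if registry is not None else load_standards()
    key = name.replace(" ", "").upper()
    for spec in registry.values():
        candidates = {spec.name.upper(), *(a.replace(" ", "").upper() for a in spec.aliases)}
        if key in candidates:
            return spec
    raise StandardsError(f"unknown standard {name!r}")


def check_compliance(
    props: FuelProperties, spec: StandardSpec, season: str | None = None
) -> ComplianceReport:
    """Grade one property set against one standard.

    Raises :class:`StandardsError` when the standard has seasonal limits and
    no (or an unknown) season is given.
    """
    values = props.as_dict()
    verdicts = []
    for prop in PROPERTY_COLUMNS:
        limit = spec.limit_for(prop)
        if limit is None:
            verdicts.append(PropertyVerdict(prop=prop, verdict="not-specified"))
            continue
        threshold = limit.resolve(season)  # raises on missing season
        ok = limit.passes(values[prop], season)
        sign = ">=" if limit.comparator == "ge" else "<="
        verdicts.append(
            PropertyVerdict(
                prop=prop,
                verdict="pass" if ok else "fail",
                limit=f"{sign} {threshold:g}",
                value=values[prop],
            )
        )
    return ComplianceReport(
        sample_id="", standard=spec.name, season=season, verdicts=tuple(verdicts)
    )


def compliance_matrix(
    table: pd.DataFrame,
    spec: StandardSpec,
    season: str | None = None,
) -> pd.DataFrame:
    """Per-sample pass/fail matrix for a property table (sample_id + columns)."""
    rows = []
    for _, r in table.iterrows():
        props = FuelProperties(
            **{c.lower(): float(r[c.upper()]) for c in PROPERTY_COLUMNS}
        )
        report = check_compliance(props, spec, season)
        row: dict[str, object] = {"sample_id": r["sample_id"]}
        for v in report.verdicts:
            row[v.prop] = v.verdict if v.verdict != "not-specified" else "-"
        row["overall"] = report.overall
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *PROPERTY_COLUMNS, "overall"])
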