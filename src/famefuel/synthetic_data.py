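"""Seedable generator of treatment-structured FAME profiles and energy
yields, shaped like real microalgal GC-MS composition tables.

What it emulates
----------------
Sparse profiles over a panel of ~28 fatty acids dominated by a handful of
species (palmitic C16:0 among the saturates, oleic C18:1 among the
monounsaturates, linoleic C18:2 among the polyunsaturates), class totals in
the ranges observed for heavy-metal-stressed *Chlorella* cultures (SFA
roughly 45–65 %, MUFA 20–47 %, PUFA 0–17 % of total fatty acids), a grand
total at or below 100 %, and many not-detected ("ND") zeros.  Treatment
effects are phenomenological additive shifts on the class proportions —
there is no mechanistic model of metal-stress physiology here.

Sampling
--------
Class proportions are drawn from a Dirichlet centred on ``class_mix`` with
concentration ``class_concentration`` (larger = tighter around the mix);
treatment shifts are added and the result is clipped to the simplex.  Each
class's share is then split over its panel acids by a second Dirichlet whose
weights favour the dominant species, scaled to a total drawn uniformly from
``tfa_range``, and percents below ``nd_threshold`` are zeroed to mimic ND
cells.  One integer seed fixes everything bit-for-bit; per-sample substreams
are derived from it so growing ``n_samples`` never reshuffles earlier
samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .fame_profile import FAProfile, FattyAcid, Treatment, parse_fatty_acid
from .reec import EnergyYields

__all__ = ["SyntheticConfig", "generate_profiles", "generate_yields", "default_panel"]


def default_panel() -> list[FattyAcid]:
    """The 29-acid panel of the bundled reference table."""
    shorthands = [
        "C4:0", "C5:0", "C6:0", "C8:0", "C9:0", "C10:0", "C11:0", "C12:0",
        "C13:0", "C14:0", "C15:0", "C16:0", "C17:0", "C18:0", "C19:0",
        "C20:0", "C22:0", "C24:0", "C28:0", "C30:0", "C32:0",
        "C9:1", "C16:1 n-7", "C18:1 n-9", "C20:1",
        "C18:2 n-6", "C18:4 n-3", "C20:3 n-3", "C20:4 n-6",
    ]
    return [parse_fatty_acid(s) for s in shorthands]


#: within-class Dirichlet weights; heavier weight = dominant species
_DOMINANT_WEIGHTS = {
    ("SFA", 16, 0): 40.0,   # palmitic
    ("SFA", 18, 0): 10.0,   # stearic
    ("SFA", 14, 0): 3.0,
    ("MUFA", 18, 1): 40.0,  # oleic
    ("MUFA", 16, 1): 10.0,  # palmitoleic
    ("PUFA", 18, 2): 40.0,  # linoleic
    ("PUFA", 18, 4): 10.0,  # stearidonic
}
_BASE_WEIGHT = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults mirror the statistical shape of heavy-metal-stressed *Chlorella*
    composition tables: mean class mix (SFA, MUFA, PUFA) = (0.59, 0.37, 0.04)
    of total fatty acids with a spread of a few points, totals between 72 and
    100 %, and yield means at the observed carbohydrate/lipid levels (mg per
    g cell dry weight) with 5 % dispersion.
    """

    seed: int = 0
    n_samples: int = 11
    fa_panel: tuple[FattyAcid, ...] = field(default_factory=lambda: tuple(default_panel()))
    class_mix: tuple[float, float, float] = (0.59, 0.37, 0.04)
    class_concentration: float = 60.0
    within_concentration: float = 30.0
    tfa_range: tuple[float, float] = (72.0, 100.0)
    nd_threshold: float = 0.05  # percent below which an acid reads as ND
    treatment_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    yield_model: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        # treatment -> compound -> (mean, coefficient of variation)
        default_factory=lambda: {
            "control": {"carbohydrate": (167.0, 0.05), "lipid": (153.0, 0.05)},
            "Co-2": {"carbohydrate": (255.0, 0.05), "lipid": (231.0, 0.05)},
            "Mn-2": {"carbohydrate": (74.0, 0.05), "lipid": (184.0, 0.05)},
            "Mn-6": {"carbohydrate": (120.0, 0.05), "lipid": (111.0, 0.05)},
        }
    )

    def __post_init__(self) -> None:
        if not self.fa_panel:
            raise ValueError("fa_panel must be nonempty")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
            raise ValueError("class_mix must be nonnegative and sum to 1")
        lo, hi = self.tfa_range
        if not (0 < lo <= hi <= 100):
            raise ValueError("tfa_range must lie within (0, 100]")
        if self.class_concentration <= 0 or self.within_concentration <= 0:
            raise ValueError("concentration parameters must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load from YAML or JSON; fatty acids given as shorthand strings."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if "fa_panel" in raw:
            raw["fa_panel"] = tuple(parse_fatty_acid(s) for s in raw["fa_panel"])
        for key in ("class_mix", "tfa_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "treatment_effects" in raw:
            raw["treatment_effects"] = {
                k: tuple(v) for k, v in raw["treatment_effects"].items()
            }
        if "yield_model" in raw:
            raw["yield_model"] = {
                t: {c: tuple(mv) for c, mv in comps.items()}
                for t, comps in raw["yield_model"].items()
            }
        return cls(**raw)


def _sample_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # independent substream per (stream, index): sample i is identical
    # whatever n_samples is
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def _clip_to_simplex(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise ValueError("treatment shift degenerated the class simplex")
    return p / total


def _treatment_label_metal(label: str) -> Treatment:
    for metal in ("Zn", "Co", "Mn"):
        if label.startswith(metal):
            dose = label.split("-", 1)[1] if "-" in label else None
            return Treatment(metal=metal, dose=float(dose) if dose else None)
    return Treatment(metal="none")


def generate_profiles(config: SyntheticConfig) -> list[FAProfile]:
    """Draw ``n_samples`` synthetic profiles (seed-deterministic).

    Treatment labels cycle through ``treatment_effects`` keys (plus an
    untreated "control" when no effects are configured); sample ``i`` always
    uses substream ``i`` of the seed.
    """
    labels = list(config.treatment_effects) or ["control"]
    by_class: dict[str, list[FattyAcid]] = {"SFA": [], "MUFA": [], "PUFA": []}
    for acid in config.fa_panel:
        by_class[acid.saturation_class].append(acid)
    if any(not v for v in by_class.values()):
        raise ValueError("fa_panel must contain acids of every saturation class")

    mix = np.asarray(config.class_mix, dtype=float)
    profiles = []
    for i in range(config.n_samples):
        rng = _sample_rng(config.seed, 0, i)
        label = labels[i % len(labels)]
        shift = np.asarray(
            config.treatment_effects.get(label, (0.0, 0.0, 0.0)), dtype=float
        )
        alpha = np.maximum(mix * config.class_concentration, 1e-6)
        class_props = _clip_to_simplex(rng.dirichlet(alpha) + shift)
        tfa = rng.uniform(*config.tfa_range)

        composition: dict[FattyAcid, float] = {}
        for cls_idx, cls in enumerate(("SFA", "MUFA", "PUFA")):
            acids = by_class[cls]
            weights = np.array(
                [
                    _DOMINANT_WEIGHTS.get((cls, a.carbons, a.double_bonds), _BASE_WEIGHT)
                    for a in acids
                ]
            )
            weights = weights / weights.sum() * config.within_concentration
            split = rng.dirichlet(np.maximum(weights, 1e-6))
            for acid, frac in zip(acids, split):
                pct = tfa * class_props[cls_idx] * frac
                if pct >= config.nd_threshold:
                    composition[acid] = pct

        profiles.append(
            FAProfile(
                sample_id=f"syn-{i:03d}-{label}",
                composition=composition,
                treatment=_treatment_label_metal(label),
                provenance=f"synthetic seed={config.seed} sample={i}",
            )
        )
    return profiles


def generate_yields(config: SyntheticConfig) -> list[EnergyYields]:
    """Draw per-treatment energy yields from the configured mean/dispersion.

    Gamma draws (always positive) with the given mean and coefficient of
    variation; zero dispersion returns the mean exactly.  Seed-deterministic
    via a substream separate from the profile stream.
    """
    results = []
    for j, (label, comps) in enumerate(sorted(config.yield_model.items())):
        rng = _sample_rng(config.seed, 1, j)
        values: dict[str, float | None] = {"carbohydrate": None, "lipid": None}
        for compound in ("carbohydrate", "lipid"):
            if compound not in comps:
                continue
            mean, cv = comps[compound]
            if mean <= 0:
                raise ValueError(f"{label}: {compound} mean must be positive")
            if cv < 0:
                raise ValueError(f"{label}: dispersion must be >= 0")
            if cv == 0:
                values[compound] = float(mean)
            else:
                shape = 1.0 / cv**2
                values[compound] = float(rng.gamma(shape, mean / shape))
        results.append(
            EnergyYields(
                treatment=label,
                carbohydrate=values["carbohydrate"],
                lipid=values["lipid"],
                is_control=label == "control",
            )
        )
    return results
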