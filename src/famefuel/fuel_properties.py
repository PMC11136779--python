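"""The property engine: ten empirical biodiesel quality indices from a
fatty-acid profile.

All ten are literature regressions on the weight-percent composition:

* ``SV = sum(560 * N_i / M_i)``            (saponification value, mg KOH/g)
* ``IV = sum(254 * D_i * N_i / M_i)``      (iodine value, g I2/100 g)
* ``CN = 46.3 + 5448/SV - 0.005 * IV``     (cetane number)
* ``DU = MUFA + 2 * PUFA``                 (degree of unsaturation, wt %)
* ``LCSF = 0.1*C16:0 + 0.5*C18:0 + 1*C20:0 + 1.5*C22:0 + 2*C24:0``
* ``CFPP = 3.1417 * LCSF - 16.477``        (cold filter plugging point, degC)
* ``OS = 7.770 - 0.0384 * DU``             (oxidative stability, h)
* ``CP = 0.526 * C16:0 - 4.992``           (cloud point, degC)
* ``PP = 0.571 * C16:0 - 12.240``          (pour point, degC)
* ``FP = 205.226 + 0.083*C16:0 - 1.723*C18:0 - 0.5717*C18:1
        - 0.3557*C18:2 - 0.46*C18:3 - 0.2287*C22:0``  (flash point, degC)

N_i is the acid's percent of total fatty acids, M_i its FAME molar mass and
D_i its double-bond count.  Percents are used exactly as given (they are NOT
renormalized to sum to 100), and every downstream equation consumes unrounded
intermediates; rounding belongs to report time only.

The pour-point regression is published in terms of "C18" in some sources, but
only the palmitic-acid (C16:0) reading reproduces reference pour points; it
is the default, with the stearic reading selectable for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import pandas as pd

from .fame_chemistry import mass_table
from .fame_profile import ClassTotals, FAProfile, FattyAcid

__all__ = [
    "FuelProperties",
    "PROPERTY_COLUMNS",
    "compute_sv",
    "compute_iv",
    "compute_cn",
    "compute_du",
    "compute_lcsf",
    "compute_cfpp",
    "compute_os",
    "compute_cp",
    "compute_pp",
    "compute_fp",
    "predict_all",
    "properties_table",
]

PROPERTY_COLUMNS = ["CN", "SV", "IV", "DU", "LCSF", "CFPP", "CP", "PP", "OS", "FP"]

# LCSF term weights on the saturated C16..C24 percents
_LCSF_WEIGHTS = {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}


@dataclass(frozen=True)
class FuelProperties:
    """The ten predicted quantities for one profile (unrounded)."""

    cn: float
    sv: float
    iv: float
    du: float
    lcsf: float
    cfpp: float
    cp: float
    pp: float
    os: float
    fp: float

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k.upper(): v for k, v in d.items()}


def _masses(
    profile: FAProfile, masses: Mapping[FattyAcid, float] | None, convention: str
) -> Mapping[FattyAcid, float]:
    if masses is not None:
        return masses
    return mass_table(profile.composition.keys(), convention)


def compute_sv(
    profile: FAProfile,
    masses: Mapping[FattyAcid, float] | None = None,
    convention: str = "methyl_ester",
) -> float:
    """Saponification value, mg KOH per g."""
    mm = _masses(profile, masses, convention)
    return sum(560.0 * pct / mm[acid] for acid, pct in profile.composition.items())


def compute_iv(
    profile: FAProfile,
    masses: Mapping[FattyAcid, float] | None = None,
    convention: str = "methyl_ester",
) -> float:
    """Iodine value, g I2 per 100 g; exactly 0 for fully saturated profiles."""
    mm = _masses(profile, masses, convention)
    return sum(
        254.0 * acid.double_bonds * pct / mm[acid]
        for acid, pct in profile.composition.items()
    )


def compute_cn(sv: float, iv: float) -> float:
    """Cetane number from SV and IV.  Undefined (raises) when SV = 0."""
    if sv == 0:
        raise ValueError("cetane number is undefined for SV = 0")
    return 46.3 + 5448.0 / sv - 0.005 * iv


def compute_du(totals: ClassTotals) -> float:
    """Degree of unsaturation: MUFA + 2 x PUFA (wt %)."""
    return totals.mufa + 2.0 * totals.pufa


def compute_lcsf(profile: FAProfile) -> float:
    """Long-chain saturation factor: weighted sum of saturated C16..C24."""
    return sum(
        w * profile.percent(FattyAcid(n, 0)) for n, w in _LCSF_WEIGHTS.items()
    )


def compute_cfpp(lcsf: float) -> float:
    """Cold filter plugging point (degC) from the unrounded LCSF."""
    return 3.1417 * lcsf - 16.477


def compute_os(du: float) -> float:
    """Oxidative stability (h) from the unrounded DU."""
    return -0.0384 * du + 7.770


def compute_cp(profile: FAProfile) -> float:
    """Cloud point (degC), affine in the palmitic-acid percent."""
    return 0.526 * profile.percent(FattyAcid(16, 0)) - 4.992


def compute_pp(profile: FAProfile, on_palmitic: bool = True) -> float:
    """Pour point (degC).

    Default uses the palmitic (C16:0) percent; ``on_palmitic=False`` applies
    the literal stearic (C18:0) reading of the published coefficient.
    """
    carbons = 16 if on_palmitic else 18
    return 0.571 * profile.percent(FattyAcid(carbons, 0)) - 12.240


def compute_fp(profile: FAProfile) -> float:
    """Flash point (degC).  Evaluates to the 205.226 intercept on an empty
    profile; C18:1/C18:2/C18:3 terms sum across omega isomers and the C22
    term is taken as behenic acid (C22:0)."""
    return (
        205.226
        + 0.083 * profile.percent(FattyAcid(16, 0))
        - 1.723 * profile.percent(FattyAcid(18, 0))
        - 0.5717 * profile.percent_of_species(18, 1)
        - 0.3557 * profile.percent_of_species(18, 2)
        - 0.46 * profile.percent_of_species(18, 3)
        - 0.2287 * profile.percent(FattyAcid(22, 0))
    )


def predict_all(
    profile: FAProfile,
    masses: Mapping[FattyAcid, float] | None = None,
    convention: str = "methyl_ester",
    use_reported_totals: bool = False,
    pp_on_palmitic: bool = True,
) -> FuelProperties:
    """All ten properties for one profile.

    ``use_reported_totals=True`` computes DU (and hence OS) from the class
    totals as printed in the source table when the profile carries them —
    the faithful reproduction mode for transcribed literature tables whose
    printed class sums disagree with their own per-acid cells.  CN propagates
    a ValueError for an empty (SV = 0) profile.
    """
    sv = compute_sv(profile, masses, convention)
    iv = compute_iv(profile, masses, convention)
    du = compute_du(profile.totals(reported=use_reported_totals))
    lcsf = compute_lcsf(profile)
    return FuelProperties(
        cn=compute_cn(sv, iv),
        sv=sv,
        iv=iv,
        du=du,
        lcsf=lcsf,
        cfpp=compute_cfpp(lcsf),
        cp=compute_cp(profile),
        pp=compute_pp(profile, on_palmitic=pp_on_palmitic),
        os=compute_os(du),
        fp=compute_fp(profile),
    )


def properties_table(
    profiles: Iterable[FAProfile],
    convention: str = "methyl_ester",
    use_reported_totals: bool = False,
    pp_on_palmitic: bool = True,
    round_to: int | None = None,
) -> pd.DataFrame:
    """One row per sample with the standard property columns.

    Values are full precision unless ``round_to`` is given (presentation
    only; nothing downstream consumes rounded numbers).
    """
    rows = []
    for p in profiles:
        props = predict_all(
            p,
            convention=convention,
            use_reported_totals=use_reported_totals,
            pp_on_palmitic=pp_on_palmitic,
        )
        rows.append({"sample_id": p.sample_id, **props.as_dict()})
    df = pd.DataFrame(rows, columns=["sample_id", *PROPERTY_COLUMNS])
    if round_to is not None:
        df[PROPERTY_COLUMNS] = df[PROPERTY_COLUMNS].round(round_to)
    return df
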