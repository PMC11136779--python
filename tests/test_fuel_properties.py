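"""The property engine: single-equation checks, reference-culture values,
affine identities, and an independent re-evaluation oracle."""

import math

import pytest
from hypothesis import given
import hypothesis.strategies as st

from famefuel.fame_chemistry import fame_molar_mass
from famefuel.fame_profile import ClassTotals, FAProfile, FattyAcid, class_totals
from famefuel.fuel_properties import (
    compute_cfpp,
    compute_cn,
    compute_cp,
    compute_du,
    compute_fp,
    compute_iv,
    compute_lcsf,
    compute_os,
    compute_pp,
    compute_sv,
    predict_all,
    properties_table,
)

from conftest import profiles


def single(acid: FattyAcid, pct: float = 100.0) -> FAProfile:
    return FAProfile("single", {acid: pct})


def by_id(table1, sample_id):
    return next(p for p in table1 if p.sample_id == sample_id)


class TestSaponificationValue:
    def test_single_component_oleate(self):
        # 560 * 100 / 296.495
        got = compute_sv(single(FattyAcid(18, 1, 9)))
        assert got == pytest.approx(560 * 100 / 296.495, rel=1e-9)
        assert got == pytest.approx(188.9, abs=0.05)

    def test_empty_profile_gives_zero(self):
        assert compute_sv(FAProfile("empty", {})) == 0.0

    def test_control_culture_close_to_reference(self, table1_profiles):
        sv = compute_sv(by_id(table1_profiles, "control"))
        assert sv == pytest.approx(143.77, rel=0.003)  # documented <0.3 % residual

    def test_free_acid_convention_overshoots_reference(self, table1_profiles):
        """Only the methyl-ester mass convention reproduces the reference
        SV; free-acid masses land ~5 % high (the documented reason the
        ester convention is the default)."""
        sv = compute_sv(by_id(table1_profiles, "control"), convention="free_acid")
        assert sv == pytest.approx(151.7, abs=0.5)
        assert abs(sv - 143.77) / 143.77 > 0.04


class TestIodineValue:
    def test_zero_for_fully_saturated(self):
        prof = FAProfile("sat", {FattyAcid(16, 0): 60.0, FattyAcid(18, 0): 30.0})
        assert compute_iv(prof) == 0.0

    def test_cobalt_3uM_culture(self, table1_profiles):
        iv = compute_iv(by_id(table1_profiles, "Co-3"))
        assert iv == pytest.approx(17.65, rel=0.005)

    def test_single_component_linoleate(self):
        got = compute_iv(single(FattyAcid(18, 2, 6)))
        assert got == pytest.approx(254 * 2 * 100 / 294.479, rel=1e-9)
        assert got == pytest.approx(172.5, abs=0.1)


class TestCetaneNumber:
    @pytest.mark.parametrize(
        "sv, iv, expected",
        [
            (143.77, 24.49, 84.07),  # reference control row inputs
            (5448.0, 0.0, 47.3),     # unit-fraction case
            (203.09, 63.38, 72.81),
        ],
    )
    def test_direct_evaluation(self, sv, iv, expected):
        assert compute_cn(sv, iv) == pytest.approx(expected, abs=0.005)

    def test_undefined_at_zero_sv(self):
        with pytest.raises(ValueError):
            compute_cn(0.0, 10.0)


class TestUnsaturationChain:
    @pytest.mark.parametrize(
        "mufa, pufa, expected",
        [(28.02, 17.25, 62.52), (0.0, 0.0, 0.0), (19.95, 0.0, 19.95)],
    )
    def test_du(self, mufa, pufa, expected):
        assert compute_du(ClassTotals(0, mufa, pufa)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "du, expected", [(19.95, 7.00), (0.0, 7.770), (62.52, 5.37)]
    )
    def test_os(self, du, expected):
        assert compute_os(du) == pytest.approx(expected, abs=0.005)


class TestColdFlow:
    def test_lcsf_reference_cultures(self, table1_profiles):
        assert compute_lcsf(by_id(table1_profiles, "Co-3")) == pytest.approx(14.26, abs=0.005)
        assert compute_lcsf(by_id(table1_profiles, "Co-2")) == pytest.approx(5.21, abs=0.01)
        assert compute_lcsf(FAProfile("empty", {})) == 0.0

    @pytest.mark.parametrize(
        "lcsf, expected",
        [(14.263, 28.33), (0.0, -16.477), (5.2445, 0.0)],
    )
    def test_cfpp_affine_map(self, lcsf, expected):
        assert compute_cfpp(lcsf) == pytest.approx(expected, abs=0.005)

    def test_cp_pp_from_palmitic_percent(self):
        prof = single(FattyAcid(16, 0), 58.17)
        assert compute_pp(prof) == pytest.approx(20.98, abs=0.01)
        prof2 = single(FattyAcid(16, 0), 53.59)
        assert compute_pp(prof2) == pytest.approx(18.36, abs=0.005)
        assert compute_cp(prof2) == pytest.approx(23.20, abs=0.005)
        empty = FAProfile("empty", {})
        assert compute_cp(empty) == pytest.approx(-4.992)
        assert compute_pp(empty) == pytest.approx(-12.240)

    def test_pp_stearic_reading_selectable(self):
        prof = FAProfile("x", {FattyAcid(16, 0): 40.0, FattyAcid(18, 0): 10.0})
        assert compute_pp(prof, on_palmitic=False) == pytest.approx(
            0.571 * 10.0 - 12.240
        )


class TestFlashPoint:
    def test_intercept_on_empty_profile(self):
        assert compute_fp(FAProfile("empty", {})) == pytest.approx(205.226)

    def test_single_stearic_term(self):
        assert compute_fp(single(FattyAcid(18, 0), 10.0)) == pytest.approx(187.996)

    def test_control_culture_equation_as_written(self, table1_profiles):
        # diverges from the reference table's printed 189.36 — documented
        assert compute_fp(by_id(table1_profiles, "control")) == pytest.approx(176.3, abs=0.05)


class TestPredictAll:
    def test_cobalt_3uM_row(self, table1_profiles):
        props = predict_all(by_id(table1_profiles, "Co-3"), use_reported_totals=True)
        assert props.lcsf == pytest.approx(14.26, abs=0.005)
        assert props.cfpp == pytest.approx(28.33, abs=0.005)
        assert props.du == pytest.approx(19.95, abs=0.005)
        assert props.os == pytest.approx(7.00, abs=0.005)
        assert props.cp == pytest.approx(16.59, abs=0.005)
        assert props.pp == pytest.approx(11.19, abs=0.005)

    def test_empty_profile_raises_for_cn(self):
        with pytest.raises(ValueError):
            predict_all(FAProfile("empty", {}))

    @given(profiles())
    def test_matches_independent_per_equation_reevaluation(self, profile):
        """predict_all equals a from-scratch re-evaluation of every formula."""
        props = predict_all(profile)
        masses = {
            a: fame_molar_mass(a).molar_mass for a in profile.composition
        }
        sv = sum(560 * v / masses[a] for a, v in profile.composition.items())
        iv = sum(
            254 * a.double_bonds * v / masses[a]
            for a, v in profile.composition.items()
        )
        mufa = sum(v for a, v in profile.composition.items() if a.double_bonds == 1)
        pufa = sum(v for a, v in profile.composition.items() if a.double_bonds >= 2)
        c = {
            (n, d): sum(
                v
                for a, v in profile.composition.items()
                if a.carbons == n and a.double_bonds == d
            )
            for n in (16, 18, 20, 22, 24)
            for d in (0, 1, 2, 3)
        }
        assert props.sv == pytest.approx(sv, rel=1e-12)
        assert props.iv == pytest.approx(iv, rel=1e-12)
        assert props.du == pytest.approx(mufa + 2 * pufa, rel=1e-12)
        lcsf = (
            0.1 * c[(16, 0)] + 0.5 * c[(18, 0)] + 1.0 * c[(20, 0)]
            + 1.5 * c[(22, 0)] + 2.0 * c[(24, 0)]
        )
        assert props.lcsf == pytest.approx(lcsf, rel=1e-12)
        assert props.cp == pytest.approx(0.526 * c[(16, 0)] - 4.992, rel=1e-12)
        assert props.pp == pytest.approx(0.571 * c[(16, 0)] - 12.240, rel=1e-12)
        fp = (
            205.226 + 0.083 * c[(16, 0)] - 1.723 * c[(18, 0)]
            - 0.5717 * c[(18, 1)] - 0.3557 * c[(18, 2)]
            - 0.46 * c[(18, 3)] - 0.2287 * c[(22, 0)]
        )
        assert props.fp == pytest.approx(fp, rel=1e-12)

    @given(profiles())
    def test_affine_identities_hold_to_machine_tolerance(self, profile):
        """OS + 0.0384*DU = 7.770 and CFPP - 3.1417*LCSF = -16.477 exactly."""
        props = predict_all(profile)
        assert props.os + 0.0384 * props.du == pytest.approx(7.770, abs=1e-12)
        assert props.cfpp - 3.1417 * props.lcsf == pytest.approx(-16.477, abs=1e-12)

    @given(profiles(), st.floats(min_value=0.1, max_value=1.0))
    def test_sv_iv_linear_under_composition_scaling(self, profile, k):
        scaled = FAProfile(
            "scaled", {a: v * k for a, v in profile.composition.items()}
        )
        assert compute_sv(scaled) == pytest.approx(k * compute_sv(profile), rel=1e-9)
        assert compute_iv(scaled) == pytest.approx(k * compute_iv(profile), rel=1e-9)


class TestMonotonicity:
    @pytest.mark.parametrize("carbons", [16, 18, 20, 22, 24])
    def test_adding_saturated_mass_raises_cold_flow_indices(self, carbons):
        base = FAProfile("b", {FattyAcid(16, 0): 30.0, FattyAcid(18, 1, 9): 20.0})
        bumped = dict(base.composition)
        acid = FattyAcid(carbons, 0)
        bumped[acid] = bumped.get(acid, 0.0) + 5.0
        more = FAProfile("m", bumped)
        assert compute_lcsf(more) > compute_lcsf(base)
        assert compute_cfpp(compute_lcsf(more)) > compute_cfpp(compute_lcsf(base))
        if carbons == 16:
            assert compute_cp(more) > compute_cp(base)
            assert compute_pp(more) > compute_pp(base)

    def test_double_bonds_raise_iv_du_and_lower_os(self):
        sat = FAProfile("s", {FattyAcid(18, 0): 50.0})
        mono = FAProfile("m", {FattyAcid(18, 1, 9): 50.0})
        poly = FAProfile("p", {FattyAcid(18, 2, 6): 50.0})
        ivs = [compute_iv(p) for p in (sat, mono, poly)]
        dus = [compute_du(class_totals(p)) for p in (sat, mono, poly)]
        assert ivs == sorted(ivs) and ivs[0] < ivs[1] < ivs[2]
        assert dus == sorted(dus) and dus[0] < dus[1] < dus[2]
        oss = [compute_os(du) for du in dus]
        assert oss[0] > oss[1] > oss[2]


def test_properties_table_shape_and_rounding(table1_profiles):
    df = properties_table(table1_profiles, use_reported_totals=True, round_to=2)
    assert list(df.columns) == [
        "sample_id", "CN", "SV", "IV", "DU", "LCSF", "CFPP", "CP", "PP", "OS", "FP"
    ]
    assert len(df) == 11
    # rounding is presentation-only: the Co-2 CFPP sign survives
    co2 = df.set_index("sample_id").loc["Co-2"]
    assert co2["CFPP"] == pytest.approx(-0.12, abs=0.005)
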